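"""PCA, factorability diagnostics, parallel analysis and MANOVA."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.multivariate.manova import MANOVA as SmMANOVA

from plasmapanel import (
    BiomarkerTable,
    bartlett_sphericity,
    kmo,
    manova_wilks,
    parallel_analysis,
    run_pca,
    variable_contributions,
)


def _table(values, group=None, markers=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return BiomarkerTable(
        subject_ids=[f"s{i}" for i in range(n)],
        marker_names=markers or [f"m{j}" for j in range(p)],
        values=values,
        group=group if group is not None else ["g"] * n,
    )


class TestPCA:
    def test_rank_one_pair_gives_all_variance_to_pc1(self, rng):
        x = rng.normal(10, 1, 40)
        t = _table(np.column_stack([x, 2 * x]))
        res = run_pca(t, matrix_mode="correlation")
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_eigenvalue_sum_equals_marker_count(self, rng):
        t = _table(rng.normal(10, 2, (50, 5)))
        res = run_pca(t, matrix_mode="correlation")
        assert res.eigenvalues.sum() == pytest.approx(5.0, abs=1e-9)

    def test_modes_agree_on_pct_variance(self, set1_cohort):
        a = run_pca(set1_cohort, matrix_mode="covariance_normalized")
        b = run_pca(set1_cohort, matrix_mode="correlation")
        assert np.allclose(a.pct_variance, b.pct_variance, atol=1e-9)

    def test_component_scores_uncorrelated(self, set2_cohort):
        res = run_pca(set2_cohort)
        scores = res.component_scores[:, :3]  # well-conditioned components
        r = np.corrcoef(scores, rowvar=False)
        assert np.max(np.abs(r[~np.eye(3, dtype=bool)])) < 1e-8

    def test_constant_marker_rejected(self, rng):
        vals = rng.normal(10, 1, (20, 3))
        vals[:, 1] = 7.0
        with pytest.raises(ValueError, match="m1"):
            run_pca(_table(vals))

    def test_contribution_ranking_and_range_check(self, set2_cohort):
        res = run_pca(set2_cohort)
        ranked = variable_contributions(res, 0)
        mags = np.abs(ranked.to_numpy())
        assert (np.diff(mags) <= 1e-12).all()
        with pytest.raises(IndexError):
            variable_contributions(res, 99)

    def test_separation_markers_dominate_pc1(self, set2_cohort):
        # every marker carries the same group shift, so PC1 loads all of
        # them nearly equally and positively (sign convention)
        res = run_pca(set2_cohort)
        pc1 = res.contributions["PC1"]
        assert (pc1 > 0).all()
        assert pc1.max() / pc1.min() < 1.2


class TestBartlett:
    def test_independent_markers_near_null(self, rng):
        t = _table(rng.normal(50, 5, (1000, 5)))
        stat, p = bartlett_sphericity(t)
        df = 5 * 4 / 2
        assert stat == pytest.approx(df, abs=4 * np.sqrt(2 * df))
        assert p > 0.05

    def test_duplicated_marker_forces_p_to_zero(self, rng):
        x = rng.normal(10, 1, 30)
        y = rng.normal(10, 1, 30)
        with pytest.warns(UserWarning, match="singular"):
            stat, p = bartlett_sphericity(_table(np.column_stack([x, y, x])))
        assert p == 0.0

    def test_matches_direct_determinant_oracle(self, rng):
        for _ in range(5):
            t = _table(rng.normal(20, 3, (40, 5)) + rng.normal(0, 2, (40, 1)))
            stat, p = bartlett_sphericity(t)
            R = np.corrcoef(t.values, rowvar=False)
            n, k = 40, 5
            expected = -(n - 1 - (2 * k + 5) / 6) * np.log(np.linalg.det(R))
            assert stat == pytest.approx(expected, abs=1e-9)
            assert p == pytest.approx(stats.chi2.sf(expected, k * (k - 1) / 2), abs=1e-12)


class TestKMO:
    def test_strong_common_factor_gives_high_kmo(self, rng):
        f = rng.normal(0, 1, 500)
        vals = 20 + 2 * f[:, None] + rng.normal(0, 1, (500, 6))
        overall, per = kmo(_table(vals))
        assert overall > 0.8
        assert ((per > 0.7) & (per <= 1.0)).all()

    def test_independent_noise_gives_kmo_near_half(self, rng):
        overall, _ = kmo(_table(rng.normal(30, 2, (2000, 6))))
        assert overall == pytest.approx(0.5, abs=0.07)

    def test_matches_partial_correlation_oracle(self, rng):
        # independent route: partial correlations from OLS residuals
        vals = 20 + rng.normal(0, 1, (60, 4)) + 1.5 * rng.normal(0, 1, (60, 1))
        t = _table(vals)
        overall, _ = kmo(t)
        X = vals - vals.mean(axis=0)
        p = X.shape[1]
        r2_sum, q2_sum = 0.0, 0.0
        R = np.corrcoef(X, rowvar=False)
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                others = [k for k in range(p) if k not in (i, j)]
                Z = X[:, others]
                beta_i = np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
                beta_j = np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
                ri = X[:, i] - Z @ beta_i
                rj = X[:, j] - Z @ beta_j
                q = np.corrcoef(ri, rj)[0, 1]
                r2_sum += R[i, j] ** 2
                q2_sum += q**2
        assert overall == pytest.approx(r2_sum / (r2_sum + q2_sum), abs=1e-9)

    def test_singular_matrix_rejected(self, rng):
        x = rng.normal(10, 1, 30)
        with pytest.raises(ValueError, match="collinear"):
            kmo(_table(np.column_stack([x, 2 * x, rng.normal(0, 1, 30)])))


class TestParallelAnalysis:
    def test_seed_reproducible(self, set2_cohort):
        a = parallel_analysis(set2_cohort, n_permutations=150, seed=3)
        b = parallel_analysis(set2_cohort, n_permutations=150, seed=3)
        assert np.array_equal(a.simulated_p95, b.simulated_p95)

    def test_p50_below_p95_and_monotone(self, rng):
        t = _table(rng.normal(15, 2, (60, 6)))
        res = parallel_analysis(t, n_permutations=1000, seed=0)
        assert (res.simulated_p50 <= res.simulated_p95).all()
        assert (np.diff(res.simulated_p95) <= 1e-12).all()

    def test_structured_cohorts_retain_one_component(self, set1_cohort, set2_cohort):
        for t in (set1_cohort, set2_cohort):
            res = parallel_analysis(t, n_permutations=300, seed=1)
            assert res.n_significant == 1

    def test_normal_reference_variant(self, set2_cohort):
        res = parallel_analysis(set2_cohort, n_permutations=150, seed=2, method="normal")
        assert res.n_significant == 1

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_permutations=50), dict(percentiles=(95, 50)), dict(method="bogus")],
    )
    def test_invalid_arguments_rejected(self, set2_cohort, kwargs):
        with pytest.raises(ValueError):
            parallel_analysis(set2_cohort, **kwargs)


class TestManova:
    def test_univariate_f_matches_scipy(self, rng):
        vals = rng.normal(10, 1, (30, 3))
        vals[15:, 1] += 0.8
        group = ["a"] * 15 + ["b"] * 15
        res = manova_wilks(_table(vals, group=group))
        for j in range(3):
            f_ref, p_ref = stats.f_oneway(vals[:15, j], vals[15:, j])
            assert res.univariate["F"].iloc[j] == pytest.approx(f_ref, abs=1e-9)
            assert res.univariate["p"].iloc[j] == pytest.approx(p_ref, abs=1e-12)

    def test_wilks_f_reduces_to_univariate_f_for_scalar_response(self, rng):
        # for a single response the Wilks F is the one-way F exactly; the
        # scalar scatter "matrices" are computed here as the oracle
        x = np.concatenate([rng.normal(0, 1, 12), rng.normal(1, 1, 13)])
        groups = np.array([0] * 12 + [1] * 13)
        w = sum(((x[groups == g] - x[groups == g].mean()) ** 2).sum() for g in (0, 1))
        b = sum(
            (groups == g).sum() * (x[groups == g].mean() - x.mean()) ** 2
            for g in (0, 1)
        )
        lam = w / (w + b)
        n = len(x)
        f_from_lambda = (1 - lam) / lam * (n - 2)
        f_ref, _ = stats.f_oneway(x[groups == 0], x[groups == 1])
        assert f_from_lambda == pytest.approx(f_ref, abs=1e-9)

    def test_two_group_wilks_matches_statsmodels(self, set2_cohort):
        res = manova_wilks(set2_cohort)
        sm_fit = SmMANOVA(
            set2_cohort.values,
            np.column_stack(
                [
                    np.ones(set2_cohort.n_subjects),
                    (set2_cohort.group == "autistic").astype(float),
                ]
            ),
        ).mv_test()
        table = sm_fit.results["x1"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), abs=1e-9
        )
        assert res.F_multivariate == pytest.approx(
            float(table.loc["Wilks' lambda", "F Value"]), rel=1e-9
        )

    def test_three_group_wilks_matches_statsmodels(self, rng):
        vals = rng.normal(20, 2, (45, 4))
        vals[15:30] += 1.0
        group = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        res = manova_wilks(_table(vals, group=group))
        design = np.column_stack(
            [
                np.ones(45),
                np.array([g == "b" for g in group], dtype=float),
                np.array([g == "c" for g in group], dtype=float),
            ]
        )
        sm_fit = SmMANOVA(vals, design).mv_test(
            hypotheses=[("groups", np.array([[0, 1, 0], [0, 0, 1]]), None)]
        )
        table = sm_fit.results["groups"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), abs=1e-9
        )
        assert res.p_multivariate == pytest.approx(
            float(table.loc["Wilks' lambda", "Pr > F"]), abs=1e-9
        )

    def test_lambda_invariant_to_affine_marker_rescaling(self, set2_cohort, rng):
        res = manova_wilks(set2_cohort)
        scale = rng.uniform(0.5, 3.0, set2_cohort.n_markers)
        shift = rng.uniform(-5, 5, set2_cohort.n_markers)
        rescaled = BiomarkerTable(
            subject_ids=set2_cohort.subject_ids,
            marker_names=set2_cohort.marker_names,
            values=set2_cohort.values * scale + shift + 50,
            group=set2_cohort.group,
        )
        assert manova_wilks(rescaled).wilks_lambda == pytest.approx(
            res.wilks_lambda, rel=1e-9
        )

    def test_separated_groups_strongly_significant(self, set1_cohort):
        res = manova_wilks(set1_cohort)
        assert res.p_multivariate < 1e-10
        assert 0 < res.wilks_lambda < 0.1

    def test_degenerate_groupings_rejected(self, rng):
        vals = rng.normal(10, 1, (10, 3))
        with pytest.raises(ValueError, match="2 groups"):
            manova_wilks(_table(vals, group=["a"] * 10))
        with pytest.raises(ValueError, match="at least 2 subjects"):
            manova_wilks(_table(vals, group=["a"] * 9 + ["b"]))
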