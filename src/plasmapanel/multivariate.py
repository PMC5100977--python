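"""PCA with variance normalization, factorability diagnostics, parallel
analysis for component retention, and MANOVA group testing.

Two PCA weighting modes are offered.  ``correlation`` diagonalises the sample
correlation matrix.  ``covariance_normalized`` first rescales every marker to
unit variance and then uses the covariance matrix of the rescaled data —
which makes the two modes coincide, the point of the normalization being that
markers measured on large numeric scales must not dominate the decomposition.
A literal variance-division variant (dividing by the variance rather than the
standard deviation) is retained behind a flag for auditability; it is not the
default because it leaves residual scale differences between markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import BiomarkerTable

__all__ = [
    "PCAResult",
    "ParallelAnalysisResult",
    "ManovaResult",
    "run_pca",
    "variable_contributions",
    "bartlett_sphericity",
    "kmo",
    "parallel_analysis",
    "manova_wilks",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Eigendecomposition of a marker panel.

    ``contributions`` holds the signed variable coordinates (loading times
    the square root of the eigenvalue), the usual quantity for ranking how
    much each marker drives a component.
    """

    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    component_scores: np.ndarray
    contributions: pd.DataFrame
    matrix_mode: str

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _unit_scale(table: BiomarkerTable, variance_division: bool) -> np.ndarray:
    X = table.values
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [table.marker_names[j] for j in zero]
        raise ValueError(f"constant (zero-variance) markers: {names}")
    return X / (sd**2 if variance_division else sd)


def run_pca(
    table: BiomarkerTable,
    matrix_mode: str = "covariance_normalized",
    variance_division: bool = False,
) -> PCAResult:
    """Principal component analysis of a biomarker table.

    Parameters
    ----------
    matrix_mode
        ``covariance_normalized`` (markers scaled to unit variance, then
        covariance) or ``correlation``.  The two coincide.
    variance_division
        Audit variant: scale by the variance instead of the standard
        deviation (only meaningful in ``covariance_normalized`` mode).

    Component signs are fixed so the largest-magnitude loading of each
    component is positive.  Eigenvalues use the n-1 covariance denominator.
    """
    if matrix_mode not in ("covariance_normalized", "correlation"):
        raise ValueError(f"unknown matrix_mode {matrix_mode!r}")
    if matrix_mode == "correlation":
        Z = _unit_scale(table, variance_division=False)
    else:
        Z = _unit_scale(table, variance_division)
    Zc = Z - Z.mean(axis=0)
    C = (Zc.T @ Zc) / (table.n_subjects - 1)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(eigvecs.shape[1])])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    loadings = eigvecs * np.sqrt(eigvals)
    comps = [f"PC{k + 1}" for k in range(len(eigvals))]
    return PCAResult(
        eigenvalues=eigvals,
        pct_variance=100.0 * eigvals / eigvals.sum(),
        component_scores=Zc @ eigvecs,
        contributions=pd.DataFrame(loadings, index=table.marker_names, columns=comps),
        matrix_mode=matrix_mode,
    )


def variable_contributions(result: PCAResult, component: int) -> pd.Series:
    """Markers ranked by their contribution to one component (0-based).

    Returns the signed loadings sorted by decreasing magnitude; ties keep the
    input marker order (the sort is stable).
    """
    if not 0 <= component < result.n_components:
        raise IndexError(
            f"component {component} out of range 0..{result.n_components - 1}"
        )
    col = result.contributions.iloc[:, component]
    order = np.argsort(-np.abs(col.to_numpy()), kind="stable")
    return col.iloc[order]


# ---------------------------------------------------------------------------
# Factorability diagnostics
# ---------------------------------------------------------------------------


def bartlett_sphericity(table: BiomarkerTable) -> tuple[float, float]:
    """Bartlett's test that the marker correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), with df = p(p-1)/2.  A singular
    correlation matrix (det <= 0 numerically) is reported as p -> 0 with a
    warning, since it is maximally far from sphericity.
    """
    n, p = table.values.shape
    if n <= p:
        warnings.warn(
            "fewer subjects than markers; Bartlett's test is unreliable",
            stacklevel=2,
        )
    R = np.corrcoef(table.values, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn(
            "singular correlation matrix; reporting Bartlett p ~ 0", stacklevel=2
        )
        return float("inf"), 0.0
    statistic = -(n - 1 - (2 * p + 5) / 6) * logdet
    df = p * (p - 1) / 2
    return float(statistic), float(stats.chi2.sf(statistic, df))


def kmo(table: BiomarkerTable) -> tuple[float, pd.Series]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Compares squared correlations with squared partial correlations obtained
    from the anti-image (scaled inverse) correlation matrix:

        KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2),   i != j

    Values near 1 indicate that markers share enough common variance for a
    components analysis to be meaningful; values near 0.5 arise when partial
    and marginal correlations are comparable (little shared structure).
    Returns the overall value and the per-marker values.
    """
    R = np.corrcoef(table.values, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular correlation matrix; remove collinear markers before "
            "computing KMO"
        ) from None
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(len(R), dtype=bool)
    r2 = R[off] ** 2
    q2 = Q[off] ** 2
    overall = r2.sum() / (r2.sum() + q2.sum())
    per = (R**2 * off).sum(axis=1) / ((R**2 * off).sum(axis=1) + (Q**2 * off).sum(axis=1))
    return float(overall), pd.Series(per, index=table.marker_names, name="kmo")


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------


@dataclass
class ParallelAnalysisResult:
    """Observed eigenvalues against permutation-based reference percentiles.

    ``significant`` flags components whose observed eigenvalue exceeds the
    95th percentile of the eigenvalues of datasets in which every marker
    column was independently shuffled, destroying inter-marker correlation
    while preserving marginals.  ``n_significant`` counts the *leading run*
    of significant components — retention stops at the first component that
    fails, the usual scree-plot reading; an isolated exceedance deep in the
    tail (expected by chance in about 5% of components) does not add a
    retained component.
    """

    raw_eigenvalues: np.ndarray
    simulated_p50: np.ndarray
    simulated_p95: np.ndarray
    significant: np.ndarray
    n_permutations: int
    seed: int | None
    method: str

    @property
    def n_significant(self) -> int:
        run = 0
        for flag in self.significant:
            if not flag:
                break
            run += 1
        return run


def parallel_analysis(
    table: BiomarkerTable,
    n_permutations: int = 1000,
    percentiles: tuple[float, float] = (50.0, 95.0),
    seed: int | None = None,
    matrix_mode: str = "covariance_normalized",
    method: str = "permutation",
) -> ParallelAnalysisResult:
    """Monte-Carlo component retention (Horn-style parallel analysis).

    ``method='permutation'`` (default) shuffles each observed marker column
    independently in every replicate; ``method='normal'`` draws independent
    standard-normal columns of the same shape.  Eigenvalues of the replicate
    correlation matrices are summarised at the requested percentiles, and a
    component is retained when its observed eigenvalue exceeds the upper
    percentile.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    lo, hi = percentiles
    if not (0 < lo < hi < 100):
        raise ValueError(f"invalid percentiles {percentiles!r}")
    if method not in ("permutation", "normal"):
        raise ValueError(f"unknown method {method!r}")
    raw = run_pca(table, matrix_mode=matrix_mode).eigenvalues
    rng = np.random.default_rng(seed)
    n, p = table.values.shape
    sims = np.empty((n_permutations, p))
    X = table.values
    for b in range(n_permutations):
        if method == "permutation":
            perm = np.empty_like(X)
            for j in range(p):
                perm[:, j] = X[rng.permutation(n), j]
        else:
            perm = rng.standard_normal((n, p))
        ev = np.linalg.eigvalsh(np.corrcoef(perm, rowvar=False))
        sims[b] = ev[::-1]
    p50 = np.percentile(sims, lo, axis=0)
    p95 = np.percentile(sims, hi, axis=0)
    return ParallelAnalysisResult(
        raw_eigenvalues=raw,
        simulated_p50=p50,
        simulated_p95=p95,
        significant=raw > p95,
        n_permutations=n_permutations,
        seed=seed,
        method=method,
    )


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------


@dataclass
class ManovaResult:
    """Wilks' lambda MANOVA with per-marker univariate F tests."""

    wilks_lambda: float
    F_multivariate: float
    df1: float
    df2: float
    p_multivariate: float
    univariate: pd.DataFrame  # per-marker F and p


def manova_wilks(
    table: BiomarkerTable, group_labels: np.ndarray | None = None
) -> ManovaResult:
    """One-way MANOVA on all markers via Wilks' lambda.

    Lambda = det(W) / det(W + B) with W and B the within- and between-group
    scatter matrices; the p-value uses Rao's F approximation (exact for 2
    groups).  Univariate one-way F tests are reported per marker.
    """
    labels = table.group if group_labels is None else np.asarray(group_labels)
    X = table.values
    n, p = X.shape
    uniq = list(dict.fromkeys(str(g) for g in labels))
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    idx = [np.flatnonzero(np.asarray([str(x) for x in labels]) == u) for u in uniq]
    if any(len(i) < 2 for i in idx):
        raise ValueError("every group needs at least 2 subjects")
    if n <= p + g:
        raise ValueError("total subjects must exceed markers + groups")
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for i in idx:
        Xi = X[i]
        ci = Xi - Xi.mean(axis=0)
        W += ci.T @ ci
        d = (Xi.mean(axis=0) - grand)[:, None]
        B += len(i) * (d @ d.T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("singular within-group scatter matrix")
    lam = float(np.exp(logdet_w - logdet_t))
    dfh = g - 1
    denom = p**2 + dfh**2 - 5
    t = np.sqrt((p**2 * dfh**2 - 4) / denom) if denom > 0 else 1.0
    w = n - 1 - (p + g) / 2
    df1 = p * dfh
    df2 = w * t - (df1 - 2) / 2
    lam_t = lam ** (1 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    p_mv = float(stats.f.sf(F, df1, df2))
    rows = []
    for j, name in enumerate(table.marker_names):
        fj, pj = stats.f_oneway(*(X[i, j] for i in idx))
        rows.append((name, float(fj), float(pj)))
    uni = pd.DataFrame(rows, columns=["marker", "F", "p"]).set_index("marker")
    return ManovaResult(
        wilks_lambda=lam,
        F_multivariate=float(F),
        df1=float(df1),
        df2=float(df2),
        p_multivariate=p_mv,
        univariate=uni,
    )
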