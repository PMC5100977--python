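"""Marker-severity correlation screening and stepwise multiple regression.

Severity is the SSP total score of case subjects (points; lower = more
impaired).  Screening reports Pearson r (linear association) and Spearman rho
(monotone association) per marker with two-sided p-values.  Predictor
selection uses classical stepwise regression: forward entry of the candidate
with the smallest partial-F p-value below ``p_enter``, backward removal of
any included predictor whose p-value rises above ``p_remove``, iterated to a
fixpoint.  Each retained model is reported with R, R-squared, adjusted
R-squared, the overall F statistic and its p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_data import BiomarkerTable

__all__ = [
    "correlate_markers",
    "StepModel",
    "RegressionTrace",
    "stepwise_regression",
]


def _exact_spearman_p(rho: float, ranks_x: np.ndarray, ranks_y: np.ndarray) -> float:
    """Exact two-sided permutation p-value for Spearman's rho (small n)."""
    n = len(ranks_x)
    observed = abs(rho)
    count = 0
    total = 0
    ry = ranks_y - ranks_y.mean()
    rx = ranks_x - ranks_x.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    for perm in permutations(range(n)):
        r = float(rx[list(perm)] @ ry) / denom
        count += abs(r) >= observed - 1e-12
        total += 1
    return count / total


def correlate_markers(
    table: BiomarkerTable,
    target: np.ndarray | None = None,
    exact_spearman_max_n: int = 9,
) -> pd.DataFrame:
    """Per-marker Pearson and Spearman correlation with a severity target.

    ``target`` defaults to the table's severity scores; subjects without a
    finite score are dropped.  Pearson p-values come from the t transform;
    Spearman p-values are exact (full permutation null) for n at most
    ``exact_spearman_max_n`` and use the t approximation otherwise.  All
    p-values are two-sided.
    """
    if target is None:
        if table.severity_score is None:
            raise ValueError("table has no severity scores and no target was given")
        target = table.severity_score
    target = np.asarray(target, dtype=float)
    if len(target) != table.n_subjects:
        raise ValueError("target length does not match subject count")
    keep = np.isfinite(target)
    y = target[keep]
    if len(y) < 4:
        raise ValueError("need at least 4 subjects with a severity score")
    if y.std() == 0:
        raise ValueError("severity target has zero variance")
    rows = []
    for j, name in enumerate(table.marker_names):
        x = table.values[keep, j]
        if x.std() == 0:
            raise ValueError(f"marker {name!r} has zero variance; correlation undefined")
        r, p_r = stats.pearsonr(x, y)
        rho, p_rho = stats.spearmanr(x, y)
        if len(y) <= exact_spearman_max_n:
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            p_rho = _exact_spearman_p(float(rho), rx, ry)
        rows.append((name, float(r), float(p_r), float(rho), float(p_rho)))
    return pd.DataFrame(
        rows, columns=["marker", "pearson_r", "pearson_p", "spearman_rho", "spearman_p"]
    ).set_index("marker")


@dataclass
class StepModel:
    """One model in a stepwise trace, recorded after an entry/removal."""

    action: str  # "add" or "remove"
    changed: str  # predictor added or removed
    change_p: float  # partial-F p-value that triggered the action
    predictors: tuple[str, ...]
    R: float
    r_squared: float
    adj_r_squared: float
    F: float
    p: float
    coefficients: dict[str, float]


@dataclass
class RegressionTrace:
    """Ordered stepwise models; empty when no candidate ever entered."""

    steps: list[StepModel]
    p_enter: float
    p_remove: float
    n: int

    @property
    def final(self) -> StepModel | None:
        return self.steps[-1] if self.steps else None

    @property
    def selected(self) -> tuple[str, ...]:
        return self.final.predictors if self.steps else ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [", ".join(s.predictors) for s in self.steps],
                "action": [f"{s.action} {s.changed}" for s in self.steps],
                "R": [s.R for s in self.steps],
                "R2": [s.r_squared for s in self.steps],
                "adj_R2": [s.adj_r_squared for s in self.steps],
                "F": [s.F for s in self.steps],
                "p": [s.p for s in self.steps],
            }
        )


def _fit(X: np.ndarray, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    table: BiomarkerTable,
    target: np.ndarray | None = None,
    candidates: list[str] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    collinearity_tol: float = 1e-8,
    max_steps: int = 100,
) -> RegressionTrace:
    """Stepwise (forward entry, backward removal) OLS predictor selection.

    Entry: among candidates not in the model, the one with the smallest
    partial-F p-value enters if that p-value is below ``p_enter``.  Removal:
    any included predictor whose partial p-value exceeds ``p_remove`` is
    removed (worst first).  Candidates whose addition would make the design
    numerically singular (relative condition below ``collinearity_tol``) are
    skipped with a warning.  Iterates to a fixpoint; requires p_enter <
    p_remove so the procedure cannot cycle.
    """
    if not p_enter < p_remove:
        raise ValueError("p_enter must be below p_remove")
    if target is None:
        if table.severity_score is None:
            raise ValueError("table has no severity scores and no target was given")
        target = table.severity_score
    target = np.asarray(target, dtype=float)
    keep = np.isfinite(target)
    y = target[keep]
    names = list(table.marker_names) if candidates is None else list(candidates)
    cols = {m: table.values[keep, table.marker_names.index(m)] for m in names}
    n = len(y)
    if n <= len(names):
        warnings.warn(
            "fewer subjects than candidate predictors; stepwise selection can "
            "only ever include a subset",
            stacklevel=2,
        )
    included: list[str] = []
    steps: list[StepModel] = []

    def record(action: str, changed: str, change_p: float) -> None:
        X = np.column_stack([cols[m] for m in included])
        fit = _fit(X, y)
        r2 = float(fit.rsquared)
        steps.append(
            StepModel(
                action=action,
                changed=changed,
                change_p=float(change_p),
                predictors=tuple(included),
                R=float(np.sqrt(max(r2, 0.0))),
                r_squared=r2,
                adj_r_squared=float(fit.rsquared_adj),
                F=float(fit.fvalue),
                p=float(fit.f_pvalue),
                coefficients={
                    m: float(b) for m, b in zip(["const"] + included, fit.params)
                },
            )
        )

    for _ in range(max_steps):
        changed = False
        # forward entry
        best_p, best_m = None, None
        for m in names:
            if m in included:
                continue
            if n <= len(included) + 2:
                break  # no residual degrees of freedom for another predictor
            X = np.column_stack([cols[q] for q in included + [m]])
            s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
            if s[-1] < collinearity_tol * s[0]:
                warnings.warn(
                    f"skipping collinear candidate {m!r}", stacklevel=2
                )
                continue
            fit = _fit(X, y)
            p_m = float(fit.pvalues[-1])
            if best_p is None or p_m < best_p:
                best_p, best_m = p_m, m
        if best_m is not None and best_p < p_enter:
            included.append(best_m)
            record("add", best_m, best_p)
            changed = True
        # backward removal
        while len(included) > 1:
            X = np.column_stack([cols[q] for q in included])
            fit = _fit(X, y)
            pvals = fit.pvalues[1:]  # skip intercept
            worst = int(np.argmax(pvals))
            if float(pvals[worst]) <= p_remove:
                break
            removed = included.pop(worst)
            record("remove", removed, float(pvals[worst]))
            changed = True
        if not changed:
            break
    return RegressionTrace(steps=steps, p_enter=p_enter, p_remove=p_remove, n=n)
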