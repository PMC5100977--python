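"""Canberra distances, classical MDS, and neighbor-joining trees over subjects.

The dissimilarity between two subjects' marker profiles X and Y is the
averaged Canberra distance

    D(X, Y) = (1/n) * sum_i |X_i - Y_i| / (|X_i| + |Y_i|)

with terms where both coordinates are zero contributing 0.  Each term is at
most 1 for non-negative data, so D lies in [0, 1]; the measure is
scale-invariant per marker, which is why it is computed on raw (unscaled)
concentrations.  On positive vectors it is a true metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .core_data import BiomarkerTable, Tree

__all__ = [
    "canberra_distance",
    "distance_matrix",
    "MDSOrdination",
    "classical_mds",
    "neighbor_joining",
]


def canberra_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Averaged Canberra distance between two marker vectors.

    Both vectors must have the same length; a warning is issued for negative
    entries (concentrations are expected to be non-negative, and the metric
    axioms are only guaranteed on the non-negative orthant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty vectors")
    if (x < 0).any() or (y < 0).any():
        warnings.warn(
            "negative entries; Canberra distance assumes non-negative data",
            stacklevel=2,
        )
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(terms.mean())


def distance_matrix(table: BiomarkerTable) -> DistanceMatrix:
    """Pairwise averaged Canberra distances on raw marker values.

    Distances are deliberately computed on unstandardised concentrations:
    the per-marker normalisation is built into the Canberra terms.
    """
    X = table.values
    if (X < 0).any():
        warnings.warn(
            "negative marker values; Canberra distance assumes non-negative data",
            stacklevel=2,
        )
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i] - X[i + 1 :])
        den = np.abs(X[i]) + np.abs(X[i + 1 :])
        terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        out[i, i + 1 :] = terms.mean(axis=1)
    out += out.T
    return DistanceMatrix(out, ids=table.subject_ids)


@dataclass
class MDSOrdination:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # subjects x dims
    eigenvalues: np.ndarray  # all eigenvalues of the centered matrix, desc


def classical_mds(dm: DistanceMatrix, dims: int = 2) -> MDSOrdination:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix and takes the top ``dims``
    eigenpairs.  Axes are ordered by eigenvalue; negative eigenvalues (the
    signature of a non-Euclidean dissimilarity such as Canberra) are dropped
    with a warning, and ``dims`` is truncated to the number of positive
    eigenvalues if necessary.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    D = dm.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    n_pos = int((eigvals > tol).sum())
    if (eigvals < -tol).any():
        warnings.warn(
            "negative eigenvalues in classical MDS (non-Euclidean input); "
            "dropping them",
            stacklevel=2,
        )
    if dims > n_pos:
        warnings.warn(
            f"requested {dims} dimensions but only {n_pos} positive "
            "eigenvalues; truncating",
            stacklevel=2,
        )
        dims = n_pos
    coords = eigvecs[:, :dims] * np.sqrt(eigvals[:dims])
    df = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"MDS{k + 1}" for k in range(dims)]
    )
    df.index.name = "subject_id"
    return MDSOrdination(coordinates=df, eigenvalues=eigvals)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining (Saitou-Nei) tree from a subject distance matrix.

    Iteratively joins the pair minimising the Q-criterion and computes branch
    lengths from the three-point formulas; negative branch lengths are
    clamped to zero with the deficit moved to the sister branch.  Exactly
    recovers any additive (tree-realizable) distance matrix.  Requires at
    least 3 subjects.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 subjects")
    return nj(dm, neg_as_zero=True)
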