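"""Library-based leave-one-out KNN identification of subjects.

A *library* is a labelled reference set of subjects partitioned into *units*
(e.g. autistic/control, or severe/mild-moderate).  An unknown subject is
compared to every library entry by averaged Canberra distance on raw marker
values; its k most similar entries are found and it is assigned to the unit
holding the most of them.  The assignment score

    score = 100 * (matches in the assigned unit) / k

is 100 when the top-k neighbors are unanimous and 50 when, in a two-unit
library, they split evenly — higher scores mean higher confidence.  k must
not exceed the size of the smallest unit.  Leave-one-out evaluation removes
each subject in turn, identifies it against the remainder, and reports
per-unit and overall correct-assignment rates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import BiomarkerTable

__all__ = [
    "MARKER_SETS",
    "Library",
    "IdentificationResult",
    "LOOResult",
    "identify_subject",
    "loo_evaluate",
]

#: Named marker panels.  Sets 1 and 2 are the two assay panels; set 3 is the
#: six severity-correlated markers (the five set-2 lipid mediators that track
#: sensory scores plus PE from set 1); set 4 is the best three-predictor
#: combination from stepwise regression.
MARKER_SETS: dict[str, tuple[str, ...]] = {
    "set1": ("PE", "PS", "PC", "MAP2K1", "IL-10", "IL-12", "NF-kB"),
    "set2": ("PGE2", "PGE2-EP2", "mPGES-1", "cPLA2", "8-isoprostane", "COX-2"),
    "set3": ("PGE2", "mPGES-1", "cPLA2", "8-isoprostane", "COX-2", "PE"),
    "set4": ("PGE2", "mPGES-1", "PE"),
}


@dataclass
class Library:
    """Reference subjects grouped into units over a chosen marker panel."""

    subject_ids: list[str]
    values: np.ndarray  # entries x markers, raw concentrations
    unit: np.ndarray  # per-entry unit label
    markers: list[str]
    marker_set: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.unit = np.asarray([str(u) for u in self.unit], dtype=object)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.subject_ids):
            raise ValueError("values must be an entries x markers matrix")
        if self.values.shape[1] != len(self.markers) or not self.markers:
            raise ValueError("marker list must be non-empty and match values")
        if len(self.unit) != len(self.subject_ids):
            raise ValueError("one unit label per entry required")
        if len(self.subject_ids) == 0:
            raise ValueError("empty library")
        counts = Counter(self.unit)
        small = [u for u, c in counts.items() if c < 2]
        if small:
            raise ValueError(f"units with fewer than 2 entries: {small}")

    @classmethod
    def from_table(
        cls,
        table: BiomarkerTable,
        marker_set: str = "custom",
        markers: list[str] | None = None,
        unit_labels: np.ndarray | None = None,
    ) -> "Library":
        """Build a library from a table.

        ``marker_set`` may name one of :data:`MARKER_SETS` (its markers must
        all be present in the table) or be ``"custom"`` with an explicit
        ``markers`` list (default: all table markers).  ``unit_labels``
        default to the table's group labels.
        """
        if marker_set in MARKER_SETS:
            markers = list(MARKER_SETS[marker_set])
        elif markers is None:
            markers = list(table.marker_names)
        sub = table.select(markers=markers)
        units = table.group if unit_labels is None else np.asarray(unit_labels)
        return cls(
            subject_ids=list(sub.subject_ids),
            values=sub.values,
            unit=units,
            markers=markers,
            marker_set=marker_set,
        )

    @property
    def unit_sizes(self) -> dict[str, int]:
        return dict(Counter(self.unit))

    @property
    def smallest_unit_size(self) -> int:
        return min(self.unit_sizes.values())


@dataclass
class IdentificationResult:
    """Outcome of matching one subject against a library."""

    subject_id: str
    assigned_unit: str
    true_unit: str | None
    score: float  # 0-100, percent of top-k neighbors in the assigned unit
    k: int
    neighbor_ids: list[str]
    neighbor_distances: np.ndarray

    @property
    def correct(self) -> bool | None:
        if self.true_unit is None:
            return None
        return self.assigned_unit == self.true_unit


def _canberra_to_all(x: np.ndarray, M: np.ndarray) -> np.ndarray:
    num = np.abs(x - M)
    den = np.abs(x) + np.abs(M)
    terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return terms.mean(axis=1)


def _vote(top_units: np.ndarray, k: int) -> tuple[str, float]:
    """Modal-unit assignment over the k nearest entries with the tie policy:
    count ties go to the unit of the single nearest entry, residual ties to
    the alphabetically first unit label."""
    counts = Counter(top_units)
    best = max(counts.values())
    tied = sorted(u for u, c in counts.items() if c == best)
    if len(tied) == 1:
        assigned = tied[0]
    else:
        nearest_unit = top_units[0]
        assigned = nearest_unit if nearest_unit in tied else tied[0]
    return str(assigned), 100.0 * counts[assigned] / k


def identify_subject(
    subject: np.ndarray,
    library: Library,
    k: int | None = None,
    subject_id: str = "?",
    true_unit: str | None = None,
) -> IdentificationResult:
    """Assign a marker vector to the library unit of its k nearest entries.

    ``k`` defaults to the smallest unit size (its upper bound).  Neighbors
    are ordered by (distance, entry index) — a stable rule that makes
    distance ties deterministic.  A tie in neighbor counts between units is
    broken in favour of the unit containing the single nearest entry, then
    by unit label order.
    """
    if k is None:
        k = library.smallest_unit_size
    if not 1 <= k <= library.smallest_unit_size:
        raise ValueError(
            f"k={k} must be between 1 and the smallest unit size "
            f"({library.smallest_unit_size})"
        )
    x = np.asarray(subject, dtype=float)
    if x.shape != (len(library.markers),):
        raise ValueError(
            f"subject vector length {x.shape} does not match library markers "
            f"({len(library.markers)})"
        )
    d = _canberra_to_all(x, library.values)
    order = np.argsort(d, kind="stable")[:k]
    assigned, score = _vote(library.unit[order], k)
    return IdentificationResult(
        subject_id=subject_id,
        assigned_unit=assigned,
        true_unit=true_unit,
        score=score,
        k=k,
        neighbor_ids=[library.subject_ids[i] for i in order],
        neighbor_distances=d[order],
    )


@dataclass
class LOOResult:
    """Leave-one-out identification rates for a library."""

    per_unit_rate: dict[str, float]  # percent correct within each unit
    overall_rate: float  # percent correct over all subjects
    k: int
    marker_set: str
    results: list[IdentificationResult]

    def scores(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.results],
                "true_unit": [r.true_unit for r in self.results],
                "assigned_unit": [r.assigned_unit for r in self.results],
                "score": [r.score for r in self.results],
                "correct": [r.correct for r in self.results],
            }
        ).set_index("subject_id")


def loo_evaluate(library: Library, k: int | None = None) -> LOOResult:
    """Leave-one-out evaluation of library identification.

    Each subject is removed from the library and identified against the
    remainder, so the largest feasible ``k`` is one less than the smallest
    unit size; that maximum is the default.
    """
    max_k = library.smallest_unit_size - 1
    if max_k < 1:
        raise ValueError("every unit needs at least 2 entries for leave-one-out")
    if k is None:
        k = max_k
    if not 1 <= k <= max_k:
        raise ValueError(
            f"k={k} infeasible for leave-one-out; maximum feasible k is {max_k}"
        )
    # precompute all pairwise distances once; each subject is then matched
    # against every other entry (its own row/column excluded)
    n = len(library.subject_ids)
    D = np.empty((n, n))
    for i in range(n):
        D[i] = _canberra_to_all(library.values[i], library.values)
    results = []
    for i, sid in enumerate(library.subject_ids):
        others = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        order = others[np.argsort(D[i, others], kind="stable")][:k]
        assigned, score = _vote(library.unit[order], k)
        results.append(
            IdentificationResult(
                subject_id=sid,
                assigned_unit=assigned,
                true_unit=str(library.unit[i]),
                score=score,
                k=k,
                neighbor_ids=[library.subject_ids[j] for j in order],
                neighbor_distances=D[i, order],
            )
        )
    per_unit: dict[str, float] = {}
    for u, size in library.unit_sizes.items():
        correct = sum(1 for r in results if r.true_unit == u and r.correct)
        per_unit[u] = 100.0 * correct / size
    overall = 100.0 * sum(1 for r in results if r.correct) / len(results)
    return LOOResult(
        per_unit_rate=per_unit,
        overall_rate=overall,
        k=k,
        marker_set=library.marker_set,
        results=results,
    )
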