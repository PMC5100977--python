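"""Core domain types and delimited-table / Newick I/O.

A study cohort is a subjects x markers matrix of plasma concentrations with a
group label per subject (case/control, or a sensory-severity class) and an
optional Short Sensory Profile (SSP) total score.  The SSP is a 38-item
caregiver questionnaire whose total ranges from 38 to 190 points; lower scores
indicate more impaired sensory processing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "SSP_MIN",
    "SSP_MAX",
    "SeverityThresholds",
    "BiomarkerTable",
    "Tree",
    "classify_severity",
    "severity_group",
    "read_biomarker_table",
    "write_biomarker_table",
    "read_newick",
    "write_newick",
]

#: Instrument range of the SSP total score, in points.
SSP_MIN = 38.0
SSP_MAX = 190.0

#: A subject dendrogram; leaf names are subject ids, branch lengths are
#: Canberra distance units.  scikit-bio's TreeNode is the concrete type.
Tree = TreeNode


@dataclass(frozen=True)
class SeverityThresholds:
    """Cutoffs (SSP points) mapping a total score to a severity class.

    Two conventions exist for the severe/mild-moderate boundary: the
    instrument manual places severe below 142, while case-control analyses
    commonly dichotomise autistic subjects at <=145.  The default uses 145;
    pass ``severe_cutoff=141`` for the manual's convention.
    """

    severe_cutoff: float = 145.0
    typical_lower: float = 142.0
    typical_upper: float = 153.0

    def __post_init__(self) -> None:
        if not self.typical_lower < self.typical_upper:
            raise ValueError(
                "typical_lower must be strictly below typical_upper, got "
                f"{self.typical_lower} >= {self.typical_upper}"
            )
        if not (self.typical_lower - 10 <= self.severe_cutoff <= self.typical_upper):
            raise ValueError(
                f"severe_cutoff {self.severe_cutoff} outside "
                f"[{self.typical_lower - 10}, {self.typical_upper}]"
            )


def classify_severity(
    score: float, thresholds: SeverityThresholds = SeverityThresholds()
) -> str:
    """Map an SSP total score to ``severe``, ``mild_moderate`` or ``typical``.

    With default thresholds: score <= 145 -> severe; 145 < score < 153 ->
    mild_moderate; >= 153 -> typical.  Scores outside the instrument range
    [38, 190] raise ``ValueError``.
    """
    if not np.isfinite(score) or not (SSP_MIN <= score <= SSP_MAX):
        raise ValueError(
            f"SSP score {score!r} outside instrument range [{SSP_MIN}, {SSP_MAX}]"
        )
    if score <= thresholds.severe_cutoff:
        return "severe"
    if score < thresholds.typical_upper:
        return "mild_moderate"
    return "typical"


def severity_group(
    score: float, thresholds: SeverityThresholds = SeverityThresholds()
) -> str:
    """Dichotomous severity split used for group comparisons.

    Case-control style analyses of autistic subjects dichotomise at the
    severe cutoff: score <= cutoff -> ``severe``, anything above (including
    typical-range scores) -> ``mild_moderate``.
    """
    return "severe" if classify_severity(score, thresholds) == "severe" else "mild_moderate"


@dataclass
class BiomarkerTable:
    """A subjects x markers concentration matrix with group labels.

    Parameters
    ----------
    subject_ids
        Unique subject identifiers, one per row.
    marker_names
        Unique marker names, one per column, order preserved from input.
    values
        Real matrix of plasma concentrations (assay units).  No missing or
        non-finite entries are allowed.
    group
        Per-subject categorical label (e.g. ``autistic``/``control``).
    severity_score
        Optional per-subject SSP total in points.  ``nan`` marks subjects
        without an SSP assessment (typically controls); finite entries must
        lie in [38, 190].
    """

    subject_ids: list[str]
    marker_names: list[str]
    values: np.ndarray
    group: np.ndarray
    severity_score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.marker_names = [str(m) for m in self.marker_names]
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        if self.severity_score is not None:
            self.severity_score = np.asarray(self.severity_score, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n, p = self.values.shape if self.values.ndim == 2 else (0, 0)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x markers matrix")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match values rows")
        if len(self.marker_names) != p:
            raise ValueError("marker_names length does not match values columns")
        if len(set(self.subject_ids)) != n:
            dupes = sorted(
                {s for s in self.subject_ids if self.subject_ids.count(s) > 1}
            )
            raise ValueError(f"duplicate subject ids: {dupes}")
        if len(set(self.marker_names)) != p:
            raise ValueError("duplicate marker names")
        if n < 3:
            raise ValueError(f"need at least 3 subjects, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 markers, got {p}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("marker values contain missing or non-finite entries")
        if len(self.group) != n:
            raise ValueError("group length does not match subject count")
        if any(g is None or str(g) == "" for g in self.group):
            raise ValueError("every subject needs a group label")
        if self.severity_score is not None:
            if len(self.severity_score) != n:
                raise ValueError("severity_score length does not match subjects")
            finite = self.severity_score[np.isfinite(self.severity_score)]
            if finite.size and (finite.min() < SSP_MIN or finite.max() > SSP_MAX):
                raise ValueError(
                    f"severity scores outside instrument range [{SSP_MIN}, {SSP_MAX}]"
                )
        if (self.values <= 0).any():
            warnings.warn(
                "non-positive marker values present; Canberra distances assume "
                "positive concentrations",
                stacklevel=3,
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(str(g), None)
        return list(seen)

    def marker(self, name: str) -> np.ndarray:
        """Column of values for one marker."""
        try:
            j = self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None
        return self.values[:, j]

    def select(
        self,
        subjects: Sequence[str] | np.ndarray | None = None,
        markers: Iterable[str] | None = None,
    ) -> "BiomarkerTable":
        """Subset by subject ids (or a boolean mask) and/or marker names."""
        if subjects is None:
            row_idx = np.arange(self.n_subjects)
        elif isinstance(subjects, np.ndarray) and subjects.dtype == bool:
            row_idx = np.flatnonzero(subjects)
        else:
            pos = {s: i for i, s in enumerate(self.subject_ids)}
            row_idx = np.array([pos[str(s)] for s in subjects], dtype=int)
        if markers is None:
            col_idx = np.arange(self.n_markers)
        else:
            mpos = {m: j for j, m in enumerate(self.marker_names)}
            missing = [m for m in markers if m not in mpos]
            if missing:
                raise KeyError(f"unknown markers: {missing}")
            col_idx = np.array([mpos[m] for m in markers], dtype=int)
        return BiomarkerTable(
            subject_ids=[self.subject_ids[i] for i in row_idx],
            marker_names=[self.marker_names[j] for j in col_idx],
            values=self.values[np.ix_(row_idx, col_idx)],
            group=self.group[row_idx],
            severity_score=None
            if self.severity_score is None
            else self.severity_score[row_idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.marker_names
        )
        df.index.name = "subject_id"
        df["group"] = [str(g) for g in self.group]
        if self.severity_score is not None:
            df["severity_score"] = self.severity_score
        return df


def read_biomarker_table(
    path: str | Path,
    group_column: str = "group",
    severity_column: str | None = None,
    delimiter: str = ",",
) -> BiomarkerTable:
    """Read a delimited subjects x markers table.

    The file must have a header row; the first column holds subject ids, one
    row per subject.  All columns other than the group and optional severity
    column are treated as numeric marker columns (order preserved).

    Raises
    ------
    ValueError
        On an empty file, duplicate subject ids, a non-numeric marker cell
        (the offending row and column are named) or a missing group column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=object)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no subjects")
    subject_ids = [str(s) for s in df.index]
    if len(set(subject_ids)) != len(subject_ids):
        dupes = sorted({s for s in subject_ids if subject_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate subject ids: {dupes}")
    if group_column not in df.columns:
        raise ValueError(f"{path}: group column {group_column!r} not found")
    if severity_column is not None and severity_column not in df.columns:
        raise ValueError(f"{path}: severity column {severity_column!r} not found")
    if severity_column is None and "severity_score" in df.columns:
        severity_column = "severity_score"  # conventional name, auto-detected
    special = {group_column} | ({severity_column} if severity_column else set())
    marker_names = [c for c in df.columns if c not in special]
    values = np.empty((len(subject_ids), len(marker_names)))
    for j, name in enumerate(marker_names):
        col = pd.to_numeric(df[name], errors="coerce")
        bad = col.index[col.isna() & df[name].notna()]
        if len(bad) or col.isna().any():
            row = (bad if len(bad) else col.index[col.isna()])[0]
            raise ValueError(
                f"{path}: non-numeric or missing value in marker column "
                f"{name!r}, subject {row!r}"
            )
        values[:, j] = col.to_numpy(dtype=float)
    severity = None
    if severity_column is not None:
        severity = pd.to_numeric(df[severity_column], errors="coerce").to_numpy(
            dtype=float
        )
    return BiomarkerTable(
        subject_ids=subject_ids,
        marker_names=marker_names,
        values=values,
        group=df[group_column].to_numpy(dtype=object),
        severity_score=severity,
    )


def write_biomarker_table(
    table: BiomarkerTable, path: str | Path, delimiter: str = ","
) -> None:
    """Write a table in the layout :func:`read_biomarker_table` reads."""
    table.to_dataframe().to_csv(path, sep=delimiter)


def write_newick(tree: Tree, path: str | Path) -> None:
    """Serialize a subject dendrogram to a Newick file with branch lengths."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> Tree:
    """Parse a Newick file back into a tree."""
    return TreeNode.read(str(path), format="newick")
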