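"""End-to-end study workflow and structured reporting.

Runs, in order: factorability diagnostics (Bartlett, KMO) -> PCA with
parallel-analysis component retention -> Canberra distances with classical
MDS and a neighbor-joining dendrogram -> severity classification and MANOVA
of severity groups -> leave-one-out library identification (case/control and
severity, for every named marker set available in the table) -> marker-
severity correlations and stepwise regression.  A stage that cannot run on
the given inputs is recorded as skipped with its reason; the remaining stages
are still attempted.  Reports are deterministic given inputs, config and
seed, and serialize to JSON.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__ as _version
from .core_data import (
    BiomarkerTable,
    SeverityThresholds,
    severity_group,
)
from .distance_geometry import classical_mds, distance_matrix, neighbor_joining
from .library_identification import MARKER_SETS, Library, loo_evaluate
from .multivariate import (
    bartlett_sphericity,
    kmo,
    manova_wilks,
    parallel_analysis,
    run_pca,
    variable_contributions,
)
from .severity_association import correlate_markers, stepwise_regression

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "render_report"]

logger = logging.getLogger("plasmapanel")


@dataclass
class AnalysisConfig:
    """Thresholds and knobs of the full workflow, one committed object."""

    severity_thresholds: SeverityThresholds = field(default_factory=SeverityThresholds)
    matrix_mode: str = "covariance_normalized"
    n_permutations: int = 1000
    mds_dims: int = 2
    k: int | None = None  # None: largest feasible leave-one-out k
    marker_sets: tuple[str, ...] = ("set1", "set2", "set3", "set4")
    p_enter: float = 0.05
    p_remove: float = 0.10
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["marker_sets"] = list(self.marker_sets)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("severity_thresholds", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "marker_sets"})
        if "marker_sets" in raw:
            cfg.marker_sets = tuple(raw["marker_sets"])
        if thr:
            cfg.severity_thresholds = SeverityThresholds(**thr)
        return cfg


@dataclass
class AnalysisReport:
    """Per-stage results of one full analysis, JSON-serializable."""

    stages: dict[str, Any]
    skipped: dict[str, str]
    provenance: dict[str, Any]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "stages": self.stages,
                "skipped": self.skipped,
                "provenance": self.provenance,
            },
            indent=indent,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        raw = json.loads(text)
        return cls(
            stages=raw["stages"], skipped=raw["skipped"], provenance=raw["provenance"]
        )


def _table_hash(table: BiomarkerTable) -> str:
    h = hashlib.sha256()
    h.update(",".join(table.subject_ids).encode())
    h.update(",".join(table.marker_names).encode())
    h.update(np.ascontiguousarray(table.values).tobytes())
    h.update(",".join(str(g) for g in table.group).encode())
    if table.severity_score is not None:
        h.update(np.ascontiguousarray(table.severity_score).tobytes())
    return h.hexdigest()[:16]


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_full_analysis(
    case_control_table: BiomarkerTable,
    severity_table: BiomarkerTable | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Execute the whole workflow on a case/control cohort.

    ``severity_table`` holds the (sub)cohort with SSP scores for the
    severity analyses; when omitted, the case subjects of the main table are
    used, provided severity scores are present.  Stage failures are recorded
    under ``skipped`` and do not abort later stages.
    """
    cfg = config or AnalysisConfig()
    table = case_control_table
    stages: dict[str, Any] = {}
    skipped: dict[str, str] = {}

    def stage(name: str, fn) -> Any:
        try:
            out = fn()
            stages[name] = out
            logger.info("stage %s: ok", name)
            return out
        except Exception as exc:  # record and continue
            skipped[name] = str(exc)
            logger.warning("stage %s skipped: %s", name, exc)
            return None

    # -- diagnostics -------------------------------------------------------
    def _diagnostics():
        stat, p = bartlett_sphericity(table)
        overall, per = kmo(table)
        return {
            "bartlett_chi2": stat,
            "bartlett_p": p,
            "kmo_overall": overall,
            "kmo_per_marker": per.to_dict(),
        }

    stage("diagnostics", _diagnostics)

    # -- PCA + parallel analysis ------------------------------------------
    def _pca():
        res = run_pca(table, matrix_mode=cfg.matrix_mode)
        pa = parallel_analysis(
            table,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed,
            matrix_mode=cfg.matrix_mode,
        )
        return {
            "eigenvalues": res.eigenvalues,
            "pct_variance": res.pct_variance,
            "contributions": {
                c: res.contributions[c].to_dict() for c in res.contributions.columns
            },
            "top_markers_pc1": list(variable_contributions(res, 0).index[:4]),
            "parallel_analysis": {
                "raw_eigenvalues": pa.raw_eigenvalues,
                "simulated_p50": pa.simulated_p50,
                "simulated_p95": pa.simulated_p95,
                "n_significant": pa.n_significant,
                "n_permutations": pa.n_permutations,
            },
        }

    stage("pca", _pca)

    # -- distances, MDS, tree ---------------------------------------------
    def _geometry():
        dm = distance_matrix(table)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # Canberra embeddings are non-Euclidean
            ord_ = classical_mds(dm, dims=cfg.mds_dims)
        tree = neighbor_joining(dm)
        buf = io.StringIO()
        tree.write(buf, format="newick")
        return {
            "mds_coordinates": {
                sid: row.tolist()
                for sid, row in zip(
                    ord_.coordinates.index, ord_.coordinates.to_numpy()
                )
            },
            "mds_eigenvalues": ord_.eigenvalues,
            "newick": buf.getvalue().strip(),
        }

    stage("geometry", _geometry)

    # -- severity classes + MANOVA ----------------------------------------
    sev_table = severity_table if severity_table is not None else table
    case_mask = None
    sev_classes = None

    def _severity_groups():
        nonlocal case_mask, sev_classes
        if sev_table.severity_score is None:
            raise ValueError("no severity scores available")
        case_mask = np.isfinite(sev_table.severity_score)
        if case_mask.sum() < 6:
            raise ValueError("too few subjects with severity scores")
        sev_classes = np.array(
            [
                severity_group(s, cfg.severity_thresholds)
                for s in sev_table.severity_score[case_mask]
            ],
            dtype=object,
        )
        counts = {
            u: int((sev_classes == u).sum()) for u in dict.fromkeys(sev_classes)
        }
        cases = sev_table.select(subjects=case_mask)
        mv = manova_wilks(cases, group_labels=sev_classes)
        return {
            "class_counts": counts,
            "wilks_lambda": mv.wilks_lambda,
            "F_multivariate": mv.F_multivariate,
            "p_multivariate": mv.p_multivariate,
            "univariate_p": mv.univariate["p"].to_dict(),
        }

    stage("severity_manova", _severity_groups)

    # -- MANOVA of case vs control ----------------------------------------
    def _group_manova():
        mv = manova_wilks(table)
        return {
            "wilks_lambda": mv.wilks_lambda,
            "F_multivariate": mv.F_multivariate,
            "p_multivariate": mv.p_multivariate,
        }

    stage("group_manova", _group_manova)

    # -- library identification -------------------------------------------
    def _loo_for(tbl: BiomarkerTable, units: np.ndarray, set_name: str):
        markers = (
            list(MARKER_SETS[set_name])
            if set_name in MARKER_SETS
            else list(tbl.marker_names)
        )
        missing = [m for m in markers if m not in tbl.marker_names]
        if missing:
            raise ValueError(f"markers unavailable in table: {missing}")
        lib = Library.from_table(
            tbl, marker_set=set_name, markers=markers, unit_labels=units
        )
        res = loo_evaluate(lib, k=cfg.k)
        return {
            "per_unit_rate": res.per_unit_rate,
            "overall_rate": res.overall_rate,
            "k": res.k,
            "mean_score": float(np.mean([r.score for r in res.results])),
        }

    def _identification():
        out: dict[str, Any] = {
            "case_control": _loo_for(table, table.group, "all_markers")
        }
        if sev_classes is not None:
            cases = sev_table.select(subjects=case_mask)
            out["severity"] = {}
            for set_name in cfg.marker_sets:
                try:
                    out["severity"][set_name] = _loo_for(
                        cases, sev_classes, set_name
                    )
                except ValueError as exc:
                    out["severity"][set_name] = {"skipped": str(exc)}
        return out

    stage("identification", _identification)

    # -- correlations + stepwise regression --------------------------------
    def _association():
        if sev_table.severity_score is None:
            raise ValueError("no severity scores available")
        cases = sev_table.select(subjects=np.isfinite(sev_table.severity_score))
        corr = correlate_markers(cases)
        trace = stepwise_regression(
            cases, p_enter=cfg.p_enter, p_remove=cfg.p_remove
        )
        return {
            "correlations": {
                m: dict(row) for m, row in corr.round(6).iterrows()
            },
            "stepwise": {
                "selected": list(trace.selected),
                "steps": [
                    {
                        "action": s.action,
                        "changed": s.changed,
                        "predictors": list(s.predictors),
                        "R": s.R,
                        "R2": s.r_squared,
                        "adj_R2": s.adj_r_squared,
                        "F": s.F,
                        "p": s.p,
                    }
                    for s in trace.steps
                ],
            },
        }

    stage("association", _association)

    provenance = {
        "input_hash": _table_hash(table),
        "severity_input_hash": None
        if severity_table is None
        else _table_hash(severity_table),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "version": _version,
    }
    return AnalysisReport(
        stages=_jsonify(stages), skipped=skipped, provenance=_jsonify(provenance)
    )


def render_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write a report to disk: JSON, plain-text summary, Newick, MDS CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    json_path = out_dir / "report.json"
    json_path.write_text(report.to_json())
    written.append(json_path)

    lines = ["plasmapanel analysis report", "=" * 30]
    st = report.stages
    if "diagnostics" in st:
        d = st["diagnostics"]
        lines += [
            "",
            "Factorability diagnostics",
            f"  KMO overall            {d['kmo_overall']:.3f}",
            f"  Bartlett chi2 (p)      {d['bartlett_chi2']:.1f} ({d['bartlett_p']:.2e})",
        ]
    if "pca" in st:
        p = st["pca"]
        pct = p["pct_variance"]
        lines += [
            "",
            "Principal components",
            "  " + "  ".join(f"PC{i + 1} {v:.1f}%" for i, v in enumerate(pct[:3])),
            f"  significant components {p['parallel_analysis']['n_significant']}",
        ]
    if "identification" in st:
        ident = st["identification"]
        lines += ["", "Leave-one-out library identification (% correct)"]
        cc = ident["case_control"]
        lines.append(
            f"  case/control (k={cc['k']}): overall {cc['overall_rate']:.0f}  "
            + "  ".join(f"{u} {r:.0f}" for u, r in cc["per_unit_rate"].items())
        )
        for set_name, res in ident.get("severity", {}).items():
            if "skipped" in res:
                lines.append(f"  severity {set_name}: skipped: {res['skipped']}")
            else:
                lines.append(
                    f"  severity {set_name} (k={res['k']}): overall "
                    f"{res['overall_rate']:.0f}  "
                    + "  ".join(
                        f"{u} {r:.0f}" for u, r in res["per_unit_rate"].items()
                    )
                )
    if "association" in st:
        sw = st["association"]["stepwise"]
        lines += ["", "Stepwise severity regression"]
        for s in sw["steps"]:
            lines.append(
                f"  {s['action']:6s} {s['changed']:14s} "
                f"R={s['R']:.3f} R2={s['R2']:.3f} adjR2={s['adj_R2']:.3f} "
                f"F={s['F']:.3f} p={s['p']:.3g}"
            )
        lines.append(f"  selected: {', '.join(sw['selected']) or '(none)'}")
    for name, reason in report.skipped.items():
        lines.append(f"skipped: {name}: {reason}")
    summary_path = out_dir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    written.append(summary_path)

    if "geometry" in st:
        nwk_path = out_dir / "tree.newick"
        nwk_path.write_text(st["geometry"]["newick"] + "\n")
        written.append(nwk_path)
        coords = st["geometry"]["mds_coordinates"]
        csv_path = out_dir / "mds_coordinates.csv"
        with open(csv_path, "w") as fh:
            dims = len(next(iter(coords.values())))
            fh.write("subject_id," + ",".join(f"MDS{i + 1}" for i in range(dims)) + "\n")
            for sid, row in coords.items():
                fh.write(sid + "," + ",".join(f"{v:.10g}" for v in row) + "\n")
        written.append(csv_path)
    return written
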