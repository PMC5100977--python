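"""Synthetic cohort generator.

Emulates the statistical structure of a two-group plasma-biomarker study: a
case and a control group separated by a large mean shift on every marker, a
single shared latent factor inducing positive inter-marker correlation within
each group, and (for case subjects only) a continuous sensory-severity score
linearly and negatively driven by a small subset of markers.

The generative model for subject *i*, marker *j* is

    x_ij = mu_{g(i), j} + lambda_j * f_i + eps_ij

with ``f_i ~ N(0, 1)`` one latent draw per subject and ``eps_ij ~ N(0,
sigma_j)`` independent residual noise.  Positivity of concentrations is
obtained by construction (group means several total standard deviations above
zero), not by truncation, so Gaussian theory applies exactly to the generated
values.  Case subjects additionally receive an SSP total

    s_i = alpha + sum_j beta_j * x_ij + eta_i,    eta_i ~ N(0, tau)

clipped to the instrument range [38, 190]; control subjects have no SSP
score, mirroring the usual design in which only patients receive the sensory
assessment.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .core_data import SSP_MAX, SSP_MIN, BiomarkerTable

__all__ = [
    "SET1_MARKERS",
    "SET2_MARKERS",
    "CohortConfig",
    "generate_cohort",
    "study_like_config",
    "population_r2",
]

#: Panel 1: membrane phospholipids, a MAPK-pathway kinase, two interleukins
#: and a transcription factor.
SET1_MARKERS = ("PE", "PS", "PC", "MAP2K1", "IL-10", "IL-12", "NF-kB")
#: Panel 2: the COX-2/PGE2 lipid-signalling axis plus an oxidative-stress
#: marker.
SET2_MARKERS = ("PGE2", "PGE2-EP2", "mPGES-1", "cPLA2", "8-isoprostane", "COX-2")


@dataclass
class CohortConfig:
    """Parameters of the one-factor two-group generative model.

    All marker-level fields are per-marker sequences in the order of
    ``marker_names``; units are arbitrary assay units for marker quantities
    and SSP points for severity quantities.
    """

    n_case: int
    n_control: int
    marker_names: tuple[str, ...]
    case_means: tuple[float, ...]
    control_means: tuple[float, ...]
    shared_factor_loading: tuple[float, ...]
    noise_sd: tuple[float, ...]
    severity_intercept: float
    severity_coefficients: tuple[float, ...]
    severity_noise_sd: float
    seed: int = 0
    case_label: str = "autistic"
    control_label: str = "control"

    def __post_init__(self) -> None:
        p = len(self.marker_names)
        self.marker_names = tuple(str(m) for m in self.marker_names)
        for name in (
            "case_means",
            "control_means",
            "shared_factor_loading",
            "noise_sd",
            "severity_coefficients",
        ):
            value = tuple(float(v) for v in getattr(self, name))
            if len(value) != p:
                raise ValueError(f"{name} must have one entry per marker ({p})")
            setattr(self, name, value)
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 subjects")
        if any(s <= 0 for s in self.noise_sd):
            raise ValueError("noise_sd entries must be positive")
        if self.severity_noise_sd <= 0:
            raise ValueError("severity_noise_sd must be positive")

    # -- (de)serialisation for the CLI ------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def case_covariance(self) -> np.ndarray:
        """Population covariance of the markers within the case group."""
        lam = np.asarray(self.shared_factor_loading)
        sig = np.asarray(self.noise_sd)
        return np.outer(lam, lam) + np.diag(sig**2)


def population_r2(config: CohortConfig) -> float:
    """Closed-form population R-squared of severity on all markers.

    With ``s = alpha + beta' x + eta`` and ``Var(x) = Sigma`` within the case
    group, the severity variance explained by the markers is ``beta' Sigma
    beta`` and ``R^2 = beta' Sigma beta / (beta' Sigma beta + tau^2)``.
    Clipping to the SSP range is ignored (the default configurations keep
    scores many standard deviations inside the range).
    """
    beta = np.asarray(config.severity_coefficients)
    if not beta.any():
        return 0.0
    signal = float(beta @ config.case_covariance() @ beta)
    return signal / (signal + config.severity_noise_sd**2)


def generate_cohort(config: CohortConfig) -> BiomarkerTable:
    """Draw one cohort from the configured model.

    The same seed always yields a bit-identical table.  Case subjects come
    first (ids ``A01..``), controls after (ids ``C01..``).  A warning is
    issued if more than 1% of the drawn marker values are non-positive,
    since downstream Canberra distances assume positive concentrations.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    p = len(config.marker_names)
    means = np.vstack(
        [
            np.tile(config.case_means, (config.n_case, 1)),
            np.tile(config.control_means, (config.n_control, 1)),
        ]
    )
    factor = rng.standard_normal(n)
    noise = rng.standard_normal((n, p)) * np.asarray(config.noise_sd)
    values = means + factor[:, None] * np.asarray(config.shared_factor_loading) + noise
    if (values <= 0).mean() > 0.01:
        warnings.warn(
            "more than 1% of generated marker values are non-positive; "
            "increase the group means relative to the total noise scale",
            stacklevel=2,
        )
    beta = np.asarray(config.severity_coefficients)
    severity = np.full(n, np.nan)
    eta = rng.standard_normal(config.n_case) * config.severity_noise_sd
    severity[: config.n_case] = np.clip(
        config.severity_intercept + values[: config.n_case] @ beta + eta,
        SSP_MIN,
        SSP_MAX,
    )
    width = len(str(max(config.n_case, config.n_control)))
    subject_ids = [f"A{i + 1:0{width}d}" for i in range(config.n_case)] + [
        f"C{i + 1:0{width}d}" for i in range(config.n_control)
    ]
    group = np.array(
        [config.case_label] * config.n_case + [config.control_label] * config.n_control,
        dtype=object,
    )
    return BiomarkerTable(
        subject_ids=subject_ids,
        marker_names=list(config.marker_names),
        values=values,
        group=group,
        severity_score=severity,
    )


def _noise_sd_for_r2(config_cov: np.ndarray, beta: np.ndarray, r2: float) -> float:
    """Severity noise SD giving population R^2 = ``r2`` for given betas."""
    signal = float(beta @ config_cov @ beta)
    return float(np.sqrt(signal * (1 - r2) / r2))


def study_like_config(set_id: int, seed: int = 0) -> CohortConfig:
    """Default study-shaped configuration for panel 1 or panel 2.

    Panel 1: 7 markers, 35 cases + 38 controls; a large case/control mean
    shift (18 assay units against a within-group SD of about 1) and a weak
    shared factor, so the pooled panel has one dominant component while the
    case-only sub-cohort is close to unstructured.  Severity depends weakly
    on PE alone (the only panel-1 marker with a severity association).

    Panel 2: 6 markers, 29 cases + 16 controls; same mean shift with a
    moderate shared factor, and severity driven by three lipid mediators
    (PGE2, mPGES-1, 8-isoprostane) with equal negative coefficients.  The
    severity noise is set in closed form so the population R^2 of severity
    on the three true predictors is 0.65.
    """
    if set_id == 1:
        markers = SET1_MARKERS
        p = len(markers)
        loading = (0.2,) * p
        noise = (1.0,) * p
        beta = tuple(-2.0 if m == "PE" else 0.0 for m in markers)
        cov = np.outer(loading, loading) + np.diag(np.square(noise))
        tau = _noise_sd_for_r2(cov, np.asarray(beta), 0.09)
        return CohortConfig(
            n_case=35,
            n_control=38,
            marker_names=markers,
            case_means=(30.0,) * p,
            control_means=(12.0,) * p,
            shared_factor_loading=loading,
            noise_sd=noise,
            severity_intercept=204.5,
            severity_coefficients=beta,
            severity_noise_sd=tau,
            seed=seed,
        )
    if set_id == 2:
        markers = SET2_MARKERS
        p = len(markers)
        loading = (0.2,) * p
        noise = (1.0,) * p
        truth = {"PGE2", "mPGES-1", "8-isoprostane"}
        beta = tuple(-2.0 if m in truth else 0.0 for m in markers)
        cov = np.outer(loading, loading) + np.diag(np.square(noise))
        tau = _noise_sd_for_r2(cov, np.asarray(beta), 0.65)
        return CohortConfig(
            n_case=29,
            n_control=16,
            marker_names=markers,
            case_means=(30.0,) * p,
            control_means=(12.0,) * p,
            shared_factor_loading=loading,
            noise_sd=noise,
            severity_intercept=324.5,
            severity_coefficients=beta,
            severity_noise_sd=tau,
            seed=seed,
        )
    raise ValueError(f"set_id must be 1 or 2, got {set_id!r}")
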