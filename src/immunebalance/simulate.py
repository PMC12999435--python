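"""Synthetic flow-cytometry cohort generation.

Percent-of-parent subset frequencies are simulated on the logit scale:
per-sample Gaussian draws around a subset-specific baseline (optionally
correlated within group), back-transformed through the inverse logit and
scaled to percent. This keeps every frequency strictly inside (0, 100) and
approximately preserves configured correlation targets.

A single latent severity variable in [0, 1], drawn per patient, couples the
cellular and clinical layers. Clinical domain probabilities increase with
severity. Cellular shifts keep their configured sign for every patient but
their magnitude is attenuated with severity (multiplier ``1 -
severity_attenuation * s``), emulating a cohort in which the clinically
severest patients — under treatment pressure and effector exhaustion — show
the least florid inflammatory expansion. That common axis with opposed
gradients is what makes the inverse coupling between the cellular
dysregulation score and the clinical z-score recoverable downstream while
the patient group as a whole stays shifted away from controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import (
    CONTROL,
    PATIENT,
    CohortDataset,
    CohortError,
    FOUR_DOMAIN,
)

# Baseline percent-of-parent locations for a realistic paediatric panel.
_DEFAULT_BASELINE_PERCENT = {
    "BCL6_T": 8.0,
    "ICOS_BCL6_T": 3.0,
    "CD8_CD25_T": 6.0,
    "Treg_FOXP3": 5.0,
    "Breg_transitional": 4.0,
    "Breg_memory": 10.0,
    "T_memory": 40.0,
    "T_IL17A": 2.0,
    "T_CCR6": 15.0,
    "CD8_HLADR": 12.0,
    "Plasmablasts": 3.0,
    "Tfh_CXCR5": 10.0,
}

# Signed logit-scale shifts applied to patients, scaled by latent severity.
# Signs: regulatory subsets and memory compartments contract, follicular-
# helper-like and activated CD8 subsets expand.
_DEFAULT_EFFECTS = {
    "Treg_FOXP3": -0.8,
    "Breg_transitional": -0.8,
    "Breg_memory": -0.6,
    "T_memory": -0.6,
    "BCL6_T": 0.8,
    "ICOS_BCL6_T": 0.8,
    "CD8_CD25_T": 0.8,
}

# Increasing affine maps severity -> Bernoulli probability, (intercept, slope).
_DEFAULT_LOADINGS = {
    "autoimmunity": (0.05, 0.85),
    "chronic_inflammation": (0.05, 0.80),
    "lymphoproliferation": (0.05, 0.70),
    "malignancy": (0.00, 0.35),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort.

    ``baseline_mean`` / ``baseline_sd`` are logit-scale locations and scales
    per subset; ``effect_sizes`` are signed logit shifts applied to patients,
    multiplied by each patient's latent severity. ``clinical_loadings`` map
    each domain to ``(intercept, slope)`` of an increasing affine severity ->
    probability function. ``correlation_structure`` optionally gives a full
    subset x subset correlation target matrix per group.
    """

    n_patients: int = 39
    n_controls: int = 17
    subset_names: tuple[str, ...] = tuple(_DEFAULT_BASELINE_PERCENT)
    baseline_mean: dict[str, float] = field(
        default_factory=lambda: {
            k: float(logit(v / 100.0)) for k, v in _DEFAULT_BASELINE_PERCENT.items()
        }
    )
    baseline_sd: dict[str, float] = field(
        default_factory=lambda: {k: 0.5 for k in _DEFAULT_BASELINE_PERCENT}
    )
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    severity_distribution: tuple[float, float] = (2.0, 2.0)  # Beta(a, b)
    severity_attenuation: float = 0.8  # cellular shift multiplier = 1 - att * s
    clinical_domains: tuple[str, ...] = FOUR_DOMAIN
    clinical_loadings: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LOADINGS)
    )
    correlation_structure: dict[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "subset_names", tuple(self.subset_names))
        object.__setattr__(self, "clinical_domains", tuple(self.clinical_domains))
        if self.n_patients < 2 or self.n_controls < 2:
            raise CohortError("need at least 2 patients and 2 controls")
        missing = set(self.effect_sizes) - set(self.subset_names)
        if missing:
            raise CohortError(f"effect_sizes name unknown subsets: {sorted(missing)}")
        for name in self.subset_names:
            if name not in self.baseline_mean or name not in self.baseline_sd:
                raise CohortError(f"subset {name!r} lacks baseline mean/sd")
            if self.baseline_sd[name] <= 0:
                raise CohortError(f"baseline_sd for {name!r} must be > 0")
        a, b = self.severity_distribution
        if a <= 0 or b <= 0:
            raise CohortError("severity Beta parameters must be positive")
        if not 0 <= self.severity_attenuation <= 1:
            raise CohortError("severity_attenuation must lie in [0, 1]")
        for dom in self.clinical_domains:
            if dom not in self.clinical_loadings:
                raise CohortError(f"domain {dom!r} lacks a clinical loading")
        if self.correlation_structure is not None:
            for group, mat in self.correlation_structure.items():
                if group not in (PATIENT, CONTROL):
                    raise CohortError(f"unknown group {group!r} in correlation structure")
                _validate_correlation(np.asarray(mat, dtype=float), len(self.subset_names))

    def scale_effects(self, factor: float) -> "SimulationConfig":
        """Return a config with all subset effect sizes multiplied by ``factor``."""
        return replace(
            self, effect_sizes={k: v * factor for k, v in self.effect_sizes.items()}
        )


def _validate_correlation(mat: np.ndarray, p: int) -> np.ndarray:
    if mat.shape != (p, p):
        raise CohortError(f"correlation matrix must be {p}x{p}, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise CohortError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise CohortError("correlation matrix needs a unit diagonal")
    if np.linalg.eigvalsh(mat).min() < 1e-10:
        raise CohortError("correlation target matrix is not positive definite")
    return mat


def _correlated_normals(
    rng: np.random.Generator, n: int, p: int, corr: np.ndarray | None
) -> np.ndarray:
    z = rng.standard_normal((n, p))
    if corr is None:
        return z
    return z @ np.linalg.cholesky(corr).T


def generate_clinical_features(
    severity: pd.Series,
    loadings: dict[str, tuple[float, float]],
    seed: int,
    domains: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Draw a binary clinical matrix from per-patient severity.

    Each domain is Bernoulli(intercept + slope * severity). Probabilities
    outside [0, 1] are a configuration error, not silently clipped.
    """
    sev = np.asarray(severity, dtype=float)
    if ((sev < 0) | (sev > 1)).any():
        raise CohortError("severity values must lie in [0, 1]")
    domains = tuple(domains) if domains is not None else tuple(loadings)
    rng = np.random.default_rng(seed)
    out = {}
    for dom in domains:
        intercept, slope = loadings[dom]
        p = intercept + slope * sev
        if ((p < 0) | (p > 1)).any():
            raise CohortError(f"domain {dom!r}: probability outside [0, 1]")
        out[dom] = (rng.random(len(sev)) < p).astype(int)
    return pd.DataFrame(out, index=severity.index)


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a deterministic synthetic cohort from ``config``.

    Patients get subset-specific logit shifts ``effect * (1 -
    severity_attenuation * severity_i)`` on top of the shared baseline;
    controls are drawn from the baseline alone.
    """
    names = list(config.subset_names)
    p = len(names)
    ss = np.random.SeedSequence(config.seed)
    seed_sev, seed_pat, seed_ctl, seed_clin = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )

    a, b = config.severity_distribution
    severity = np.random.default_rng(seed_sev).beta(a, b, size=config.n_patients)

    mu = np.array([config.baseline_mean[n] for n in names])
    sd = np.array([config.baseline_sd[n] for n in names])
    eff = np.array([config.effect_sizes.get(n, 0.0) for n in names])

    corr = config.correlation_structure or {}
    z_pat = _correlated_normals(
        np.random.default_rng(seed_pat), config.n_patients, p, corr.get(PATIENT)
    )
    z_ctl = _correlated_normals(
        np.random.default_rng(seed_ctl), config.n_controls, p, corr.get(CONTROL)
    )

    shift_scale = 1.0 - config.severity_attenuation * severity
    logit_pat = mu + shift_scale[:, None] * eff + z_pat * sd
    logit_ctl = mu + z_ctl * sd

    # |logit| capped so the inverse logit stays strictly inside (0, 1) in float64
    logits = np.clip(np.vstack([logit_pat, logit_ctl]), -30.0, 30.0)
    freqs = 100.0 * expit(logits)

    ids = [f"P{i + 1:03d}" for i in range(config.n_patients)] + [
        f"C{i + 1:03d}" for i in range(config.n_controls)
    ]
    index = pd.Index(ids, name="sample_id")
    subset_matrix = pd.DataFrame(freqs, index=index, columns=names)
    groups = pd.Series(
        [PATIENT] * config.n_patients + [CONTROL] * config.n_controls,
        index=index,
        name="group",
    )
    sev_series = pd.Series(severity, index=index[: config.n_patients], name="severity")
    clinical = generate_clinical_features(
        sev_series, config.clinical_loadings, seed_clin, domains=config.clinical_domains
    )
    return CohortDataset(
        subset_matrix=subset_matrix,
        group_labels=groups,
        clinical_matrix=clinical,
        latent_severity=sev_series,
    )


def plant_correlation_flip(
    config: SimulationConfig,
    pair: tuple[str, str],
    r_control: float,
    r_patient: float,
) -> SimulationConfig:
    """Return a config whose cohorts carry a planted correlation change.

    The named subset pair is given within-group logit-scale correlation
    ``r_control`` in controls and ``r_patient`` in patients, on top of any
    correlation structure already present. Used to construct fixtures for
    delta-correlation network analysis.
    """
    a, b = pair
    if a == b:
        raise CohortError("pair must name two distinct subsets")
    for name in pair:
        if name not in config.subset_names:
            raise CohortError(f"unknown subset {name!r}")
    for r in (r_control, r_patient):
        if not abs(r) < 1:
            raise CohortError("correlation targets must satisfy |r| < 1")

    names = list(config.subset_names)
    i, j = names.index(a), names.index(b)
    existing = config.correlation_structure or {}
    structure: dict[str, np.ndarray] = {}
    for group, r in ((CONTROL, r_control), (PATIENT, r_patient)):
        mat = np.array(existing.get(group, np.eye(len(names))), dtype=float, copy=True)
        mat[i, j] = mat[j, i] = r
        _validate_correlation(mat, len(names))
        structure[group] = mat
    return replace(config, correlation_structure=structure)
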