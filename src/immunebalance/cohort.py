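"""Core data containers: cohorts, panels and clinical domain sets.

A cohort is a set of samples (patients and healthy controls) described by a
percent-of-parent subset-frequency matrix, an optional binary clinical table
(patients only, typically), optional genetic-diagnosis labels, and — for
synthetic cohorts — the latent severity that generated them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PATIENT = "patient"
CONTROL = "control"

#: Inflammatory-side subsets of the default immune dysregulation panel:
#: follicular-helper-like BCL6+ and ICOS+BCL6+ T cells, activated CD8+CD25+ T cells.
DEFAULT_INFLAMMATORY = ("BCL6_T", "ICOS_BCL6_T", "CD8_CD25_T")

#: Regulatory-side subsets: CD4+CD25hiCD127loFOXP3+ Tregs, transitional and
#: memory regulatory B cells.
DEFAULT_REGULATORY = ("Treg_FOXP3", "Breg_transitional", "Breg_memory")

#: Four-manifestation clinical preset (composite score range 0-4).
FOUR_DOMAIN = (
    "autoimmunity",
    "chronic_inflammation",
    "lymphoproliferation",
    "malignancy",
)

#: Six-domain clinical preset.
SIX_DOMAIN = (
    "autoimmune_inflammatory",
    "malignancy",
    "lymphadenopathy",
    "recurrent_infections",
    "hypo_hypergammaglobulinemia",
    "hepatosplenomegaly",
)


class CohortError(ValueError):
    """Raised when a cohort, panel or configuration violates its contract."""


@dataclass(frozen=True)
class PanelDefinition:
    """Named inflammatory and regulatory subset lists parameterizing the IDS.

    The immune dysregulation score is the log of the ratio of geometric means
    of the inflammatory over the regulatory subset frequencies. ``pseudocount``
    (percentage points) is added to zero values before taking logs;
    ``log_base`` fixes the logarithm base (natural log by default).
    """

    inflammatory_subsets: tuple[str, ...] = DEFAULT_INFLAMMATORY
    regulatory_subsets: tuple[str, ...] = DEFAULT_REGULATORY
    pseudocount: float = 0.01
    log_base: float = float(np.e)

    def __post_init__(self) -> None:
        infl = tuple(self.inflammatory_subsets)
        reg = tuple(self.regulatory_subsets)
        object.__setattr__(self, "inflammatory_subsets", infl)
        object.__setattr__(self, "regulatory_subsets", reg)
        if not infl or not reg:
            raise CohortError("panel lists must be non-empty")
        if set(infl) & set(reg):
            raise CohortError("inflammatory and regulatory lists must be disjoint")
        if self.pseudocount <= 0:
            raise CohortError("pseudocount must be > 0")
        if self.log_base <= 0 or self.log_base == 1:
            raise CohortError("log_base must be positive and != 1")

    @property
    def all_subsets(self) -> tuple[str, ...]:
        return self.inflammatory_subsets + self.regulatory_subsets

    def to_dict(self) -> dict:
        return {
            "inflammatory_subsets": list(self.inflammatory_subsets),
            "regulatory_subsets": list(self.regulatory_subsets),
            "pseudocount": self.pseudocount,
            "log_base": self.log_base,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelDefinition":
        return cls(
            inflammatory_subsets=tuple(d["inflammatory_subsets"]),
            regulatory_subsets=tuple(d["regulatory_subsets"]),
            pseudocount=float(d.get("pseudocount", 0.01)),
            log_base=float(d.get("log_base", np.e)),
        )


@dataclass(frozen=True)
class ClinicalDomainSet:
    """Binary-coded clinical manifestation domains (0 absent / 1 present)."""

    domains: tuple[str, ...] = FOUR_DOMAIN

    def __post_init__(self) -> None:
        domains = tuple(self.domains)
        object.__setattr__(self, "domains", domains)
        if len(set(domains)) != len(domains):
            raise CohortError("domain names must be unique")
        if not domains:
            raise CohortError("domain set must be non-empty")

    @classmethod
    def preset(cls, name: str) -> "ClinicalDomainSet":
        presets = {"four-domain": FOUR_DOMAIN, "six-domain": SIX_DOMAIN}
        if name not in presets:
            raise CohortError(f"unknown clinical preset {name!r}")
        return cls(domains=presets[name])

    def __len__(self) -> int:
        return len(self.domains)


@dataclass
class CohortDataset:
    """Samples x subsets frequency matrix plus group labels and clinical data.

    All component tables are indexed by the same sample ids. ``subset_matrix``
    holds percent-of-parent values strictly within (0, 100) for generated
    data. ``clinical_matrix`` is binary {0, 1} with NaN marking missing
    entries and may omit samples (controls usually have no clinical table).
    """

    subset_matrix: pd.DataFrame
    group_labels: pd.Series
    clinical_matrix: pd.DataFrame | None = None
    genetic_labels: pd.Series | None = None
    latent_severity: pd.Series | None = None

    def __post_init__(self) -> None:
        self.group_labels = self.group_labels.reindex(self.subset_matrix.index)
        if self.group_labels.isna().any():
            raise CohortError("every sample needs a group label")
        bad = set(self.group_labels.unique()) - {PATIENT, CONTROL}
        if bad:
            raise CohortError(f"group labels must be patient/control, got {sorted(bad)}")
        if self.subset_matrix.index.has_duplicates:
            raise CohortError("duplicate sample ids")
        if self.subset_matrix.isna().any().any():
            raise CohortError("subset matrix contains missing values")
        vals = self.subset_matrix.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 100).any():
            raise CohortError("subset frequencies must lie within [0, 100]")
        if self.clinical_matrix is not None:
            extra = set(self.clinical_matrix.index) - set(self.subset_matrix.index)
            if extra:
                raise CohortError(f"clinical rows for unknown samples: {sorted(extra)}")
            cv = self.clinical_matrix.to_numpy(dtype=float)
            ok = np.isnan(cv) | (cv == 0) | (cv == 1)
            if not ok.all():
                raise CohortError("clinical entries must be 0, 1 or missing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.subset_matrix.index

    @property
    def subset_names(self) -> list[str]:
        return list(self.subset_matrix.columns)

    @property
    def patient_ids(self) -> pd.Index:
        return self.sample_ids[self.group_labels == PATIENT]

    @property
    def control_ids(self) -> pd.Index:
        return self.sample_ids[self.group_labels == CONTROL]

    def group_matrix(self, group: str) -> pd.DataFrame:
        ids = self.patient_ids if group == PATIENT else self.control_ids
        return self.subset_matrix.loc[ids]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CohortDataset({len(self.patient_ids)} patients, "
            f"{len(self.control_ids)} controls, "
            f"{self.subset_matrix.shape[1]} subsets)"
        )
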