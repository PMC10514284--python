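"""Configuration models shared across the pipeline.

All tunables live in two pydantic models: :class:`CohortSpec` drives the
synthetic cohort generator, :class:`ScoringConfig` drives the per-document
literature scoring.  Both validate on construction so that an invalid field
fails before any file is written or any score computed.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping

from pydantic import BaseModel, Field, field_validator, model_validator

#: Evidence document categories ("asset classes").  Theses appear in the
#: source accounting but carry zero weight in prioritization, which
#: enumerates six weighted classes only.
ASSET_CLASSES: tuple[str, ...] = (
    "publication",
    "clinical_trial",
    "patent",
    "grant",
    "congress",
    "news",
    "thesis",
)

#: Mention-position vocabulary, in decreasing order of specificity.
POSITIONS: tuple[str, ...] = (
    "title",
    "abstract",
    "indication",
    "intervention",
    "full_text",
    "raw_text",
)

TRIAL_STATUSES: tuple[str, ...] = (
    "completed",
    "active",
    "recruiting",
    "terminated",
    "withdrawn",
)

#: Mean documents per target per asset class for background (non-planted)
#: targets; over-dispersed counts are drawn around these.
DEFAULT_CLASS_RATES: dict[str, float] = {
    "publication": 8.0,
    "clinical_trial": 1.5,
    "patent": 3.0,
    "grant": 2.0,
    "congress": 2.5,
    "news": 2.0,
    "thesis": 0.8,
}


class CohortSpec(BaseModel):
    """Parameters of one synthetic evidence cohort.

    The defaults describe the benchmark condition used throughout the test
    suite: 500 candidate targets of which 10 are planted with saturated,
    multi-class evidence, 126 planted up-regulated and 14 down-regulated
    genes in the expression table, and a variant file whose records straddle
    every hard-filter boundary.
    """

    n_targets: int = Field(default=500, gt=0)
    n_planted_top: int = Field(default=10, ge=0)
    seed: int = 0

    asset_class_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CLASS_RATES)
    )
    #: Over-dispersion of per-target document counts (negative binomial
    #: shape parameter; smaller = more over-dispersed).
    nb_dispersion: float = Field(default=1.5, gt=0)
    #: Extra documents per asset class given to each planted-top target;
    #: set at the relevance threshold so planted targets clear it in every
    #: class by construction.
    planted_docs_per_class: int = Field(default=20, ge=0)

    frac_druggable: float = Field(default=0.6, ge=0, le=1)
    frac_unsafe: float = Field(default=0.02, ge=0, le=1)
    frac_novel: float = Field(default=0.05, ge=0, le=1)
    frac_biomarker: float = Field(default=0.05, ge=0, le=1)

    n_deg_up: int = Field(default=126, ge=0)
    n_deg_down: int = Field(default=14, ge=0)
    de_effect_log2fc: float = 2.0
    de_noise_sd: float = Field(default=0.3, gt=0)
    n_replicates: int = Field(default=5, ge=2)

    variant_pass_fraction: float = Field(default=0.6, ge=0, le=1)
    n_variants: int = Field(default=600, gt=0)

    #: All dates are drawn relative to this anchor so that a cohort is a
    #: pure function of its spec, independent of the wall clock.
    reference_date: dt.date = dt.date(2023, 1, 1)
    window_years: float = Field(default=15.0, gt=0)

    @field_validator("asset_class_rates")
    @classmethod
    def _rates_known_and_nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        for cls_name, rate in v.items():
            if cls_name not in ASSET_CLASSES:
                raise ValueError(f"unknown asset class {cls_name!r}")
            if rate < 0:
                raise ValueError(f"asset_class_rates[{cls_name!r}] must be >= 0")
        return v

    @model_validator(mode="after")
    def _planted_within_cohort(self) -> "CohortSpec":
        if self.n_planted_top > self.n_targets:
            raise ValueError("n_planted_top cannot exceed n_targets")
        if self.n_deg_up + self.n_deg_down > self.n_targets:
            raise ValueError("n_deg_up + n_deg_down cannot exceed n_targets")
        return self


class ScoringConfig(BaseModel):
    """Weights and transforms for per-document literature scoring.

    Each scored attribute maps into [0, 1]:

    * recency: ``2 ** (-age_years / recency_half_life_years)``;
    * impact factor: ``min(IF, if_cap) / if_cap``;
    * mention position, trial phase and trial status: direct table lookup.

    A document's score is the sum of the components its asset class uses,
    so it lies in ``[0, k]`` for ``k`` components (3 for publications and
    clinical trials, 2 for the recency+position classes).
    """

    recency_half_life_years: float = Field(default=5.0, gt=0)
    if_cap: float = Field(default=30.0, gt=0)

    position_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "title": 1.0,
            "abstract": 0.8,
            "indication": 0.7,
            "intervention": 0.7,
            "full_text": 0.4,
            "raw_text": 0.2,
        }
    )
    phase_weights: dict[int, float] = Field(
        default_factory=lambda: {1: 0.4, 2: 0.6, 3: 0.8, 4: 1.0}
    )
    status_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "completed": 1.0,
            "active": 1.0,
            "recruiting": 0.8,
            "terminated": 0.2,
            "withdrawn": 0.2,
        }
    )

    #: Optional fourth publication component log1p(citations)/log1p(cap);
    #: off by default.
    include_citations: bool = False
    citations_cap: int = Field(default=1000, gt=0)

    #: Relevance threshold: targets with fewer total documents than this
    #: across all asset classes are dropped by the filter cascade.
    min_total_docs: int = Field(default=20, ge=0)

    @field_validator("position_weights", "status_weights")
    @classmethod
    def _weights_unit_interval(cls, v: Mapping) -> Mapping:
        for key, w in v.items():
            if not 0 <= w <= 1:
                raise ValueError(f"weight for {key!r} must lie in [0, 1]")
        return v

    @field_validator("phase_weights")
    @classmethod
    def _phases_unit_interval(cls, v: dict[int, float]) -> dict[int, float]:
        for key, w in v.items():
            if not 0 <= w <= 1:
                raise ValueError(f"weight for phase {key} must lie in [0, 1]")
        return v
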