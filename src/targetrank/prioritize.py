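"""Composite 40/60 weighted prioritization and ranking.

The literature side carries 40% of the composite score, split across six
asset classes (publications 12, congress 3, clinical trials 9, patents 4,
grants 6, news 6; theses carry zero weight).  The disease-relevance side
carries 60%, split across seven parameters (druggability 12, pathways 9,
biomarker 3, safety 3, expression & mutation 12, tissue expression 9,
novelty 12).  Each weighted input lies in [0, 1], so a target's total lies
in [0, 100] and decomposes exactly into its two components.

Per-parameter scoring rules (how a profile becomes a number in [0, 1]) are
collected in :func:`disease_parameter_scores` and documented there; the
weights themselves are user-overridable under a strict or normalizing
policy.
"""

from __future__ import annotations

import hashlib
import json
import math
from typing import Iterable, Mapping, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator
from pydantic import ValidationError as PydanticValidationError

from .models import PriorityScore, TargetProfile

LITERATURE_WEIGHTS_DEFAULT = {
    "publication": 12.0,
    "congress": 3.0,
    "clinical_trial": 9.0,
    "patent": 4.0,
    "grant": 6.0,
    "news": 6.0,
}

DISEASE_WEIGHTS_DEFAULT = {
    "druggability": 12.0,
    "pathways": 9.0,
    "biomarker": 3.0,
    "safety": 3.0,
    "expression_mutation": 12.0,
    "tissue_expression": 9.0,
    "novelty": 12.0,
}

LITERATURE_TOTAL = 40.0
DISEASE_TOTAL = 60.0

#: Severity of the most impactful surviving variant, as a [0, 1] sub-signal.
IMPACT_SCORES = {"HIGH": 1.0, "MODERATE": 0.6, "LOW": 0.3}

TISSUE_SCORES = {"exclusive": 1.0, "high_shared": 0.7, "other": 0.2}
DRUGGABILITY_SCORES = {"highly": 1.0, "potentially": 0.5, "none": 0.0}

#: Pathway-overlap counts at or above this cap score 1.0.
PATHWAY_OVERLAP_CAP = 5


class WeightConfigError(ValueError):
    """Weight sums violate the 40/60/100 policy."""


class WeightConfig(BaseModel):
    """Percent weights for the literature (40) and disease (60) sides."""

    literature: dict[str, float] = Field(
        default_factory=lambda: dict(LITERATURE_WEIGHTS_DEFAULT)
    )
    disease: dict[str, float] = Field(
        default_factory=lambda: dict(DISEASE_WEIGHTS_DEFAULT)
    )

    @model_validator(mode="after")
    def _sums(self) -> "WeightConfig":
        for side, weights, expected in (
            ("literature", self.literature, LITERATURE_TOTAL),
            ("disease", self.disease, DISEASE_TOTAL),
        ):
            if any(w < 0 for w in weights.values()):
                raise WeightConfigError(f"{side} weights must be non-negative")
            total = sum(weights.values())
            if not math.isclose(total, expected, abs_tol=1e-9):
                raise WeightConfigError(
                    f"{side} weights sum to {total}, expected {expected}"
                )
        return self

    @property
    def total(self) -> float:
        return sum(self.literature.values()) + sum(self.disease.values())


def reweight(
    base: Optional[WeightConfig] = None,
    literature: Optional[Mapping[str, float]] = None,
    disease: Optional[Mapping[str, float]] = None,
    policy: str = "strict",
) -> WeightConfig:
    """Apply user weight overrides under a sum policy.

    ``strict``: the overridden sides must still sum to 40 / 60 exactly.
    ``normalize``: after overriding, the non-overridden weights on the same
    side are rescaled proportionally so the side sum is restored (if they
    are all zero, every weight on the side is rescaled instead).
    Negative overrides are rejected under either policy.
    """
    if policy not in ("strict", "normalize"):
        raise ValueError(f"unknown reweight policy {policy!r}")
    base = base or WeightConfig()

    def apply(side: dict[str, float], overrides: Mapping[str, float], total: float):
        unknown = set(overrides) - set(side)
        if unknown:
            raise WeightConfigError(f"unknown parameters: {sorted(unknown)}")
        if any(w < 0 for w in overrides.values()):
            raise WeightConfigError("weights must be non-negative")
        merged = {**side, **{k: float(v) for k, v in overrides.items()}}
        if policy == "normalize":
            fixed = sum(merged[k] for k in overrides)
            if fixed > total:
                raise WeightConfigError(
                    f"overridden weights alone exceed the side total {total}"
                )
            free = [k for k in merged if k not in overrides]
            free_sum = sum(merged[k] for k in free)
            if free:
                if free_sum > 0:
                    factor = (total - fixed) / free_sum
                    for k in free:
                        merged[k] *= factor
                else:
                    for k in free:
                        merged[k] = (total - fixed) / len(free)
        return merged

    lit = apply(dict(base.literature), literature or {}, LITERATURE_TOTAL)
    dis = apply(dict(base.disease), disease or {}, DISEASE_TOTAL)
    try:
        return WeightConfig(literature=lit, disease=dis)  # re-validates the sums
    except PydanticValidationError as exc:
        raise WeightConfigError(str(exc)) from exc


def disease_parameter_scores(
    profile: TargetProfile,
    deg_survivor: bool = False,
    variant_headline_impact: Optional[str] = None,
    overlap_cap: int = PATHWAY_OVERLAP_CAP,
) -> dict[str, float]:
    """Map a target's evaluated profile onto [0, 1] parameter scores.

    Rules: druggability highly=1.0 / potentially=0.5 / none=0; pathways
    min(overlap / cap, 1); biomarker 1 if any category; safety 1 only when
    safe (unsafe targets are down-weighted, not removed); expression &
    mutation is the mean of a DEG-survivor indicator and the surviving
    variants' headline-impact severity (HIGH 1.0, MODERATE 0.6, LOW 0.3);
    tissue exclusive=1 / high_shared=0.7 / other=0.2; novelty 1 if novel.
    """
    severity = IMPACT_SCORES.get(variant_headline_impact or "", 0.0)
    return {
        "druggability": DRUGGABILITY_SCORES[profile.druggability],
        "pathways": min(profile.pathway_overlap_count / overlap_cap, 1.0),
        "biomarker": 1.0 if profile.biomarker_categories else 0.0,
        "safety": 1.0 if profile.safety == "safe" else 0.0,
        "expression_mutation": ((1.0 if deg_survivor else 0.0) + severity) / 2.0,
        "tissue_expression": TISSUE_SCORES[profile.lung_expression],
        "novelty": 1.0 if profile.novel else 0.0,
    }


def combine(
    scaled_class_scores: Mapping[str, float],
    parameter_scores: Mapping[str, float],
    weights: WeightConfig,
    target: str = "",
) -> PriorityScore:
    """Weighted sum of scaled literature class scores and parameter scores.

    A class or parameter absent from the input contributes 0.  Components
    stay within [0, 40] and [0, 60] because every input lies in [0, 1].
    """
    lit = sum(
        w * float(scaled_class_scores.get(cls, 0.0))
        for cls, w in weights.literature.items()
    )
    dis = sum(
        w * float(parameter_scores.get(param, 0.0))
        for param, w in weights.disease.items()
    )
    return PriorityScore(
        target=target,
        literature_component=lit,
        disease_component=dis,
        total=lit + dis,
    )


def rank(scores: Iterable[PriorityScore]) -> list[PriorityScore]:
    """Sort descending by total, ties broken by symbol; assign ranks 1..N."""
    ordered = sorted(scores, key=lambda s: (-s.total, s.target))
    for i, score in enumerate(ordered, start=1):
        score.rank = i
    return ordered


def ranking_table(scores: Iterable[PriorityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": s.rank,
                "target": s.target,
                "literature_component": s.literature_component,
                "disease_component": s.disease_component,
                "total": s.total,
            }
            for s in scores
        ]
    )


def config_hash(*configs: BaseModel) -> str:
    """Short stable hash of the run configuration, for the run log."""
    payload = json.dumps(
        [c.model_dump(mode="json") for c in configs], sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
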