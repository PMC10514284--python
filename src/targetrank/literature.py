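"""Per-asset-class literature scoring and the relevance filter cascade.

Each document is scored as a sum of bounded attribute components (recency,
impact factor and mention position for publications; trial status, phase
and position for clinical trials; recency and position for the remaining
classes).  Per-target class scores are the sums over that class's
documents, then min-max scaled to [0, 1] across the cohort within each
class.

The filter cascade then drops targets with fewer than the threshold number
of total documents, and drops single-asset-class targets unless their
annotated pathways overlap the disease-relevant pathway set.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .config import ASSET_CLASSES, ScoringConfig
from .models import EvidenceDocument, TargetEvidence


class ScoringError(ValueError):
    """A document lacks a field mandatory for its asset class."""


def _recency(doc_date: dt.date, today: dt.date, half_life_years: float) -> float:
    """Exponential decay with configurable half-life; future dates score 1."""
    age_years = max((today - doc_date).days, 0) / 365.25
    return 2.0 ** (-age_years / half_life_years)


def score_document(doc: EvidenceDocument, cfg: ScoringConfig, today: dt.date) -> float:
    """Score one document; each component lies in [0, 1].

    Publications: recency + impact factor + position (+ optional citations).
    Clinical trials: status + phase + position.  All other classes:
    recency + position.  A missing date or position is a hard error naming
    the document; a missing impact factor, phase or status contributes 0.
    """
    if doc.date is None:
        raise ScoringError(f"document {doc.doc_id}: missing date")
    if doc.position is None:
        raise ScoringError(f"document {doc.doc_id}: missing position")
    if doc.position not in cfg.position_weights:
        raise ScoringError(f"document {doc.doc_id}: unknown position {doc.position!r}")

    position = cfg.position_weights[doc.position]

    if doc.asset_class == "publication":
        recency = _recency(doc.date, today, cfg.recency_half_life_years)
        if_component = min(doc.impact_factor or 0.0, cfg.if_cap) / cfg.if_cap
        score = recency + if_component + position
        if cfg.include_citations:
            score += math.log1p(min(doc.citations or 0, cfg.citations_cap)) / math.log1p(
                cfg.citations_cap
            )
        return score

    if doc.asset_class == "clinical_trial":
        status = cfg.status_weights.get(doc.status, 0.0) if doc.status else 0.0
        phase = cfg.phase_weights.get(doc.phase, 0.0) if doc.phase else 0.0
        return status + phase + position

    recency = _recency(doc.date, today, cfg.recency_half_life_years)
    return recency + position


def class_score(
    evidence: TargetEvidence, asset_class: str, cfg: ScoringConfig, today: dt.date
) -> float:
    """Raw class score: sum of document scores; zero documents scores 0."""
    docs = evidence.docs_by_class.get(asset_class, [])
    return sum(score_document(doc, cfg, today) for doc in docs)


def scale_scores(raw: Mapping[str, float]) -> dict[str, float]:
    """Min-max scale one class's raw scores across the cohort.

    The cohort minimum maps to 0 and the maximum to 1; a degenerate cohort
    (all raw scores equal, including a single target) maps to all zeros.
    """
    if not raw:
        raise ValueError("cannot scale an empty score collection")
    lo, hi = min(raw.values()), max(raw.values())
    if hi == lo:
        return {t: 0.0 for t in raw}
    return {t: (s - lo) / (hi - lo) for t, s in raw.items()}


def score_matrix(
    evidence: Iterable[TargetEvidence],
    cfg: ScoringConfig,
    today: dt.date,
    scaled: bool = True,
) -> pd.DataFrame:
    """Target x asset-class score matrix (raw or cohort-scaled)."""
    evidence = list(evidence)
    data = {
        ev.target: {cls: class_score(ev, cls, cfg, today) for cls in ASSET_CLASSES}
        for ev in evidence
    }
    df = pd.DataFrame.from_dict(data, orient="index").rename_axis("target").sort_index()
    if scaled and not df.empty:
        for cls in ASSET_CLASSES:
            df[cls] = pd.Series(scale_scores(df[cls].to_dict()))
    return df


def relevance_filter(
    evidence: Iterable[TargetEvidence],
    disease_pathways: Iterable[str] = (),
    pathway_map: Optional[Mapping[str, Iterable[str]]] = None,
    min_total_docs: int = 20,
) -> tuple[list[TargetEvidence], list[tuple[str, str]]]:
    """Apply the two-stage relevance cascade.

    A target is kept iff its total document count is at least
    ``min_total_docs`` AND (its documents span at least two asset classes
    OR its pathways overlap the disease pathway set).  The exclusion log
    records which rule fired for each removed target.  The cascade is a
    per-target predicate, so it is independent of cohort order.
    """
    disease = set(disease_pathways)
    pathway_map = pathway_map or {}
    kept: list[TargetEvidence] = []
    excluded: list[tuple[str, str]] = []
    for ev in evidence:
        if ev.total_docs < min_total_docs:
            excluded.append((ev.target, f"count<{min_total_docs}"))
            continue
        if ev.n_classes < 2:
            overlap = disease & set(pathway_map.get(ev.target, ()))
            if not overlap:
                excluded.append((ev.target, "single-class no pathway overlap"))
                continue
        kept.append(ev)
    return kept, excluded
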