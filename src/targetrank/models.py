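"""Record types flowing through the pipeline.

These are plain dataclasses: they carry data between modules and are
validated where they are constructed (readers, generator), not on every
attribute access.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

VariantKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


@dataclass
class EvidenceDocument:
    """One literature / trial / patent / news record attributed to a target."""

    doc_id: str
    asset_class: str
    target: str
    date: dt.date
    position: Optional[str] = None
    impact_factor: Optional[float] = None  # publications only
    citations: Optional[int] = None  # publications only
    phase: Optional[int] = None  # clinical trials only
    status: Optional[str] = None  # clinical trials only
    relevance: Optional[float] = None  # optional upstream relevance score


@dataclass
class TargetEvidence:
    """All evidence for one gene symbol, grouped by asset class."""

    target: str
    docs_by_class: dict[str, list[EvidenceDocument]] = field(default_factory=dict)
    source_flags: set[str] = field(default_factory=set)
    db_names: set[str] = field(default_factory=set)

    @property
    def total_docs(self) -> int:
        return sum(len(docs) for docs in self.docs_by_class.values())

    @property
    def n_classes(self) -> int:
        """Number of asset classes with at least one document."""
        return sum(1 for docs in self.docs_by_class.values() if docs)


@dataclass
class SourceAccounting:
    """Per-source target counts and the arm / grand totals derived from them.

    ``grand_total`` counts targets with multiplicity (a target found by three
    sources counts three times); ``unique_total`` counts distinct symbols and
    is only available when the accounting was derived from actual evidence.
    """

    per_source_target_counts: dict[str, int]
    literature_total: int
    structured_total: int
    genomics_total: int
    grand_total: int
    unique_total: Optional[int] = None


@dataclass
class VariantQualityMetrics:
    QD: Optional[float] = None
    FS: Optional[float] = None
    MQ: Optional[float] = None
    MQRankSum: Optional[float] = None
    ReadPosRankSum: Optional[float] = None
    SOR: Optional[float] = None


@dataclass
class VariantAnnotation:
    gene: str
    biotype: str
    consequence: str
    impact: str  # HIGH / MODERATE / LOW / MODIFIER
    AF: Optional[float] = None
    ExAC_AF: Optional[float] = None
    SIFT: Optional[str] = None
    PolyPhen: Optional[str] = None


@dataclass
class AnnotatedVariant:
    """One bi-allelic variant (multi-allelic records are split upstream)."""

    key: VariantKey
    variant_class: str  # SNP / INDEL
    metrics: VariantQualityMetrics
    annotations: list[VariantAnnotation]
    rsid: Optional[str] = None
    verdicts: dict[str, bool] = field(default_factory=dict)
    is_lof: Optional[bool] = None

    @property
    def annotation(self) -> VariantAnnotation:
        """Most severe annotation block (HIGH > MODERATE > LOW > MODIFIER)."""
        order = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}
        return min(self.annotations, key=lambda a: order.get(a.impact, 4))


@dataclass
class DrugRecord:
    """One drug-target relation with clinical history."""

    drug: str
    target: str
    modality: str  # small_molecule / antibody
    max_phase: int  # 0 (preclinical) .. 4
    status: str
    approved: bool = False
    withdrawal: str = "none"  # none / market / clinical
    reason_target_attributed: bool = False


@dataclass
class TargetAnnotations:
    """Per-target facts consumed by the rule-based classifiers."""

    target: str
    has_structure: bool = False
    surface_localized: bool = False
    essential_gene: bool = False
    mechanism_known: bool = False
    drugs: list[DrugRecord] = field(default_factory=list)
    tissue_expression: dict[str, str] = field(default_factory=dict)
    pathways: set[str] = field(default_factory=set)
    biomarker_evidence: list[tuple[str, str]] = field(default_factory=list)
    highIF_pub_dates: list[dt.date] = field(default_factory=list)
    news_dates: list[dt.date] = field(default_factory=list)
    source_flags: set[str] = field(default_factory=set)

    @property
    def max_drug_phase(self) -> int:
        return max((d.max_phase for d in self.drugs), default=0)


@dataclass
class TargetProfile:
    """Evaluated classifications for one target."""

    target: str
    druggability: str  # highly / potentially / none
    modality: str  # small_molecule / antibody / both / none
    safety: str  # safe / unsafe_market_withdrawal / unsafe_clinical_withdrawal / unsafe_essential
    biomarker_categories: set[str]
    novel: bool
    novelty_taxonomy: str  # known_knowns / known_unknowns / unknown_knowns / n/a
    lung_expression: str  # exclusive / high_shared / other
    pathway_overlap_count: int


@dataclass
class PriorityScore:
    """Composite weighted score and rank for one target."""

    target: str
    literature_component: float  # in [0, 40]
    disease_component: float  # in [0, 60]
    total: float  # in [0, 100]
    rank: int = 0
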