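"""Post-alignment genomics logic: DEG post-processing and variant filtering.

Upstream tooling (aligners, variant callers, consequence predictors, the
differential-expression model itself) is out of scope; this module consumes
their standard output formats — a differential-expression table and an
annotated VCF — and re-implements the downstream decision logic:

* up/down regulation assignment and significance selection on DE tables;
* per-variant hard filtering on the six site-quality metrics
  (QD, FS, MQ, MQRankSum, ReadPosRankSum, SOR), strict inequalities;
* annotation-level filtering (protein-coding, rare, non-synonymous,
  non-MODIFIER impact);
* impact classification per gene and loss-of-function (LOF) calling on
  missense variants via SIFT/PolyPhen status.
"""

from __future__ import annotations

import operator
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .models import AnnotatedVariant, VariantAnnotation, VariantQualityMetrics

#: Canonical column set of a differential-expression result table.
DEG_COLUMNS = (
    "gene_symbol",
    "control_mean",
    "disease_mean",
    "log2fc",
    "p_value",
    "p_adj",
    "abs_log2fc",
    "regulation",
)

#: Hard-filter predicates on site quality metrics.  A variant passes a
#: metric when ``value <op> threshold`` holds; comparisons are strict, so a
#: value exactly at its threshold fails that metric.
HARD_FILTERS: dict[str, tuple[str, float]] = {
    "QD": (">", 2.0),
    "FS": ("<", 60.0),
    "MQ": (">", 40.0),
    "MQRankSum": (">", -12.5),
    "ReadPosRankSum": (">", -8.0),
    "SOR": ("<", 4.0),
}

_OPS = {">": operator.gt, "<": operator.lt}

IMPACT_SEVERITY = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}

#: Declared CSQ subfield order for generated/consumed annotation blocks.
CSQ_FIELDS = ("Gene", "BIOTYPE", "Consequence", "IMPACT", "AF", "ExAC_AF", "SIFT", "PolyPhen")


# ---------------------------------------------------------------------------
# Differential expression post-processing
# ---------------------------------------------------------------------------

def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a DE result CSV and check the canonical column set is present."""
    df = pd.read_csv(path)
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path} lacks required columns: {missing}")
    return df


def assign_regulation(table: pd.DataFrame) -> pd.DataFrame:
    """Set ``regulation`` and ``abs_log2fc`` from the sign of ``log2fc``.

    ``regulation`` is ``up`` for log2fc > 0 and ``down`` for log2fc < 0.
    Genes with log2fc exactly 0 are unregulated: they get a missing
    regulation value and are excluded from up/down tallies downstream.
    """
    out = table.copy()
    lfc = out["log2fc"].astype(float)
    if not np.isfinite(lfc).all():
        bad = out.loc[~np.isfinite(lfc), "gene_symbol"].tolist()
        raise ValueError(f"non-finite log2fc for genes: {bad[:5]}")
    out["abs_log2fc"] = lfc.abs()
    out["regulation"] = np.select([lfc > 0, lfc < 0], ["up", "down"], default=None)
    return out


def select_significant(
    table: pd.DataFrame,
    padj_max: float = 0.05,
    abs_lfc_min: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rows with ``p_adj <= padj_max`` and ``|log2fc| >= abs_lfc_min``.

    Returns the surviving rows together with up/down counts.  Regulation is
    (re)assigned first so the counts never trust a stale input column.
    """
    if padj_max < 0 or abs_lfc_min < 0:
        raise ValueError("significance thresholds must be non-negative")
    assigned = assign_regulation(table)
    keep = (assigned["p_adj"] <= padj_max) & (assigned["abs_log2fc"] >= abs_lfc_min)
    survivors = assigned.loc[keep].reset_index(drop=True)
    counts = {
        "up": int((survivors["regulation"] == "up").sum()),
        "down": int((survivors["regulation"] == "down").sum()),
    }
    return survivors, counts


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _csq_order(header: pysam.VariantHeader) -> Sequence[str]:
    rec = header.info.get("CSQ")
    if rec is not None and rec.description and "Format:" in rec.description:
        return tuple(rec.description.split("Format:")[1].strip().split("|"))
    return CSQ_FIELDS


def _parse_float(value: str) -> Optional[float]:
    return float(value) if value not in ("", ".") else None


def _parse_csq_block(block: str, order: Sequence[str]) -> VariantAnnotation:
    parts = block.split("|")
    fields = dict(zip(order, parts))
    return VariantAnnotation(
        gene=fields.get("Gene", ""),
        biotype=fields.get("BIOTYPE", ""),
        consequence=fields.get("Consequence", ""),
        impact=fields.get("IMPACT", "MODIFIER"),
        AF=_parse_float(fields.get("AF", "")),
        ExAC_AF=_parse_float(fields.get("ExAC_AF", "")),
        SIFT=fields.get("SIFT") or None,
        PolyPhen=fields.get("PolyPhen") or None,
    )


def _info_get(info, key, default=None):
    # pysam raises on keys missing from the header, not just the record
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _round(value) -> Optional[float]:
    # htslib stores Float INFO as float32; round so values read back exactly
    # as written at the precision the fixtures use.
    if value is None:
        return None
    return round(float(value), 4)


def read_vcf(path: str | Path) -> list[AnnotatedVariant]:
    """Read an annotated VCF into per-allele :class:`AnnotatedVariant`.

    Multi-allelic records are split into one variant per alternate allele
    (the filter predicates are per-allele).  When the record carries exactly
    one CSQ block per alternate allele the blocks are matched positionally;
    otherwise every block is attached to every split allele.
    """
    variants: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        order = _csq_order(vcf.header)
        for rec in vcf:
            info = rec.info
            metrics = VariantQualityMetrics(
                QD=_round(_info_get(info, "QD")),
                FS=_round(_info_get(info, "FS")),
                MQ=_round(_info_get(info, "MQ")),
                MQRankSum=_round(_info_get(info, "MQRankSum")),
                ReadPosRankSum=_round(_info_get(info, "ReadPosRankSum")),
                SOR=_round(_info_get(info, "SOR")),
            )
            csq = _info_get(info, "CSQ", ())
            if isinstance(csq, str):
                csq = (csq,)
            blocks = [_parse_csq_block(b, order) for b in csq]
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if blocks and len(blocks) == len(alts):
                    annots = [blocks[i]]
                else:
                    annots = list(blocks)
                if not annots:
                    annots = [VariantAnnotation("", "", "", "MODIFIER")]
                is_snp = len(rec.ref) == 1 and len(alt) == 1
                variants.append(
                    AnnotatedVariant(
                        key=(rec.chrom, rec.pos, rec.ref, alt),
                        variant_class="SNP" if is_snp else "INDEL",
                        metrics=metrics,
                        annotations=annots,
                        rsid=rec.id,
                    )
                )
    return variants


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------

def hard_filter(
    v: AnnotatedVariant, missing_passes: bool = True
) -> tuple[bool, list[str]]:
    """Evaluate the six site-quality predicates; return (pass, failed metrics).

    An absent metric (common for the rank-sum statistics at homozygous
    sites) passes by default; set ``missing_passes=False`` to fail it.
    """
    failed = []
    for name, (op, threshold) in HARD_FILTERS.items():
        value = getattr(v.metrics, name)
        if value is None:
            if not missing_passes:
                failed.append(name)
        elif not _OPS[op](value, threshold):
            failed.append(name)
    passed = not failed
    v.verdicts["hard_filter"] = passed
    return passed, failed


def downstream_filter(
    v: AnnotatedVariant, af_missing_passes: bool = True
) -> tuple[bool, list[str]]:
    """Annotation-level filter applied to hard-filter survivors.

    Pass requires: protein-coding biotype, AF < 0.01, ExAC_AF < 0.01,
    consequence not synonymous, and impact not exclusively MODIFIER.  The
    first four rules are evaluated on the most severe annotation block; the
    impact rule fails only when *every* block is MODIFIER.  Absent allele
    frequencies count as rare (< 0.01) by default.
    """
    ann = v.annotation
    failed = []
    if ann.biotype.lower() != "protein_coding":
        failed.append("biotype")
    for rule, value in (("AF", ann.AF), ("ExAC_AF", ann.ExAC_AF)):
        if value is None:
            if not af_missing_passes:
                failed.append(rule)
        elif not value < 0.01:
            failed.append(rule)
    if "synonymous_variant" in ann.consequence:
        failed.append("consequence")
    if all(a.impact == "MODIFIER" for a in v.annotations):
        failed.append("impact")
    passed = not failed
    v.verdicts["downstream_filter"] = passed
    return passed, failed


def call_lof(v: AnnotatedVariant, accept_possibly: bool = True) -> bool:
    """LOF call restricted to missense variants.

    A missense variant is loss-of-function when its SIFT status begins with
    ``deleterious`` and its PolyPhen status contains ``damaging``
    (``probably_damaging`` always; ``possibly_damaging`` unless
    ``accept_possibly`` is disabled).  Non-missense consequences are outside
    LOF scope and return False regardless of SIFT/PolyPhen.
    """
    ann = v.annotation
    lof = False
    if "missense_variant" in ann.consequence:
        sift_hit = bool(ann.SIFT) and ann.SIFT.startswith("deleterious")
        polyphen = ann.PolyPhen or ""
        if accept_possibly:
            poly_hit = "damaging" in polyphen
        else:
            poly_hit = polyphen.startswith("probably_damaging")
        lof = sift_hit and poly_hit
    v.is_lof = lof
    return lof


def apply_variant_filters(
    variants: Iterable[AnnotatedVariant],
    missing_passes: bool = True,
    af_missing_passes: bool = True,
    accept_possibly: bool = True,
) -> list[AnnotatedVariant]:
    """Run the hard filter then the downstream filter; LOF-call survivors.

    Returns variants passing both stages, with per-stage verdicts recorded
    on every input variant.
    """
    survivors = []
    for v in variants:
        passed, _ = hard_filter(v, missing_passes=missing_passes)
        if not passed:
            continue
        passed, _ = downstream_filter(v, af_missing_passes=af_missing_passes)
        if not passed:
            continue
        call_lof(v, accept_possibly=accept_possibly)
        survivors.append(v)
    return survivors


def classify_impact(survivors: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    """Per-gene impact tallies with a max-severity headline impact.

    Returns a frame indexed by gene with columns ``n_high``, ``n_moderate``,
    ``n_low``, ``n_lof``, ``n_variants`` and ``headline_impact``.
    """
    rows: dict[str, dict[str, int]] = {}
    for v in survivors:
        ann = v.annotation
        gene = ann.gene
        if not gene:
            continue
        entry = rows.setdefault(
            gene, {"n_high": 0, "n_moderate": 0, "n_low": 0, "n_lof": 0, "n_variants": 0}
        )
        entry["n_variants"] += 1
        if ann.impact == "HIGH":
            entry["n_high"] += 1
        elif ann.impact == "MODERATE":
            entry["n_moderate"] += 1
        elif ann.impact == "LOW":
            entry["n_low"] += 1
        if v.is_lof:
            entry["n_lof"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")
    if df.empty:
        return pd.DataFrame(
            columns=["n_high", "n_moderate", "n_low", "n_lof", "n_variants", "headline_impact"]
        ).rename_axis("gene")
    df["headline_impact"] = np.select(
        [df["n_high"] > 0, df["n_moderate"] > 0, df["n_low"] > 0],
        ["HIGH", "MODERATE", "LOW"],
        default="MODIFIER",
    )
    return df.sort_index()
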