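"""Synthetic evidence cohorts with planted ground truth.

Generates a complete, internally consistent cohort — literature documents,
a differential-expression table, an annotated VCF, pathway gene sets, and
drug / trial / annotation tables — from a :class:`CohortSpec`, together
with the :class:`GroundTruth` describing what was planted.  Every file is a
pure function of the spec (all randomness flows through one seeded
generator and all dates are drawn relative to the spec's reference date),
so identical specs yield byte-identical outputs.

What the generator plants:

* ``n_planted_top`` targets receive saturated evidence: at least the
  relevance-threshold number of recent, high-scoring documents in every
  asset class, membership in the disease pathways, clinical-stage drugs
  with structure and surface localization, favorable safety and biomarker
  annotations, lung-exclusive expression, an up-regulated DEG row and
  passing variants (one HIGH-impact, one loss-of-function missense).
* ``n_deg_up`` / ``n_deg_down`` genes with a +/- ``de_effect_log2fc``
  expression shift; replicate noise makes the p-values behave like a real
  two-group comparison.
* variants straddling every hard-filter boundary (at, just above and just
  below each threshold) plus random variants tuned so roughly
  ``variant_pass_fraction`` pass, each labelled with the expected verdict
  computed directly from the printed thresholds.

Expected labels (pass/fail verdicts, classifier classes) are computed here
from first principles, independently of the analysis modules, so they can
serve as oracles in tests.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ASSET_CLASSES, CohortSpec
from .models import VariantKey

DISEASE_PATHWAY_COUNT = 8
BACKGROUND_PATHWAY_COUNT = 30
OTHER_TISSUES = ("liver", "kidney", "brain", "heart")
SPONSORS = ("AlphaPharma", "BetaBio", "GammaTx", "DeltaMed", "EpsilonRx", "ZetaGen")

#: Safe mid-range metric values used for the non-probed metrics of a
#: boundary-straddling variant.
SAFE_METRICS = {
    "QD": 15.0,
    "FS": 5.0,
    "MQ": 55.0,
    "MQRankSum": 0.5,
    "ReadPosRankSum": 0.5,
    "SOR": 1.2,
}

#: The printed hard-filter thresholds, used here only to label fixtures.
_THRESHOLDS = {
    "QD": (">", 2.0),
    "FS": ("<", 60.0),
    "MQ": (">", 40.0),
    "MQRankSum": (">", -12.5),
    "ReadPosRankSum": (">", -8.0),
    "SOR": ("<", 4.0),
}


@dataclass
class GroundTruth:
    """What the generator planted, for oracle-style assertions downstream."""

    targets: list[str]
    planted_top_targets: set[str]
    planted_up: set[str]
    planted_down: set[str]
    variants_expected_pass: set[VariantKey]
    variants_expected_downstream: set[VariantKey]
    planted_lof: set[VariantKey]
    planted_classes: dict[str, dict]
    disease_pathways: set[str]
    source_flags: dict[str, set[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        def keys(ks):
            return sorted(":".join(map(str, k)) for k in ks)

        payload = {
            "targets": self.targets,
            "planted_top_targets": sorted(self.planted_top_targets),
            "planted_up": sorted(self.planted_up),
            "planted_down": sorted(self.planted_down),
            "variants_expected_pass": keys(self.variants_expected_pass),
            "variants_expected_downstream": keys(self.variants_expected_downstream),
            "planted_lof": keys(self.planted_lof),
            "planted_classes": {
                t: self.planted_classes[t] for t in sorted(self.planted_classes)
            },
            "disease_pathways": sorted(self.disease_pathways),
            "source_flags": {
                t: sorted(v) for t, v in sorted(self.source_flags.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=False)


# ---------------------------------------------------------------------------
# Expected-label oracles (independent re-statements of the filter rules)
# ---------------------------------------------------------------------------

def expected_hard_pass(metrics: dict[str, Optional[float]]) -> bool:
    for name, (op, thr) in _THRESHOLDS.items():
        value = metrics.get(name)
        if value is None:
            continue
        ok = value > thr if op == ">" else value < thr
        if not ok:
            return False
    return True


def _severe_block(annots: list[dict]) -> dict:
    order = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}
    return min(annots, key=lambda a: order[a["IMPACT"]])


def expected_downstream_pass(annots: list[dict]) -> bool:
    ann = _severe_block(annots)
    if ann["BIOTYPE"] != "protein_coding":
        return False
    for key in ("AF", "ExAC_AF"):
        value = ann.get(key)
        if value is not None and not value < 0.01:
            return False
    if "synonymous_variant" in ann["Consequence"]:
        return False
    if all(a["IMPACT"] == "MODIFIER" for a in annots):
        return False
    return True


def expected_lof(annots: list[dict]) -> bool:
    ann = _severe_block(annots)
    return (
        "missense_variant" in ann["Consequence"]
        and str(ann.get("SIFT") or "").startswith("deleterious")
        and "damaging" in str(ann.get("PolyPhen") or "")
    )


# ---------------------------------------------------------------------------
# Documents
# ---------------------------------------------------------------------------

_CLASS_POSITIONS = {
    "clinical_trial": ("title", "abstract", "indication", "intervention", "full_text"),
}
_DEFAULT_POSITIONS = ("title", "abstract", "full_text", "raw_text")
_POSITION_P = (0.1, 0.3, 0.4, 0.2)
_TRIAL_POSITION_P = (0.1, 0.25, 0.25, 0.25, 0.15)


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _random_date(rng: np.random.Generator, ref: dt.date, max_age_days: float) -> dt.date:
    return ref - dt.timedelta(days=int(rng.uniform(0, max_age_days)))


def _make_document(
    rng: np.random.Generator,
    spec: CohortSpec,
    target: str,
    asset_class: str,
    index: int,
    planted: bool,
) -> dict:
    ref = spec.reference_date
    doc: dict = {
        "doc_id": f"{asset_class}:{target}:{index}",
        "asset_class": asset_class,
        "target": target,
    }
    if planted:
        doc["date"] = _random_date(rng, ref, 730).isoformat()
        doc["position"] = "title"
    else:
        doc["date"] = _random_date(rng, ref, spec.window_years * 365.25).isoformat()
        if asset_class == "clinical_trial":
            doc["position"] = str(
                rng.choice(_CLASS_POSITIONS["clinical_trial"], p=_TRIAL_POSITION_P)
            )
        else:
            doc["position"] = str(rng.choice(_DEFAULT_POSITIONS, p=_POSITION_P))
    if asset_class == "publication":
        if planted:
            doc["impact_factor"] = round(float(rng.uniform(25, 40)), 2)
            doc["citations"] = int(rng.poisson(50))
        else:
            doc["impact_factor"] = round(float(rng.lognormal(0.8, 0.55)), 2)
            doc["citations"] = int(rng.poisson(5))
    elif asset_class == "clinical_trial":
        if planted:
            doc["phase"], doc["status"] = 4, "completed"
        else:
            doc["phase"] = int(rng.choice([1, 2, 3, 4], p=[0.4, 0.3, 0.2, 0.1]))
            doc["status"] = str(
                rng.choice(
                    ["completed", "active", "recruiting", "terminated", "withdrawn"],
                    p=[0.35, 0.2, 0.25, 0.15, 0.05],
                )
            )
    return doc


def _generate_documents(
    rng: np.random.Generator,
    spec: CohortSpec,
    targets: list[str],
    planted_top: set[str],
    forced_novel: set[str],
) -> list[dict]:
    docs: list[dict] = []
    ref = spec.reference_date
    for target in targets:
        is_top = target in planted_top
        for asset_class in ASSET_CLASSES:
            rate = spec.asset_class_rates.get(asset_class, 0.0)
            count = _nb_count(rng, rate, spec.nb_dispersion)
            planted_extra = spec.planted_docs_per_class if is_top else 0
            for i in range(count + planted_extra):
                docs.append(
                    _make_document(rng, spec, target, asset_class, i, planted=i >= count)
                )
        if target in forced_novel:
            # Guarantee the first two novelty criteria: one recent
            # high-impact publication and one recent news mention.
            docs.append(
                {
                    "doc_id": f"publication:{target}:novelty",
                    "asset_class": "publication",
                    "target": target,
                    "date": _random_date(rng, ref, 3 * 365).isoformat(),
                    "position": "abstract",
                    "impact_factor": round(float(rng.uniform(9, 20)), 2),
                    "citations": int(rng.poisson(20)),
                }
            )
            docs.append(
                {
                    "doc_id": f"news:{target}:novelty",
                    "asset_class": "news",
                    "target": target,
                    "date": _random_date(rng, ref, 2 * 365).isoformat(),
                    "position": "title",
                }
            )
    return docs


# ---------------------------------------------------------------------------
# Differential expression table
# ---------------------------------------------------------------------------

def _generate_deg_table(
    rng: np.random.Generator,
    spec: CohortSpec,
    targets: list[str],
    planted_up: set[str],
    planted_down: set[str],
) -> pd.DataFrame:
    n_rep = spec.n_replicates
    rows = []
    log2_means = np.log2(rng.lognormal(4.0, 1.0, size=len(targets)))
    for gene, base in zip(targets, log2_means):
        if gene in planted_up:
            shift = spec.de_effect_log2fc
        elif gene in planted_down:
            shift = -spec.de_effect_log2fc
        else:
            shift = 0.0
        control = base + rng.normal(0, spec.de_noise_sd, size=n_rep)
        disease = base + shift + rng.normal(0, spec.de_noise_sd, size=n_rep)
        p = stats.ttest_ind(disease, control, equal_var=False).pvalue
        log2fc = float(disease.mean() - control.mean())
        rows.append(
            {
                "gene_symbol": gene,
                "control_mean": float(2.0 ** control.mean()),
                "disease_mean": float(2.0 ** disease.mean()),
                "log2fc": log2fc,
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["abs_log2fc"] = df["log2fc"].abs()
    df["regulation"] = np.select(
        [df["log2fc"] > 0, df["log2fc"] < 0], ["up", "down"], default=""
    )
    return df


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _passing_metrics() -> dict[str, float]:
    return dict(SAFE_METRICS)


def _random_metrics(rng: np.random.Generator, pass_fraction: float) -> dict:
    """Draw each metric from its passing range with probability q, where
    q ** 6 equals the requested overall pass fraction."""
    q = pass_fraction ** (1.0 / 6.0) if pass_fraction > 0 else 0.0
    ranges_pass = {
        "QD": (2.5, 35.0),
        "FS": (0.0, 55.0),
        "MQ": (42.0, 60.0),
        "MQRankSum": (-10.0, 10.0),
        "ReadPosRankSum": (-6.0, 6.0),
        "SOR": (0.2, 3.5),
    }
    ranges_fail = {
        "QD": (0.1, 1.8),
        "FS": (62.0, 200.0),
        "MQ": (10.0, 38.0),
        "MQRankSum": (-30.0, -13.0),
        "ReadPosRankSum": (-20.0, -8.5),
        "SOR": (4.2, 9.0),
    }
    metrics = {}
    for name in _THRESHOLDS:
        lo, hi = (ranges_pass if rng.uniform() < q else ranges_fail)[name]
        metrics[name] = round(float(rng.uniform(lo, hi)), 3)
    # Rank-sum statistics are sometimes absent (homozygous sites).
    for name in ("MQRankSum", "ReadPosRankSum"):
        if rng.uniform() < 0.05:
            metrics[name] = None
    return metrics


_CONSEQUENCE_IMPACT = {
    "missense_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "stop_gained": "HIGH",
    "intron_variant": "MODIFIER",
    "3_prime_UTR_variant": "MODIFIER",
}


def _random_annotation(rng: np.random.Generator, gene: str) -> dict:
    consequence = str(
        rng.choice(list(_CONSEQUENCE_IMPACT), p=[0.35, 0.2, 0.1, 0.25, 0.1])
    )
    ann = {
        "Gene": gene,
        "BIOTYPE": "protein_coding" if rng.uniform() < 0.9 else "lincRNA",
        "Consequence": consequence,
        "IMPACT": _CONSEQUENCE_IMPACT[consequence],
        "AF": round(float(rng.uniform(0.0001, 0.005)), 5)
        if rng.uniform() < 0.8
        else round(float(rng.uniform(0.02, 0.2)), 4),
        "ExAC_AF": round(float(rng.uniform(0.0001, 0.005)), 5)
        if rng.uniform() < 0.85
        else round(float(rng.uniform(0.02, 0.2)), 4),
        "SIFT": None,
        "PolyPhen": None,
    }
    if consequence == "missense_variant":
        ann["SIFT"] = str(
            rng.choice(
                ["deleterious(0.01)", "deleterious_low_confidence(0.03)", "tolerated(0.4)"],
                p=[0.4, 0.1, 0.5],
            )
        )
        ann["PolyPhen"] = str(
            rng.choice(
                ["probably_damaging(0.95)", "possibly_damaging(0.6)", "benign(0.1)"],
                p=[0.35, 0.2, 0.45],
            )
        )
    return ann


@dataclass
class _Variant:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    metrics: dict
    annotations: list[dict]  # one block per alt, in alt order
    rsid: Optional[str] = None

    def keys(self) -> list[VariantKey]:
        return [(self.chrom, self.pos, self.ref, alt) for alt in self.alts]


def _boundary_variants(pos_start: int, n_per_metric: int = 3) -> list[_Variant]:
    """Variants probing each threshold: at it, just above, just below.

    ``n_per_metric`` cycles through offsets -0.1, 0.0, +0.1 relative to the
    threshold, so 3 probes cover fail/at/pass for every metric and larger
    counts repeat the pattern at growing offsets.
    """
    variants = []
    pos = pos_start
    for name in _THRESHOLDS:
        for j in range(n_per_metric):
            step = 0.1 * (1 + j // 3)
            offset = (-step, 0.0, step)[j % 3]
            metrics = _passing_metrics()
            metrics[name] = round(_THRESHOLDS[name][1] + offset, 4)
            ann = {
                "Gene": "BOUNDARY",
                "BIOTYPE": "protein_coding",
                "Consequence": "missense_variant",
                "IMPACT": "MODERATE",
                "AF": 0.001,
                "ExAC_AF": 0.001,
                "SIFT": "tolerated(0.5)",
                "PolyPhen": "benign(0.1)",
            }
            variants.append(
                _Variant("chr1", pos, "A", ("G",), metrics, [ann])
            )
            pos += 10
    return variants


def _lof_combo_variants(pos_start: int) -> list[_Variant]:
    """Missense variants covering every SIFT x PolyPhen LOF combination,
    plus a non-missense deleterious/damaging control."""
    combos = [
        ("missense_variant", "deleterious(0.0)", "probably_damaging(0.99)"),
        ("missense_variant", "deleterious(0.02)", "possibly_damaging(0.55)"),
        ("missense_variant", "deleterious_low_confidence(0.04)", "probably_damaging(0.9)"),
        ("missense_variant", "tolerated(0.3)", "probably_damaging(0.92)"),
        ("missense_variant", "deleterious(0.01)", "benign(0.05)"),
        ("missense_variant", "tolerated(0.6)", "benign(0.01)"),
        ("missense_variant", None, "probably_damaging(0.97)"),
        ("missense_variant", "deleterious(0.0)", None),
        ("stop_gained", "deleterious(0.0)", "probably_damaging(0.99)"),
    ]
    variants = []
    for i, (consequence, sift, polyphen) in enumerate(combos):
        ann = {
            "Gene": "LOFCOMBO",
            "BIOTYPE": "protein_coding",
            "Consequence": consequence,
            "IMPACT": _CONSEQUENCE_IMPACT[consequence],
            "AF": 0.0005,
            "ExAC_AF": 0.0005,
            "SIFT": sift,
            "PolyPhen": polyphen,
        }
        variants.append(
            _Variant("chr2", pos_start + 10 * i, "C", ("T",), _passing_metrics(), [ann])
        )
    return variants


def _planted_variants(targets: list[str], pos_start: int) -> list[_Variant]:
    """Two passing variants per planted target: HIGH impact + LOF missense."""
    variants = []
    pos = pos_start
    for target in targets:
        high = {
            "Gene": target,
            "BIOTYPE": "protein_coding",
            "Consequence": "stop_gained",
            "IMPACT": "HIGH",
            "AF": 0.0002,
            "ExAC_AF": 0.0002,
            "SIFT": None,
            "PolyPhen": None,
        }
        lof = {
            "Gene": target,
            "BIOTYPE": "protein_coding",
            "Consequence": "missense_variant",
            "IMPACT": "MODERATE",
            "AF": 0.0003,
            "ExAC_AF": 0.0003,
            "SIFT": "deleterious(0.0)",
            "PolyPhen": "probably_damaging(0.99)",
        }
        variants.append(_Variant("chr3", pos, "G", ("T",), _passing_metrics(), [high]))
        variants.append(
            _Variant("chr3", pos + 5, "A", ("C",), _passing_metrics(), [lof])
        )
        pos += 20
    return variants


def _random_variants(
    rng: np.random.Generator,
    spec: CohortSpec,
    targets: list[str],
    n: int,
    pos_start: int,
) -> list[_Variant]:
    variants = []
    pos = pos_start
    for i in range(n):
        gene = str(rng.choice(targets))
        metrics = _random_metrics(rng, spec.variant_pass_fraction)
        if rng.uniform() < 0.05 and n - i >= 1:
            # occasional multi-allelic site, one CSQ block per alt
            alts = ("G", "T")
            annots = [_random_annotation(rng, gene), _random_annotation(rng, gene)]
            variants.append(_Variant("chr4", pos, "A", alts, metrics, annots))
        elif rng.uniform() < 0.1:
            variants.append(  # an INDEL
                _Variant("chr4", pos, "AT", ("A",), metrics,
                         [_random_annotation(rng, gene)])
            )
        else:
            variants.append(
                _Variant("chr4", pos, "A", ("G",), metrics,
                         [_random_annotation(rng, gene)])
            )
        pos += 10
    return variants


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=248956422>
##contig=<ID=chr2,length=242193529>
##contig=<ID=chr3,length=198295559>
##contig=<ID=chr4,length=190214555>
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand bias phred p-value">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio strand bias">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: Gene|BIOTYPE|Consequence|IMPACT|AF|ExAC_AF|SIFT|PolyPhen">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _format_csq(ann: dict) -> str:
    def fmt(value) -> str:
        return "" if value is None else str(value)

    return "|".join(
        fmt(ann.get(k))
        for k in ("Gene", "BIOTYPE", "Consequence", "IMPACT", "AF", "ExAC_AF", "SIFT", "PolyPhen")
    )


def write_vcf(variants: list[_Variant], path: str | Path) -> None:
    """Write variants as plain VCFv4.2 text (readable by htslib/pysam)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in variants:
            info_parts = []
            for name in _THRESHOLDS:
                value = v.metrics.get(name)
                if value is not None:
                    info_parts.append(f"{name}={value:g}")
            info_parts.append("CSQ=" + ",".join(_format_csq(a) for a in v.annotations))
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.rsid or ".",
                        v.ref,
                        ",".join(v.alts),
                        ".",
                        ".",
                        ";".join(info_parts),
                    ]
                )
                + "\n"
            )


def _label_variants(
    variants: list[_Variant],
) -> tuple[set[VariantKey], set[VariantKey], set[VariantKey]]:
    """(hard-pass keys, downstream-pass keys, LOF keys), from first principles."""
    hard, down, lof = set(), set(), set()
    for v in variants:
        if not expected_hard_pass(v.metrics):
            continue
        for i, key in enumerate(v.keys()):
            hard.add(key)
            blocks = [v.annotations[i]] if len(v.annotations) == len(v.alts) else v.annotations
            if expected_downstream_pass(blocks):
                down.add(key)
                if expected_lof(blocks):
                    lof.add(key)
    return hard, down, lof


def generate_vcf_fixture(
    spec: CohortSpec, path: str | Path, n_per_metric: int = 10
) -> list[tuple[VariantKey, bool]]:
    """Write a boundary-probing VCF fixture and return expected verdicts.

    Emits ``n_per_metric`` probes per hard-filter metric (cycling below /
    at / above each threshold), the LOF rule combinations, and random
    variants filling up to ``spec.n_variants`` records.  Returns
    ``(variant key, expected hard-filter pass)`` for every record, computed
    directly from the printed thresholds.
    """
    rng = np.random.default_rng(spec.seed)
    targets = [f"TG{i:04d}" for i in range(1, spec.n_targets + 1)]
    variants = _boundary_variants(10_000, n_per_metric=n_per_metric)
    variants += _lof_combo_variants(50_000)
    n_fill = max(spec.n_variants - len(variants), 0)
    variants += _random_variants(rng, spec, targets, n_fill, 100_000)
    write_vcf(variants, path)
    labels = []
    for v in variants:
        ok = expected_hard_pass(v.metrics)
        for key in v.keys():
            labels.append((key, ok))
    return labels


# ---------------------------------------------------------------------------
# Annotation-side planting and expected classifier labels
# ---------------------------------------------------------------------------

def _expected_druggability(has_structure, surface, drugs) -> tuple[str, str]:
    clinical = [d for d in drugs if d["max_phase"] >= 1]
    accessible = has_structure or surface
    if clinical and accessible:
        mods = {d["modality"] for d in clinical}
        return "highly", ("both" if len(mods) == 2 else mods.pop())
    if not clinical and accessible:
        if has_structure and surface:
            return "potentially", "both"
        return "potentially", ("small_molecule" if has_structure else "antibody")
    return "none", "none"


def _expected_safety(essential, drugs) -> str:
    for d in drugs:
        if d["withdrawal"] == "market" and d["reason_target_attributed"]:
            return "unsafe_market_withdrawal"
    for d in drugs:
        if d["withdrawal"] == "clinical" and d["reason_target_attributed"]:
            rescued = any(
                o is not d
                and o["status"] in ("active", "recruiting", "completed")
                and o["max_phase"] > d["max_phase"]
                for o in drugs
            )
            if not rescued:
                return "unsafe_clinical_withdrawal"
    return "unsafe_essential" if essential else "safe"


def _expected_novelty(ref, high_if_dates, news_dates, max_phase,
                      flags, mechanism) -> tuple[bool, str]:
    def within(dates, years):
        return any(0 <= (ref - d).days <= years * 365.25 for d in dates)

    novel = within(high_if_dates, 10) and within(news_dates, 5) and max_phase <= 1
    if not novel:
        return False, "n/a"
    if flags and flags <= {"expression_analysis", "mutation_analysis"}:
        return True, "unknown_knowns"
    return True, ("known_knowns" if mechanism else "known_unknowns")


def _expected_lung(levels: dict[str, str]) -> str:
    lung = levels.get("lung", "not_detected")
    others = [t for t, l in levels.items() if t != "lung" and l != "not_detected"]
    if lung != "not_detected" and not others:
        return "exclusive"
    if lung == "high" and others:
        return "high_shared"
    return "other"


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> GroundTruth:
    """Generate a full cohort under ``out_dir`` and return its ground truth.

    Writes: documents.jsonl, deg_table.csv, variants.vcf, pathways.gmt,
    disease_pathways.txt, db_targets.tsv, drugs.tsv, trials.tsv,
    annotations.tsv, biomarker_evidence.tsv and ground_truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference_date

    targets = [f"TG{i:04d}" for i in range(1, spec.n_targets + 1)]
    planted_top = set(
        map(str, rng.choice(targets, size=spec.n_planted_top, replace=False))
    )
    background = [t for t in targets if t not in planted_top]

    # --- role assignment for background targets -----------------------------
    shuffled = list(map(str, rng.permutation(background)))
    n_druggable = int(spec.frac_druggable * len(background))
    druggable = set(shuffled[:n_druggable])
    highly = set(shuffled[: n_druggable // 2])  # rest are 'potentially'

    # Unsafe targets come from the non-druggable tail of the shuffle so the
    # withdrawn drug is their only drug (no higher-phase rescue programme).
    n_unsafe = int(spec.frac_unsafe * len(background))
    unsafe_pool = shuffled[len(shuffled) - n_unsafe:] if n_unsafe else []
    unsafe_market = set(unsafe_pool[:1])
    unsafe_clinical = set(unsafe_pool[1:2])
    unsafe_essential = set(unsafe_pool[2:])

    forced_novel = set(
        map(str, rng.choice(background, size=int(spec.frac_novel * len(background)),
                            replace=False))
    )
    biomarker_targets = set(
        map(str, rng.choice(background,
                            size=int(spec.frac_biomarker * len(background)),
                            replace=False))
    ) | set(planted_top)

    # --- documents -----------------------------------------------------------
    documents = _generate_documents(rng, spec, targets, planted_top, forced_novel)
    with open(out / "documents.jsonl", "w") as fh:
        for doc in documents:
            fh.write(json.dumps(doc, sort_keys=True) + "\n")

    docs_by_target: dict[str, list[dict]] = {t: [] for t in targets}
    for doc in documents:
        docs_by_target[doc["target"]].append(doc)

    # --- differential expression ---------------------------------------------
    non_top = [t for t in targets if t not in planted_top]
    extra_up = list(
        map(str, rng.choice(non_top, size=max(spec.n_deg_up - len(planted_top), 0),
                            replace=False))
    )
    planted_up = (set(extra_up) | planted_top) if spec.n_deg_up else set()
    down_pool = [t for t in non_top if t not in planted_up]
    planted_down = set(
        map(str, rng.choice(down_pool, size=spec.n_deg_down, replace=False))
    )
    deg = _generate_deg_table(rng, spec, targets, planted_up, planted_down)
    deg.to_csv(out / "deg_table.csv", index=False)

    # --- variants -------------------------------------------------------------
    planted_sorted = sorted(planted_top)
    variants = _boundary_variants(10_000, n_per_metric=3)
    variants += _lof_combo_variants(50_000)
    variants += _planted_variants(planted_sorted, 70_000)
    n_fill = max(spec.n_variants - len(variants), 0)
    variants += _random_variants(rng, spec, targets, n_fill, 100_000)
    write_vcf(variants, out / "variants.vcf")
    hard_pass, downstream_pass, lof_keys = _label_variants(variants)
    mutated_genes = set()
    for v in variants:
        for i, key in enumerate(v.keys()):
            if key in downstream_pass:
                blocks = (
                    [v.annotations[i]]
                    if len(v.annotations) == len(v.alts)
                    else v.annotations
                )
                order = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}
                gene = min(blocks, key=lambda a: order[a["IMPACT"]])["Gene"]
                if gene in docs_by_target:
                    mutated_genes.add(gene)

    # --- pathways -------------------------------------------------------------
    disease_pathways = {f"DISEASE_PW_{i}" for i in range(1, DISEASE_PATHWAY_COUNT + 1)}
    gene_sets: dict[str, list[str]] = {}
    for name in sorted(disease_pathways):
        members = set(planted_sorted) | set(
            map(str, rng.choice(targets, size=max(len(targets) // 20, 5), replace=False))
        )
        gene_sets[name] = sorted(members)
    for i in range(1, BACKGROUND_PATHWAY_COUNT + 1):
        members = set(
            map(str, rng.choice(targets, size=max(len(targets) // 25, 5), replace=False))
        )
        gene_sets[f"PW_{i:03d}"] = sorted(members)
    with open(out / "pathways.gmt", "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic gene set"] + members) + "\n")
    with open(out / "disease_pathways.txt", "w") as fh:
        fh.write("\n".join(sorted(disease_pathways)) + "\n")

    # --- structured databases -------------------------------------------------
    db_rows = []
    for db in ("ClinVar", "Disgenet", "GWAS central", "GWAS"):
        frac = float(rng.uniform(0.1, 0.3))
        members = set(
            map(str, rng.choice(targets, size=int(frac * len(targets)), replace=False))
        )
        if db in ("Disgenet", "GWAS"):
            members |= planted_top
        for t in sorted(members):
            db_rows.append({"target": t, "database": db})
    pd.DataFrame(db_rows).to_csv(out / "db_targets.tsv", sep="\t", index=False)
    db_members = {r["target"] for r in db_rows}

    # --- drugs, annotations, biomarker evidence -------------------------------
    drug_rows: list[dict] = []
    ann_rows: list[dict] = []
    bio_rows: list[dict] = []
    planted_classes: dict[str, dict] = {}
    source_flags: dict[str, set[str]] = {}

    for target in targets:
        is_top = target in planted_top
        drugs: list[dict] = []
        if is_top:
            has_structure, surface = True, True
            essential, mechanism = False, True
            drugs = [
                {"drug": f"{target}-sm", "modality": "small_molecule", "max_phase": 4,
                 "status": "completed", "approved": True, "withdrawal": "none",
                 "reason_target_attributed": False},
                {"drug": f"{target}-ab", "modality": "antibody", "max_phase": 3,
                 "status": "active", "approved": False, "withdrawal": "none",
                 "reason_target_attributed": False},
            ]
            tissues = {"lung": "high", **{t: "not_detected" for t in OTHER_TISSUES}}
        else:
            in_druggable = target in druggable
            has_structure = in_druggable and bool(rng.uniform() < 0.8)
            surface = in_druggable and bool(rng.uniform() < 0.5)
            if in_druggable and not (has_structure or surface):
                has_structure = True
            essential = target in unsafe_essential
            mechanism = bool(rng.uniform() < 0.5)
            if target in highly:
                modality = str(rng.choice(["small_molecule", "antibody"]))
                phase = 1 if target in forced_novel else int(rng.choice([1, 2, 3, 4]))
                drugs.append(
                    {"drug": f"{target}-d1", "modality": modality, "max_phase": phase,
                     "status": str(rng.choice(["completed", "active", "recruiting"])),
                     "approved": bool(phase == 4 and rng.uniform() < 0.5),
                     "withdrawal": "none", "reason_target_attributed": False}
                )
            if target in unsafe_market:
                drugs.append(
                    {"drug": f"{target}-wd", "modality": "small_molecule",
                     "max_phase": 4, "status": "withdrawn", "approved": True,
                     "withdrawal": "market", "reason_target_attributed": True}
                )
            elif target in unsafe_clinical:
                drugs.append(
                    {"drug": f"{target}-wd", "modality": "small_molecule",
                     "max_phase": 2, "status": "terminated", "approved": False,
                     "withdrawal": "clinical", "reason_target_attributed": True}
                )
            tissues = {
                "lung": str(rng.choice(["not_detected", "low", "medium", "high"],
                                       p=[0.3, 0.3, 0.2, 0.2]))
            }
            for t in OTHER_TISSUES:
                tissues[t] = str(
                    rng.choice(["not_detected", "low", "medium", "high"],
                               p=[0.3, 0.3, 0.25, 0.15])
                )

        if target in biomarker_targets:
            n_cats = 1 + int(rng.uniform() < 0.15)
            cats = list(
                map(str, rng.choice(
                    ["diagnostic", "prognostic", "predictive", "therapeutic"],
                    size=n_cats, replace=False))
            )
            for cat in cats:
                bio_rows.append(
                    {"target": target, "category": cat, "citation": f"PMID:{rng.integers(1_000_000, 9_999_999)}"}
                )
            bio_cats = sorted(set(cats))
        else:
            bio_cats = []

        for d in drugs:
            drug_rows.append({**d, "target": target})

        target_docs = docs_by_target[target]
        high_if_dates = sorted(
            dt.date.fromisoformat(d["date"])
            for d in target_docs
            if d["asset_class"] == "publication" and (d.get("impact_factor") or 0) > 8
        )
        news_dates = sorted(
            dt.date.fromisoformat(d["date"])
            for d in target_docs
            if d["asset_class"] == "news"
        )

        flags = set()
        if target_docs:
            flags.add("literature")
        if target in db_members:
            flags.add("structured_genomic_db")
        if target in planted_up or target in planted_down:
            flags.add("expression_analysis")
        if target in mutated_genes:
            flags.add("mutation_analysis")
        source_flags[target] = flags

        ann_rows.append(
            {
                "target": target,
                "has_structure": has_structure,
                "surface_localized": surface,
                "essential_gene": essential,
                "mechanism_known": mechanism,
                **{f"tissue:{t}": level for t, level in tissues.items()},
                "highIF_pub_dates": ";".join(d.isoformat() for d in high_if_dates),
                "news_dates": ";".join(d.isoformat() for d in news_dates),
            }
        )

        dr_class, modality = _expected_druggability(has_structure, surface, drugs)
        max_phase = max((d["max_phase"] for d in drugs), default=0)
        novel, taxonomy = _expected_novelty(
            ref, high_if_dates, news_dates, max_phase, flags, mechanism
        )
        planted_classes[target] = {
            "druggability": dr_class,
            "modality": modality,
            "safety": _expected_safety(essential, drugs),
            "biomarker_categories": bio_cats,
            "novel": novel,
            "novelty_taxonomy": taxonomy,
            "lung_expression": _expected_lung(tissues),
        }

    pd.DataFrame(drug_rows)[
        ["drug", "target", "modality", "max_phase", "status", "approved",
         "withdrawal", "reason_target_attributed"]
    ].to_csv(out / "drugs.tsv", sep="\t", index=False)
    pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame(bio_rows, columns=["target", "category", "citation"]).to_csv(
        out / "biomarker_evidence.tsv", sep="\t", index=False
    )

    trial_rows = []
    for d in drug_rows:
        if d["max_phase"] >= 1:
            for j in range(int(rng.poisson(1.5)) + 1):
                trial_rows.append(
                    {
                        "trial_id": f"TR-{d['drug']}-{j}",
                        "target": d["target"],
                        "drug": d["drug"],
                        "sponsor": str(rng.choice(SPONSORS)),
                        "phase": d["max_phase"],
                        "status": d["status"],
                    }
                )
    pd.DataFrame(
        trial_rows, columns=["trial_id", "target", "drug", "sponsor", "phase", "status"]
    ).to_csv(out / "trials.tsv", sep="\t", index=False)

    truth = GroundTruth(
        targets=targets,
        planted_top_targets=planted_top,
        planted_up=planted_up,
        planted_down=planted_down,
        variants_expected_pass=hard_pass,
        variants_expected_downstream=downstream_pass,
        planted_lof=lof_keys,
        planted_classes=planted_classes,
        disease_pathways=disease_pathways,
        source_flags=source_flags,
    )
    (out / "ground_truth.json").write_text(truth.to_json())
    return truth
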