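"""Rule-based target evaluation.

Deterministic classifiers over per-target annotation facts:

* druggability — ``highly`` needs clinical precedence (a drug at phase >= 1
  against the target, any indication) plus a 3D structure or surface
  localization; ``potentially`` needs structure/surface without precedence;
  modality follows the precedent drugs (highly) or the structure/surface
  evidence (potentially: structure -> small molecule, surface -> antibody);
* safety — three unsafe groups evaluated in order with first-match
  semantics: target-attributed market withdrawal, target-attributed
  clinical withdrawal without a higher-phase rescue, essential gene;
* biomarker — union of tagged evidence categories (diagnostic, prognostic,
  predictive, therapeutic);
* novelty — high-impact-journal discussion (IF > 8) within 10 years AND a
  news mention within 5 years AND no clinical exploration beyond phase 1,
  with a known/unknown taxonomy from provenance;
* tissue expression — lung-exclusive / high-but-shared / other;
* pathway overlap and hypergeometric gene-set enrichment with
  Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import DrugRecord, TargetAnnotations, TargetProfile

BIOMARKER_CATEGORIES = ("diagnostic", "prognostic", "predictive", "therapeutic")
TISSUE_LEVELS = ("not_detected", "low", "medium", "high")

#: Trial statuses counting as ongoing/successful when deciding whether a
#: later drug programme rescues a target from a clinical-withdrawal flag.
RESCUE_STATUSES = frozenset({"active", "recruiting", "completed"})

NOVELTY_IF_THRESHOLD = 8.0
NOVELTY_PUB_WINDOW_YEARS = 10.0
NOVELTY_NEWS_WINDOW_YEARS = 5.0
NOVELTY_MAX_PHASE = 1


def classify_druggability(ann: TargetAnnotations) -> tuple[str, str]:
    """Return (druggability class, modality)."""
    accessible = ann.has_structure or ann.surface_localized
    clinical_drugs = [d for d in ann.drugs if d.max_phase >= 1]
    if clinical_drugs and accessible:
        modalities = {d.modality for d in clinical_drugs}
        if modalities >= {"small_molecule", "antibody"}:
            modality = "both"
        else:
            modality = next(iter(modalities))
        return "highly", modality
    if not clinical_drugs and accessible:
        if ann.has_structure and ann.surface_localized:
            modality = "both"
        elif ann.has_structure:
            modality = "small_molecule"
        else:
            modality = "antibody"
        return "potentially", modality
    return "none", "none"


def classify_safety(ann: TargetAnnotations) -> str:
    """First matching unsafe rule wins; withdrawals not attributed to the
    target do not flag it."""
    for d in ann.drugs:
        if d.withdrawal == "market" and d.reason_target_attributed:
            return "unsafe_market_withdrawal"
    for d in ann.drugs:
        if d.withdrawal == "clinical" and d.reason_target_attributed:
            rescued = any(
                other is not d
                and other.status in RESCUE_STATUSES
                and other.max_phase > d.max_phase
                for other in ann.drugs
            )
            if not rescued:
                return "unsafe_clinical_withdrawal"
    if ann.essential_gene:
        return "unsafe_essential"
    return "safe"


def classify_biomarker(ann: TargetAnnotations) -> set[str]:
    """Union of evidence categories; multi-category membership is allowed."""
    cats = set()
    for category, _citation in ann.biomarker_evidence:
        if category not in BIOMARKER_CATEGORIES:
            raise ValueError(f"unknown biomarker category {category!r}")
        cats.add(category)
    return cats


def classify_novelty(ann: TargetAnnotations, today: dt.date) -> tuple[bool, str]:
    """Three-criterion novelty rule plus the known/unknown taxonomy.

    Taxonomy (novel targets only): ``unknown_knowns`` when the target
    entered the cohort solely through the genomics arms; otherwise
    ``known_knowns`` when mechanistic literature evidence exists, else
    ``known_unknowns``.
    """
    def within(dates: Sequence[dt.date], years: float) -> bool:
        cutoff = years * 365.25
        return any(0 <= (today - d).days <= cutoff for d in dates)

    novel = (
        within(ann.highIF_pub_dates, NOVELTY_PUB_WINDOW_YEARS)
        and within(ann.news_dates, NOVELTY_NEWS_WINDOW_YEARS)
        and ann.max_drug_phase <= NOVELTY_MAX_PHASE
    )
    if not novel:
        return False, "n/a"
    genomics_only = bool(ann.source_flags) and ann.source_flags <= {
        "expression_analysis",
        "mutation_analysis",
    }
    if genomics_only:
        return True, "unknown_knowns"
    if ann.mechanism_known:
        return True, "known_knowns"
    return True, "known_unknowns"


def classify_tissue(ann: TargetAnnotations, tissue: str = "lung") -> str:
    """Lung-expression class: exclusive, high_shared, or other.

    ``exclusive``: detected (at least low) in the lung and nowhere else.
    ``high_shared``: high in the lung with at least one other tissue
    detected.  A missing lung entry is treated as not detected.
    """
    levels = ann.tissue_expression
    for level in levels.values():
        if level not in TISSUE_LEVELS:
            raise ValueError(f"unknown tissue level {level!r}")
    lung = levels.get(tissue, "not_detected")
    others_detected = [
        t for t, level in levels.items() if t != tissue and level != "not_detected"
    ]
    if lung != "not_detected" and not others_detected:
        return "exclusive"
    if lung == "high" and others_detected:
        return "high_shared"
    return "other"


def pathway_overlap(target_pathways: Iterable[str], disease_pathways: Iterable[str]) -> int:
    """Number of shared pathways between a target and the disease set."""
    return len(set(target_pathways) & set(disease_pathways))


def enrich_pathways(
    targets: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a target set in gene sets.

    For each pathway with K members in a universe of size N, the p-value is
    the upper tail P(X >= k) of a hypergeometric draw of n = |targets|,
    where k is the observed overlap.  P-values are BH-adjusted across
    pathways and the result is sorted by adjusted p (ties by pathway name).
    """
    universe_set = set(universe)
    target_set = set(targets) & universe_set
    if set(targets) - universe_set:
        raise ValueError("target set must be a subset of the universe")
    if not target_set:
        return pd.DataFrame(
            columns=["pathway", "overlap", "set_size", "p_value", "p_adj"]
        )
    big_n, small_n = len(universe_set), len(target_set)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe_set
        k = len(members & target_set)
        p = float(hypergeom.sf(k - 1, big_n, len(members), small_n))
        rows.append({"pathway": name, "overlap": k, "set_size": len(members), "p_value": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_adj", "p_value", "pathway"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Table loaders
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one gene set per line (name, description, members)."""
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            gene_sets[parts[0]] = {g for g in parts[2:] if g}
    return gene_sets


def _as_bool(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes"}


def load_annotations(
    annotations_tsv: str | Path,
    drugs_tsv: Optional[str | Path] = None,
    biomarker_tsv: Optional[str | Path] = None,
    pathways_gmt: Optional[str | Path] = None,
) -> dict[str, TargetAnnotations]:
    """Assemble :class:`TargetAnnotations` from the evaluation input tables.

    ``annotations.tsv`` carries one row per target with structure /
    localization / essentiality / mechanism flags, tissue levels as
    ``tissue:<name>`` columns, and semicolon-separated high-impact
    publication and news dates.  Drugs and biomarker evidence arrive in
    their own tables; pathway membership from a GMT collection.
    """
    df = pd.read_csv(annotations_tsv, sep="\t")
    tissue_cols = [c for c in df.columns if c.startswith("tissue:")]
    ann_map: dict[str, TargetAnnotations] = {}
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        target = str(rec["target"]).upper()
        def dates(col: str) -> list[dt.date]:
            raw = rec.get(col)
            if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
                return []
            return [dt.date.fromisoformat(s) for s in str(raw).split(";") if s]
        ann_map[target] = TargetAnnotations(
            target=target,
            has_structure=_as_bool(rec.get("has_structure", False)),
            surface_localized=_as_bool(rec.get("surface_localized", False)),
            essential_gene=_as_bool(rec.get("essential_gene", False)),
            mechanism_known=_as_bool(rec.get("mechanism_known", False)),
            tissue_expression={
                c.split(":", 1)[1]: str(rec[c]) for c in tissue_cols
            },
            highIF_pub_dates=dates("highIF_pub_dates"),
            news_dates=dates("news_dates"),
        )
    if drugs_tsv is not None:
        drugs = pd.read_csv(drugs_tsv, sep="\t")
        for rec in drugs.to_dict("records"):
            target = str(rec["target"]).upper()
            if target not in ann_map:
                ann_map[target] = TargetAnnotations(target=target)
            ann_map[target].drugs.append(
                DrugRecord(
                    drug=str(rec["drug"]),
                    target=target,
                    modality=str(rec["modality"]),
                    max_phase=int(rec["max_phase"]),
                    status=str(rec["status"]),
                    approved=_as_bool(rec.get("approved", False)),
                    withdrawal=str(rec.get("withdrawal", "none")),
                    reason_target_attributed=_as_bool(
                        rec.get("reason_target_attributed", False)
                    ),
                )
            )
    if biomarker_tsv is not None:
        bio = pd.read_csv(biomarker_tsv, sep="\t")
        for rec in bio.to_dict("records"):
            target = str(rec["target"]).upper()
            if target not in ann_map:
                ann_map[target] = TargetAnnotations(target=target)
            ann_map[target].biomarker_evidence.append(
                (str(rec["category"]), str(rec.get("citation", "")))
            )
    if pathways_gmt is not None:
        for name, members in read_gmt(pathways_gmt).items():
            for gene in members:
                gene = gene.upper()
                if gene in ann_map:
                    ann_map[gene].pathways.add(name)
    return ann_map


def evaluate_target(
    ann: TargetAnnotations,
    disease_pathways: Iterable[str],
    today: dt.date,
) -> TargetProfile:
    """Run every classifier on one target's annotations."""
    druggability, modality = classify_druggability(ann)
    novel, taxonomy = classify_novelty(ann, today)
    return TargetProfile(
        target=ann.target,
        druggability=druggability,
        modality=modality,
        safety=classify_safety(ann),
        biomarker_categories=classify_biomarker(ann),
        novel=novel,
        novelty_taxonomy=taxonomy,
        lung_expression=classify_tissue(ann),
        pathway_overlap_count=pathway_overlap(ann.pathways, disease_pathways),
    )


def evaluate_targets(
    annotations: Mapping[str, TargetAnnotations],
    disease_pathways: Iterable[str],
    today: dt.date,
) -> dict[str, TargetProfile]:
    disease = set(disease_pathways)
    return {
        target: evaluate_target(ann, disease, today)
        for target, ann in annotations.items()
    }


def profiles_table(profiles: Mapping[str, TargetProfile]) -> pd.DataFrame:
    """Flatten profiles into a tidy frame (for profiles.csv)."""
    rows = []
    for target in sorted(profiles):
        p = profiles[target]
        rows.append(
            {
                "target": p.target,
                "druggability": p.druggability,
                "modality": p.modality,
                "safety": p.safety,
                "biomarker_categories": ";".join(sorted(p.biomarker_categories)),
                "novel": p.novel,
                "novelty_taxonomy": p.novelty_taxonomy,
                "lung_expression": p.lung_expression,
                "pathway_overlap_count": p.pathway_overlap_count,
            }
        )
    return pd.DataFrame(rows)


def sponsor_trial_counts(trials_tsv: str | Path) -> pd.DataFrame:
    """Trials-per-sponsor summary from a trials table (competitive view)."""
    trials = pd.read_csv(trials_tsv, sep="\t")
    return (
        trials.groupby("sponsor")
        .size()
        .rename("n_trials")
        .sort_values(ascending=False)
        .reset_index()
    )
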