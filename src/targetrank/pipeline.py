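"""End-to-end run: cohort directory in, ranked target list out.

Wires the modules together in the sourcing -> evaluation -> prioritization
order: DE and variant post-processing produce the genomics survivor sets;
ingest merges them with the literature documents and structured-database
tables; the relevance cascade filters the merged list; survivors are scored
per asset class, evaluated by the rule-based classifiers, and combined into
the 40/60 weighted ranking.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import evaluation, genomics, literature, prioritize
from .config import ScoringConfig
from .ingest import (
    account_sources,
    accounting_table,
    ingest as ingest_evidence,
    read_db_table,
    read_documents,
)
from .models import PriorityScore, SourceAccounting, TargetEvidence, TargetProfile
from .prioritize import WeightConfig


@dataclass
class PipelineResult:
    ranking: pd.DataFrame
    scores: list[PriorityScore]
    accounting: SourceAccounting
    evidence: list[TargetEvidence]
    survivors: list[TargetEvidence]
    exclusions: list[tuple[str, str]]
    profiles: dict[str, TargetProfile]
    deg_counts: dict[str, int]
    gene_impacts: pd.DataFrame

    @property
    def ranked_targets(self) -> list[str]:
        return [s.target for s in self.scores]


def run_pipeline(
    cohort_dir: str | Path,
    out_dir: Optional[str | Path] = None,
    scoring: Optional[ScoringConfig] = None,
    weights: Optional[WeightConfig] = None,
    today: Optional[dt.date] = None,
    padj_max: float = 0.05,
    abs_lfc_min: float = 1.0,
) -> PipelineResult:
    """Run the full pipeline on a cohort directory.

    ``today`` anchors recency and novelty windows; when omitted it defaults
    to the newest document date, which keeps a stored cohort reproducible
    regardless of when it is re-analysed.  When ``out_dir`` is given, the
    ranking, accounting, profiles, exclusion log and a run log are written
    there as CSV/JSON.
    """
    cohort = Path(cohort_dir)
    scoring = scoring or ScoringConfig()
    weights = weights or WeightConfig()

    # --- genomics arms -------------------------------------------------------
    deg_table = genomics.read_deg_table(cohort / "deg_table.csv")
    deg_survivors, deg_counts = genomics.select_significant(
        deg_table, padj_max=padj_max, abs_lfc_min=abs_lfc_min
    )
    deg_genes = set(deg_survivors["gene_symbol"].str.upper())

    variants = genomics.read_vcf(cohort / "variants.vcf")
    variant_survivors = genomics.apply_variant_filters(variants)
    gene_impacts = genomics.classify_impact(variant_survivors)
    variant_genes = set(gene_impacts.index.str.upper())

    # --- ingest and accounting -----------------------------------------------
    documents, _skipped = read_documents(cohort / "documents.jsonl")
    db_path = cohort / "db_targets.tsv"
    db_table = read_db_table(db_path) if db_path.exists() else None
    evidence = ingest_evidence(
        documents=documents,
        db_table=db_table,
        deg_survivors=deg_genes,
        variant_survivors=variant_genes,
    )
    accounting = account_sources(evidence)

    # --- relevance cascade ---------------------------------------------------
    gene_sets = evaluation.read_gmt(cohort / "pathways.gmt")
    disease_path = cohort / "disease_pathways.txt"
    disease_pathways = (
        {line.strip() for line in disease_path.read_text().splitlines() if line.strip()}
        if disease_path.exists()
        else set()
    )
    pathway_map: dict[str, set[str]] = {}
    for name, members in gene_sets.items():
        for gene in members:
            pathway_map.setdefault(gene.upper(), set()).add(name)
    survivors, exclusions = literature.relevance_filter(
        evidence,
        disease_pathways=disease_pathways,
        pathway_map=pathway_map,
        min_total_docs=scoring.min_total_docs,
    )

    if today is None:
        today = max((doc.date for doc in documents), default=dt.date.today())

    # --- literature scores ---------------------------------------------------
    matrix = literature.score_matrix(survivors, scoring, today, scaled=True)

    # --- evaluation ----------------------------------------------------------
    annotations = evaluation.load_annotations(
        cohort / "annotations.tsv",
        drugs_tsv=cohort / "drugs.tsv" if (cohort / "drugs.tsv").exists() else None,
        biomarker_tsv=(
            cohort / "biomarker_evidence.tsv"
            if (cohort / "biomarker_evidence.tsv").exists()
            else None
        ),
        pathways_gmt=cohort / "pathways.gmt",
    )
    by_target = {ev.target: ev for ev in survivors}
    for target, ann in annotations.items():
        if target in by_target:
            ann.source_flags = set(by_target[target].source_flags)
    profiles = {}
    for target in by_target:
        ann = annotations.get(target) or evaluation.TargetAnnotations(target=target)
        profiles[target] = evaluation.evaluate_target(ann, disease_pathways, today)

    # --- prioritization ------------------------------------------------------
    scores = []
    param_rows = {}
    for target, profile in profiles.items():
        headline = (
            str(gene_impacts.loc[target, "headline_impact"])
            if target in gene_impacts.index
            else None
        )
        params = prioritize.disease_parameter_scores(
            profile,
            deg_survivor=target in deg_genes,
            variant_headline_impact=headline,
        )
        param_rows[target] = params
        scores.append(
            prioritize.combine(
                matrix.loc[target].to_dict(), params, weights, target=target
            )
        )
    ranked = prioritize.rank(scores)

    ranking = prioritize.ranking_table(ranked)
    param_df = pd.DataFrame.from_dict(param_rows, orient="index").rename_axis("target")
    ranking = ranking.merge(
        matrix.add_prefix("lit:"), left_on="target", right_index=True, how="left"
    ).merge(param_df.add_prefix("param:"), left_on="target", right_index=True, how="left")

    result = PipelineResult(
        ranking=ranking,
        scores=ranked,
        accounting=accounting,
        evidence=evidence,
        survivors=survivors,
        exclusions=exclusions,
        profiles=profiles,
        deg_counts=deg_counts,
        gene_impacts=gene_impacts,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ranking.to_csv(out / "ranked_targets.csv", index=False)
        accounting_table(accounting).to_csv(out / "accounting.csv", index=False)
        evaluation.profiles_table(profiles).to_csv(out / "profiles.csv", index=False)
        pd.DataFrame(exclusions, columns=["target", "rule"]).to_csv(
            out / "exclusions.csv", index=False
        )
        gene_impacts.to_csv(out / "gene_variant_counts.csv")
        run_log = {
            "cohort_dir": str(cohort),
            "today": today.isoformat(),
            "padj_max": padj_max,
            "abs_lfc_min": abs_lfc_min,
            "config_hash": prioritize.config_hash(scoring, weights),
            "n_targets_ingested": accounting.unique_total,
            "n_survivors": len(survivors),
            "deg_counts": deg_counts,
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1))

    return result
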