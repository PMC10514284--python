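"""Evidence ingest and source accounting.

Merges the three sourcing arms — unstructured literature documents,
structured genomic databases, and the genomics raw-data analyses
(differential expression + variant calling) — into one unique target list
keyed by uppercased gene symbol, with full provenance, and reproduces the
per-source accounting (row counts, arm totals, grand and unique totals).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .config import ASSET_CLASSES
from .models import EvidenceDocument, SourceAccounting, TargetEvidence

logger = logging.getLogger(__name__)

LITERATURE_SOURCES = ASSET_CLASSES
STRUCTURED_DB_NAMES = ("ClinVar", "Disgenet", "GWAS central", "GWAS")
GENOMICS_SOURCES = ("expression_analysis", "mutation_analysis")


def normalize_symbol(symbol: str, alias_map: Optional[Mapping[str, str]] = None) -> str:
    """Uppercase a gene symbol and resolve it through an optional alias map."""
    sym = symbol.strip().upper()
    if alias_map:
        sym = alias_map.get(sym, sym)
    return sym


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (alias, canonical) into an uppercased map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "canonical"])
    return {
        str(a).strip().upper(): str(c).strip().upper()
        for a, c in zip(df["alias"], df["canonical"])
    }


def read_documents(
    path: str | Path,
    alias_map: Optional[Mapping[str, str]] = None,
    relevance_min: Optional[float] = None,
) -> tuple[list[EvidenceDocument], int]:
    """Read a JSONL documents file; returns (documents, skipped row count).

    Unparseable rows (bad JSON, unknown asset class, missing target or date)
    are logged and skipped rather than aborting the run.  When
    ``relevance_min`` is given, rows with a relevance score below it are
    dropped; rows without a score are always accepted.
    """
    docs: list[EvidenceDocument] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                raw = json.loads(line)
                target = normalize_symbol(raw["target"], alias_map)
                if not target:
                    raise ValueError("empty target symbol")
                asset_class = raw["asset_class"]
                if asset_class not in ASSET_CLASSES:
                    raise ValueError(f"unknown asset class {asset_class!r}")
                doc = EvidenceDocument(
                    doc_id=str(raw["doc_id"]),
                    asset_class=asset_class,
                    target=target,
                    date=dt.date.fromisoformat(raw["date"]),
                    position=raw.get("position"),
                    impact_factor=raw.get("impact_factor"),
                    citations=raw.get("citations"),
                    phase=raw.get("phase"),
                    status=raw.get("status"),
                    relevance=raw.get("relevance"),
                )
            except (KeyError, ValueError, TypeError) as exc:
                logger.warning("skipping line %d of %s: %s", lineno, path, exc)
                skipped += 1
                continue
            if (
                relevance_min is not None
                and doc.relevance is not None
                and doc.relevance < relevance_min
            ):
                continue
            docs.append(doc)
    if skipped:
        logger.info("skipped %d unparseable rows in %s", skipped, path)
    return docs, skipped


def read_db_table(path: str | Path) -> pd.DataFrame:
    """Read a structured-database TSV with columns target, database."""
    df = pd.read_csv(path, sep="\t")
    for col in ("target", "database"):
        if col not in df.columns:
            raise ValueError(f"database table {path} lacks column {col!r}")
    return df


def ingest(
    documents: Iterable[EvidenceDocument] = (),
    db_table: Optional[pd.DataFrame] = None,
    deg_survivors: Iterable[str] = (),
    variant_survivors: Iterable[str] = (),
    alias_map: Optional[Mapping[str, str]] = None,
) -> list[TargetEvidence]:
    """Merge all sourcing arms into one :class:`TargetEvidence` per symbol.

    Symbols are uppercased (and alias-resolved) before merging, so ``il13``
    and ``IL13`` land on the same record.  Provenance is kept in
    ``source_flags`` (which arms saw the target) and ``db_names`` (which
    structured databases reported it).
    """
    evidence: dict[str, TargetEvidence] = {}

    def entry(symbol: str) -> TargetEvidence:
        sym = normalize_symbol(symbol, alias_map)
        return evidence.setdefault(sym, TargetEvidence(target=sym))

    for doc in documents:
        ev = entry(doc.target)
        ev.docs_by_class.setdefault(doc.asset_class, []).append(doc)
        ev.source_flags.add("literature")

    if db_table is not None:
        for target, database in zip(db_table["target"], db_table["database"]):
            ev = entry(str(target))
            ev.source_flags.add("structured_genomic_db")
            ev.db_names.add(str(database))

    for symbol in deg_survivors:
        entry(symbol).source_flags.add("expression_analysis")
    for symbol in variant_survivors:
        entry(symbol).source_flags.add("mutation_analysis")

    return sorted(evidence.values(), key=lambda ev: ev.target)


def account_sources(evidence: Iterable[TargetEvidence]) -> SourceAccounting:
    """Derive per-source target counts and arm totals from merged evidence.

    A target contributes once to every literature asset class it has
    documents in, once per structured database that reported it, and once
    per genomics arm flag — so the grand total counts with multiplicity
    while ``unique_total`` counts distinct symbols.
    """
    evidence = list(evidence)
    counts: dict[str, int] = {}
    for cls in LITERATURE_SOURCES:
        counts[cls] = sum(1 for ev in evidence if ev.docs_by_class.get(cls))
    for db in sorted({name for ev in evidence for name in ev.db_names}):
        counts[db] = sum(1 for ev in evidence if db in ev.db_names)
    for arm in GENOMICS_SOURCES:
        counts[arm] = sum(1 for ev in evidence if arm in ev.source_flags)
    return accounting_from_counts(
        literature={cls: counts[cls] for cls in LITERATURE_SOURCES},
        structured={k: v for k, v in counts.items()
                    if k not in LITERATURE_SOURCES and k not in GENOMICS_SOURCES},
        genomics={arm: counts[arm] for arm in GENOMICS_SOURCES},
        unique_total=len({ev.target for ev in evidence}),
    )


def accounting_from_counts(
    literature: Mapping[str, int],
    structured: Mapping[str, int],
    genomics: Mapping[str, int],
    unique_total: Optional[int] = None,
) -> SourceAccounting:
    """Build a :class:`SourceAccounting` from printed per-row target counts."""
    per_source = {**literature, **structured, **genomics}
    lit_total = sum(literature.values())
    struct_total = sum(structured.values())
    genom_total = sum(genomics.values())
    grand = lit_total + struct_total + genom_total
    if unique_total is not None and unique_total > grand:
        raise ValueError("unique_total cannot exceed grand_total")
    return SourceAccounting(
        per_source_target_counts=dict(per_source),
        literature_total=lit_total,
        structured_total=struct_total,
        genomics_total=genom_total,
        grand_total=grand,
        unique_total=unique_total,
    )


def accounting_table(acc: SourceAccounting) -> pd.DataFrame:
    """Render an accounting as a tidy frame (one row per source + totals)."""
    rows = [{"source": k, "target_count": v} for k, v in acc.per_source_target_counts.items()]
    rows.append({"source": "total", "target_count": acc.grand_total})
    return pd.DataFrame(rows)


class OverlapPartition(NamedTuple):
    only_a: int
    only_b: int
    both: int

    @property
    def union(self) -> int:
        return self.only_a + self.only_b + self.both


def overlap_partition(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapPartition:
    """Partition two symbol sets into exclusive and shared counts."""
    a, b = set(set_a), set(set_b)
    return OverlapPartition(len(a - b), len(b - a), len(a & b))
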