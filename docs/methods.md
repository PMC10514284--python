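# Methods

This note documents the models, rules and numerical choices behind
`targetrank`, and what its synthetic benchmarks do and do not demonstrate.

## Pipeline model

The pipeline treats target triage as three stages over a universe of gene
symbols (uppercased; an optional alias table maps synonyms before merging).

**Sourcing.** Three arms contribute evidence: literature documents in seven
asset classes; structured genomic databases (arriving as a plain
target×database table — no API access is attempted); and genomics raw-data
post-processing.  The genomics arm consumes the *outputs* of the standard
upstream tools — a differential-expression result table and a VEP-style
annotated VCF — because alignment, variant calling and consequence
prediction are solved problems with canonical tools and re-running them is
outside this package's scope.  Source accounting counts one row per
(source, target) pair, so the grand total counts with multiplicity while
the unique total is the union cardinality; the two are related by the
overlap-partition identity `only_a + only_b + both = |A ∪ B|` used to
cross-check the arms.

**Document scoring.** Each scored attribute maps into [0, 1]:

| component | transform | default |
|---|---|---|
| recency | `2^(−age_years / half_life)` | half-life 5 y |
| impact factor | `min(IF, cap) / cap` | cap 30 |
| position | lookup | title 1.0, abstract 0.8, indication/intervention 0.7, full text 0.4, raw text 0.2 |
| trial phase | lookup | 4→1.0, 3→0.8, 2→0.6, 1→0.4 |
| trial status | lookup | completed/active 1.0, recruiting 0.8, terminated/withdrawn 0.2 |
| citations (optional, off) | `log1p(c)/log1p(cap)` | cap 1000 |

Publications score recency + impact factor + position; clinical trials
score status + phase + position; every other class scores recency +
position.  The scoring scheme names these attributes but publishes no
weighting values, so the tables above are this package's explicit,
config-visible stand-ins: each was chosen to be bounded, monotone in the
attribute it encodes, and ordered the way the attribute is ordered in the
field (e.g. positions by specificity of the mention).  The exponential
recency kernel was chosen over a linear window because it is smooth,
strictly monotone and never negative; its half-life is the single tunable.
Citation counts are scored only when explicitly enabled because citation
and impact-factor signals are strongly collinear.

Per-target class scores are sums over that class's documents (so they are
additive and monotone under document addition), then min–max scaled within
each class across the cohort: minimum→0, maximum→1, all-equal→0 by
convention.  Scaling is the only cohort-dependent step in the literature
arm.

**Relevance cascade.** A target is kept iff it has ≥ 20 total documents
(all classes counted equally, theses and news included) AND (documents in
≥ 2 asset classes OR a non-empty overlap between its annotated pathways and
the disease pathway set).  The cascade is a per-target predicate, hence
order-independent, and each exclusion is logged with the rule that fired.

**Variant filtering.** Hard-filter comparisons are strict exactly as
printed (`QD > 2`, `FS < 60`, `MQ > 40`, `MQRankSum > −12.5`,
`ReadPosRankSum > −8`, `SOR < 4`); a value equal to its threshold fails
that metric.  A single threshold set is applied to SNPs and INDELs alike,
as printed, even though separate sets are common practice.  An absent
rank-sum metric (typical at homozygous sites) passes by default
(configurable), matching common hard-filtering practice.  Multi-allelic
records are split per alternate allele before filtering; when a record
carries exactly one annotation block per allele the blocks are matched
positionally, otherwise all blocks attach to each split allele.  The
downstream filter evaluates biotype, allele frequencies and consequence on
the most severe annotation block (HIGH > MODERATE > LOW > MODIFIER) and
fails the impact rule only when *every* block is MODIFIER; absent
AF/ExAC_AF counts as rare (< 0.01), configurable.  LOF scope is missense
only: SIFT beginning with `deleterious` and PolyPhen containing `damaging`
(both `probably_` and `possibly_` accepted by default; a switch restricts
to `probably_`).  Because htslib stores Float INFO values in single
precision, the reader rounds metrics to four decimals so values compare as
written.

**DEG post-processing.** Regulation is the sign of log2FC (`up` for > 0,
`down` for < 0); a log2FC of exactly 0 is unregulated and excluded from
up/down tallies.  Significance defaults to `p_adj ≤ 0.05` and
`|log2FC| ≥ 1`, configurable — the source workflow reports "significant"
genes without printing its thresholds, and these are the field's customary
defaults.  Selection is anti-monotone in both thresholds by construction.

**Evaluation rules.** Clinical precedence means at least one drug with
maximum phase ≥ 1 against the target in *any* indication.  Safety rules
run in fixed order with first-match semantics (market withdrawal →
clinical withdrawal → essential gene); withdrawals not attributed to the
target never flag it, and a clinical withdrawal is rescued by another drug
programme at a higher phase with ongoing/successful status.  Essentiality
is an input column (a curated essential-gene list), not derived.  The
novelty taxonomy separates targets by provenance and a mechanism flag:
genomics-only provenance → unknown knowns; otherwise mechanism known →
known knowns, else known unknowns.  The mechanism criterion is narrative
in origin, so it is an explicit input column rather than an inferred
quantity.  Enrichment is the minimal standard choice — one-sided
hypergeometric upper tail with Benjamini–Hochberg adjustment over the
supplied gene-set collection, universe = the cohort annotation table.

**Prioritization.** Default weights are exactly the published percentages
(literature 12/3/9/4/6/6 summing to 40; disease 12/9/3/3/12/9/12 summing
to 60).  Theses are folded into the literature arm for accounting and the
relevance threshold but carry zero weight, because the weighted split
enumerates six classes.  How each evaluated parameter becomes a number in
[0, 1] is not published; the rules live in one table
(`disease_parameter_scores`): druggability 1 / 0.5 / 0; pathway overlap
`min(count/5, 1)`; biomarker any-category indicator; safety 1 only when
safe — unsafe targets are *down-weighted, not removed*; expression &
mutation = mean of a DEG-survivor indicator and the headline variant
severity (HIGH 1.0, MODERATE 0.6, LOW 0.3); tissue 1 / 0.7 / 0.2; novelty
indicator.  Totals are reported raw on the 0–100 scale with no second
cohort-wide rescaling.  Ranks are assigned by descending total with
alphabetical tie-break, so rankings are deterministic and
permutation-invariant.  User re-weighting supports a `strict` policy
(overrides must preserve the 40/60 sums) and a `normalize` policy
(non-overridden weights on the same side are rescaled proportionally).

## Synthetic cohorts

The generator emulates the statistical shape of a triage corpus, not its
content: documents are attribute bundles with no text.  Per-target
per-class document counts are negative binomial (dispersion 1.5) around
configurable class rates (defaults: publications 8, patents 3, congresses
2.5, grants 2, news 2, trials 1.5, theses 0.8 per target) — literature
counts are heavily over-dispersed in practice, which a Poisson would
understate.  Dates are uniform over a 15-year window behind a fixed
reference date (2023-01-01); impact factors are log-normal (median ≈ 2.2,
~1% above 8); positions, phases and statuses are categorical.  All
randomness flows through one seeded generator, so identical specs yield
byte-identical files.

Planted-top targets receive the relevance-threshold number of documents
(20) in every asset class with saturated attributes (recent, title
position, impact factor above the cap, phase-4 completed trials), disease
pathway membership, clinical-stage drugs of both modalities with structure
and surface localization, lung-exclusive expression, an up-regulated DEG
row, and two passing variants (one HIGH-impact, one LOF missense).  They
deliberately fail the novelty rule (late-phase drugs), mirroring the fact
that saturated, clinically precedented targets are not novel.

The DE table simulates five replicates per group in log2 space with
replicate noise SD 0.3; planted genes are shifted ±2 log2 units (the
default effect), p-values come from Welch's t-test and are BH-adjusted.
The default planted condition is 126 up- and 14 down-regulated genes in a
500-target cohort.  The VCF mixes boundary probes (each hard-filter metric
at, 0.1 below and 0.1 above its threshold), a block covering every
SIFT×PolyPhen LOF combination, the planted variants, multi-allelic and
INDEL records, and random variants whose per-metric pass probability is
set to the sixth root of the requested overall pass fraction (default
0.6).  Expected verdicts and classifier labels are computed inside the
generator from first principles, independently of the analysis modules, so
they serve as oracles.

What passing these benchmarks shows: the decision logic (scoring,
cascade, filters, classifiers, weighting, ranking) is implemented exactly
and recovers planted signal with complete separation.  What it does not
show: performance on real corpora — real literature counts are not
negative binomial with known rates, real annotation tables are incomplete
and inconsistent, gene-symbol aliasing is messier than an alias TSV, and
the generator plants no adversarial near-ties between planted and
background targets.

## Problem sizes and numerical choices

The default benchmark cohort is 500 targets / 10 planted (about 10,000
documents and 600 variant records), which a full pipeline run processes in
about two seconds; the recovery suite repeats it over 20 seeds, and the
boundary fixture uses ≥ 500 variants with 10 probes per metric.  These
sizes give complete planted/background separation while keeping the whole
suite under a minute.  Degenerate inputs are handled explicitly: empty
document files ingest to an empty list; an all-equal score vector scales
to zeros; an empty survivor set yields an empty tally; an empty target set
yields an empty enrichment table; weight-sum violations abort before any
scoring.  Rank ties break alphabetically; min–max scaling leaves equal raw
scores equal.

## Known limitations

* Proprietary upstream steps (ontology search, corpus relevance scoring,
  TF–IDF concept relevancy) are represented by their observable outputs
  (an optional per-document relevance column with a cut-off; the mention
  position category), not reproduced.
* Structured-database and annotation content must be supplied (or
  simulated); no online services are queried.
* The biomarker classifier aggregates tagged evidence rows; it does not
  mine text to produce the tags.
* Real-corpus headline figures that depend on those proprietary inputs
  (e.g. the size of a real filtered target list, or a specific disease's
  top-ranked genes) are out of reach by design; the package demonstrates
  parity on the arithmetic identities those figures must satisfy and on
  synthetic cohorts.
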