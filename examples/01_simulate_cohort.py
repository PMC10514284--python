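"""Generate a synthetic evidence cohort with planted ground truth.

The generator writes every input file the pipeline consumes (literature
documents, a differential-expression table, an annotated VCF, pathway gene
sets, drug/trial/annotation tables) plus a ground_truth.json recording what
was planted, so downstream results can be checked against known answers.
"""

from pathlib import Path

from targetrank import CohortSpec, generate_cohort

out = Path("scratch/example_cohort")
spec = CohortSpec(n_targets=120, n_planted_top=5, seed=42,
                  n_deg_up=30, n_deg_down=8, n_variants=200)
truth = generate_cohort(spec, out)

print(f"cohort written to {out}/:")
for path in sorted(out.iterdir()):
    print(f"  {path.name:28s} {path.stat().st_size:>8d} bytes")
print()
print(f"planted top targets ({len(truth.planted_top_targets)}):",
      ", ".join(sorted(truth.planted_top_targets)))
print(f"planted DEGs: {len(truth.planted_up)} up, {len(truth.planted_down)} down")
print(f"variants expected to pass the hard filter: "
      f"{len(truth.variants_expected_pass)}")
print(f"expected loss-of-function variants: {len(truth.planted_lof)}")
# The planted-top targets carry saturated evidence in every asset class, so
# a correct pipeline must rank them first; the expected-pass variant keys
# are the oracle for the hard-filter stage.
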