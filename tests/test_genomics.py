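"""DEG post-processing and variant hard/downstream/LOF filtering."""

import numpy as np
import pandas as pd
import pytest

from targetrank.genomics import (
    apply_variant_filters,
    assign_regulation,
    call_lof,
    classify_impact,
    downstream_filter,
    hard_filter,
    read_vcf,
    select_significant,
)
from targetrank.models import AnnotatedVariant, VariantAnnotation, VariantQualityMetrics


def make_variant(
    QD=15.0, FS=5.0, MQ=55.0, MQRankSum=0.5, ReadPosRankSum=0.5, SOR=1.2,
    gene="GENE1", biotype="protein_coding", consequence="missense_variant",
    impact="MODERATE", AF=0.001, ExAC_AF=0.001, SIFT=None, PolyPhen=None,
    extra_blocks=(),
) -> AnnotatedVariant:
    ann = VariantAnnotation(gene=gene, biotype=biotype, consequence=consequence,
                            impact=impact, AF=AF, ExAC_AF=ExAC_AF,
                            SIFT=SIFT, PolyPhen=PolyPhen)
    return AnnotatedVariant(
        key=("chr1", 100, "A", "G"),
        variant_class="SNP",
        metrics=VariantQualityMetrics(QD=QD, FS=FS, MQ=MQ, MQRankSum=MQRankSum,
                                      ReadPosRankSum=ReadPosRankSum, SOR=SOR),
        annotations=[ann, *extra_blocks],
    )


def _random_deg_table(rng, n=200) -> pd.DataFrame:
    lfc = rng.normal(0, 1.5, n)
    return pd.DataFrame(
        {
            "gene_symbol": [f"G{i}" for i in range(n)],
            "control_mean": rng.lognormal(3, 1, n),
            "disease_mean": rng.lognormal(3, 1, n),
            "log2fc": lfc,
            "p_value": rng.uniform(0, 1, n),
            "p_adj": rng.uniform(0, 1, n),
            "abs_log2fc": 0.0,
            "regulation": "",
        }
    )


class TestRegulation:
    def test_positive_log2fc_is_up_with_absolute_value(self):
        df = pd.DataFrame([{"gene_symbol": "A", "control_mean": 10, "disease_mean": 40,
                            "log2fc": 2.0, "p_value": 0.01, "p_adj": 0.02,
                            "abs_log2fc": 0.0, "regulation": ""}])
        out = assign_regulation(df)
        assert out.loc[0, "regulation"] == "up"
        assert out.loc[0, "abs_log2fc"] == 2.0  # fourfold increase

    def test_negative_log2fc_is_down(self):
        df = pd.DataFrame([{"gene_symbol": "A", "control_mean": 10, "disease_mean": 5,
                            "log2fc": -1.0, "p_value": 0.1, "p_adj": 0.2,
                            "abs_log2fc": 0.0, "regulation": ""}])
        assert assign_regulation(df).loc[0, "regulation"] == "down"

    def test_zero_log2fc_is_unregulated_and_excluded_from_counts(self):
        df = _random_deg_table(np.random.default_rng(0), 5)
        df.loc[0, "log2fc"] = 0.0
        df.loc[0, "p_adj"] = 0.0
        out = assign_regulation(df)
        assert out.loc[0, "regulation"] is None
        _, counts = select_significant(df, padj_max=1.0, abs_lfc_min=0.0)
        assert counts["up"] + counts["down"] == 4

    def test_up_down_counts_match_sign_enumeration(self):
        df = _random_deg_table(np.random.default_rng(1))
        out = assign_regulation(df)
        assert (out["regulation"] == "up").sum() == (df["log2fc"] > 0).sum()
        assert (out["regulation"] == "down").sum() == (df["log2fc"] < 0).sum()


class TestSelectSignificant:
    def test_zero_padj_threshold_empties_the_table(self):
        df = _random_deg_table(np.random.default_rng(2))
        survivors, counts = select_significant(df, padj_max=0.0)
        assert survivors.empty and counts == {"up": 0, "down": 0}

    def test_survivors_equal_row_by_row_filtering(self):
        df = _random_deg_table(np.random.default_rng(3))
        survivors, _ = select_significant(df, padj_max=0.1, abs_lfc_min=1.0)
        brute = {
            g for g, p, l in zip(df["gene_symbol"], df["p_adj"], df["log2fc"])
            if p <= 0.1 and abs(l) >= 1.0
        }
        assert set(survivors["gene_symbol"]) == brute

    def test_tightening_thresholds_never_adds_survivors(self):
        df = _random_deg_table(np.random.default_rng(4))
        wide, _ = select_significant(df, padj_max=0.2, abs_lfc_min=0.5)
        narrow_p, _ = select_significant(df, padj_max=0.05, abs_lfc_min=0.5)
        narrow_l, _ = select_significant(df, padj_max=0.2, abs_lfc_min=1.5)
        assert set(narrow_p["gene_symbol"]) <= set(wide["gene_symbol"])
        assert set(narrow_l["gene_symbol"]) <= set(wide["gene_symbol"])


class TestHardFilter:
    def test_single_failing_metric_is_reported(self):
        passed, failed = hard_filter(make_variant(FS=61.0))
        assert not passed and failed == ["FS"]

    def test_values_exactly_at_thresholds_fail_all_six(self):
        v = make_variant(QD=2.0, FS=60.0, MQ=40.0, MQRankSum=-12.5,
                         ReadPosRankSum=-8.0, SOR=4.0)
        passed, failed = hard_filter(v)
        assert not passed
        assert failed == ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR"]

    def test_strictly_inside_bounds_passes(self):
        v = make_variant(QD=2.1, FS=10, MQ=50, MQRankSum=0, ReadPosRankSum=0, SOR=1)
        assert hard_filter(v) == (True, [])

    def test_missing_metric_passes_by_default_fails_with_switch(self):
        v = make_variant(MQRankSum=None)
        assert hard_filter(v)[0]
        v2 = make_variant(MQRankSum=None)
        passed, failed = hard_filter(v2, missing_passes=False)
        assert not passed and failed == ["MQRankSum"]


class TestDownstreamFilter:
    def test_common_allele_fails_af(self):
        passed, failed = downstream_filter(make_variant(AF=0.05))
        assert not passed and failed == ["AF"]

    def test_synonymous_fails_consequence(self):
        v = make_variant(consequence="synonymous_variant", impact="LOW")
        passed, failed = downstream_filter(v)
        assert not passed and failed == ["consequence"]

    def test_modifier_only_fails_impact(self):
        v = make_variant(consequence="intron_variant", impact="MODIFIER")
        passed, failed = downstream_filter(v)
        assert not passed and "impact" in failed

    def test_non_coding_biotype_fails(self):
        assert downstream_filter(make_variant(biotype="lincRNA"))[1] == ["biotype"]

    def test_modifier_block_plus_moderate_block_passes_impact_rule(self):
        moderate = VariantAnnotation(gene="G", biotype="protein_coding",
                                     consequence="missense_variant",
                                     impact="MODERATE", AF=0.001, ExAC_AF=0.001)
        v = make_variant(consequence="intron_variant", impact="MODIFIER",
                         extra_blocks=(moderate,))
        assert downstream_filter(v)[0]

    def test_missing_af_counts_as_rare_by_default(self):
        assert downstream_filter(make_variant(AF=None, ExAC_AF=None))[0]
        passed, failed = downstream_filter(
            make_variant(AF=None, ExAC_AF=None), af_missing_passes=False
        )
        assert not passed and failed == ["AF", "ExAC_AF"]


class TestLof:
    def test_deleterious_probably_damaging_missense_is_lof(self):
        v = make_variant(SIFT="deleterious(0.01)", PolyPhen="probably_damaging(0.99)")
        assert call_lof(v)

    def test_tolerated_missense_is_not_lof(self):
        assert not call_lof(make_variant(SIFT="tolerated(0.4)",
                                         PolyPhen="probably_damaging(0.9)"))

    def test_non_missense_is_outside_lof_scope(self):
        v = make_variant(consequence="stop_gained", impact="HIGH",
                         SIFT="deleterious(0.0)", PolyPhen="probably_damaging(0.99)")
        assert not call_lof(v)

    def test_possibly_damaging_configurable(self):
        v = make_variant(SIFT="deleterious(0.01)", PolyPhen="possibly_damaging(0.6)")
        assert call_lof(v)
        assert not call_lof(v, accept_possibly=False)


class TestImpactClassification:
    def test_headline_is_max_severity(self):
        variants = [
            make_variant(impact="HIGH", consequence="stop_gained"),
            make_variant(impact="LOW", consequence="synonymous_variant"),
            make_variant(impact="LOW", consequence="synonymous_variant"),
        ]
        df = classify_impact(variants)
        row = df.loc["GENE1"]
        assert (row["n_high"], row["n_moderate"], row["n_low"]) == (1, 0, 2)
        assert row["headline_impact"] == "HIGH"

    def test_empty_survivor_set_gives_empty_tally(self):
        assert classify_impact([]).empty

    def test_tallies_match_brute_force_grouping(self, small_cohort):
        cohort_dir, _ = small_cohort
        survivors = apply_variant_filters(read_vcf(cohort_dir / "variants.vcf"))
        df = classify_impact(survivors)
        brute = {}
        for v in survivors:
            brute.setdefault(v.annotation.gene, []).append(v.annotation.impact)
        for gene, impacts in brute.items():
            assert df.loc[gene, "n_variants"] == len(impacts)
            assert df.loc[gene, "n_high"] == impacts.count("HIGH")


class TestFilterComposition:
    def test_downstream_survivors_subset_of_hard_survivors(self, small_cohort):
        cohort_dir, _ = small_cohort
        variants = read_vcf(cohort_dir / "variants.vcf")
        hard_pass = {v.key for v in variants if hard_filter(v)[0]}
        survivors = apply_variant_filters(read_vcf(cohort_dir / "variants.vcf"))
        down_pass = {v.key for v in survivors}
        assert down_pass <= hard_pass <= {v.key for v in variants}
        lof = {v.key for v in survivors if v.is_lof}
        missense = {v.key for v in survivors
                    if "missense_variant" in v.annotation.consequence}
        assert lof <= missense

    def test_verdicts_match_generator_labels(self, small_cohort):
        cohort_dir, truth = small_cohort
        survivors = apply_variant_filters(read_vcf(cohort_dir / "variants.vcf"))
        assert {v.key for v in survivors} == truth.variants_expected_downstream
        assert {v.key for v in survivors if v.is_lof} == truth.planted_lof


def test_multiallelic_records_split_per_alt(tmp_path):
    vcf = tmp_path / "multi.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000000>\n"
        '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations.'
        ' Format: Gene|BIOTYPE|Consequence|IMPACT|AF|ExAC_AF|SIFT|PolyPhen">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t500\trs1\tA\tG,T\t.\t.\tQD=12.5;CSQ="
        "GENE1|protein_coding|missense_variant|MODERATE|0.001|0.001||,"
        "GENE1|protein_coding|synonymous_variant|LOW|0.001|0.001||\n"
    )
    variants = read_vcf(vcf)
    assert [v.key for v in variants] == [("chr1", 500, "A", "G"), ("chr1", 500, "A", "T")]
    assert variants[0].annotation.consequence == "missense_variant"
    assert variants[1].annotation.consequence == "synonymous_variant"
    assert all(v.metrics.QD == 12.5 for v in variants)
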