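"""Rule-based classifiers and gene-set enrichment."""

import datetime as dt
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from targetrank import TargetAnnotations
from targetrank.evaluation import (
    classify_biomarker,
    classify_druggability,
    classify_novelty,
    classify_safety,
    classify_tissue,
    enrich_pathways,
    evaluate_target,
    load_annotations,
    pathway_overlap,
    read_gmt,
    sponsor_trial_counts,
)
from targetrank.models import DrugRecord

TODAY = dt.date(2023, 1, 1)


def drug(modality="small_molecule", max_phase=3, status="active",
         withdrawal="none", attributed=False) -> DrugRecord:
    return DrugRecord(drug="d", target="T", modality=modality, max_phase=max_phase,
                      status=status, withdrawal=withdrawal,
                      reason_target_attributed=attributed)


class TestDruggability:
    def test_clinical_precedence_both_modalities_with_structure(self):
        ann = TargetAnnotations(
            target="T", has_structure=True,
            drugs=[drug("antibody", 3), drug("small_molecule", 2)],
        )
        assert classify_druggability(ann) == ("highly", "both")

    def test_structure_only_is_potentially_small_molecule(self):
        ann = TargetAnnotations(target="T", has_structure=True)
        assert classify_druggability(ann) == ("potentially", "small_molecule")

    def test_surface_only_is_potentially_antibody(self):
        ann = TargetAnnotations(target="T", surface_localized=True)
        assert classify_druggability(ann) == ("potentially", "antibody")

    def test_precedence_without_structure_or_surface_is_none(self):
        ann = TargetAnnotations(target="T", drugs=[drug(max_phase=4)])
        assert classify_druggability(ann) == ("none", "none")

    def test_preclinical_only_drug_is_not_clinical_precedence(self):
        ann = TargetAnnotations(target="T", has_structure=True,
                                drugs=[drug(max_phase=0)])
        assert classify_druggability(ann)[0] == "potentially"

    def test_planted_category_counts_sum_to_highly_total(self):
        """242 small-molecule + 68 antibody + 94 dual-modality highly
        druggable targets tally to 404."""
        anns = []
        for i in range(242):
            anns.append(TargetAnnotations(target=f"SM{i}", has_structure=True,
                                          drugs=[drug("small_molecule")]))
        for i in range(68):
            anns.append(TargetAnnotations(target=f"AB{i}", surface_localized=True,
                                          drugs=[drug("antibody")]))
        for i in range(94):
            anns.append(TargetAnnotations(
                target=f"BO{i}", has_structure=True, surface_localized=True,
                drugs=[drug("antibody"), drug("small_molecule")]))
        results = [classify_druggability(a) for a in anns]
        assert sum(1 for c, _ in results if c == "highly") == 404
        assert sum(1 for _, m in results if m == "small_molecule") == 242
        assert sum(1 for _, m in results if m == "antibody") == 68
        assert sum(1 for _, m in results if m == "both") == 94


class TestSafety:
    def test_target_attributed_market_withdrawal_flags(self):
        ann = TargetAnnotations(target="T",
                                drugs=[drug(withdrawal="market", attributed=True)])
        assert classify_safety(ann) == "unsafe_market_withdrawal"

    def test_unattributed_clinical_withdrawal_stays_safe(self):
        ann = TargetAnnotations(target="T",
                                drugs=[drug(withdrawal="clinical", attributed=False)])
        assert classify_safety(ann) == "safe"

    def test_essential_gene_without_drug_history_flags(self):
        ann = TargetAnnotations(target="T", essential_gene=True)
        assert classify_safety(ann) == "unsafe_essential"

    def test_higher_phase_programme_rescues_clinical_withdrawal(self):
        withdrawn = drug(max_phase=2, status="terminated",
                         withdrawal="clinical", attributed=True)
        rescue = drug(max_phase=3, status="active")
        ann = TargetAnnotations(target="T", drugs=[withdrawn, rescue])
        assert classify_safety(ann) == "safe"
        ann_no_rescue = TargetAnnotations(target="T", drugs=[withdrawn])
        assert classify_safety(ann_no_rescue) == "unsafe_clinical_withdrawal"

    def test_market_rule_wins_over_essential(self):
        ann = TargetAnnotations(target="T", essential_gene=True,
                                drugs=[drug(withdrawal="market", attributed=True)])
        assert classify_safety(ann) == "unsafe_market_withdrawal"


class TestBiomarker:
    def test_multi_category_membership(self):
        ann = TargetAnnotations(target="POSTN", biomarker_evidence=[
            ("diagnostic", "c1"), ("prognostic", "c2")])
        assert classify_biomarker(ann) == {"diagnostic", "prognostic"}

    def test_no_evidence_gives_empty_set(self):
        assert classify_biomarker(TargetAnnotations(target="T")) == set()

    def test_category_counts_match_tag_enumeration(self):
        rng = np.random.default_rng(0)
        cats = ["diagnostic", "prognostic", "predictive", "therapeutic"]
        anns = []
        for i in range(50):
            tags = list(rng.choice(cats, size=rng.integers(0, 3), replace=False))
            anns.append(TargetAnnotations(
                target=f"T{i}", biomarker_evidence=[(c, "x") for c in tags]))
        per_cat = {c: sum(1 for a in anns if c in classify_biomarker(a)) for c in cats}
        brute = {c: sum(1 for a in anns
                        if c in {cat for cat, _ in a.biomarker_evidence})
                 for c in cats}
        assert per_cat == brute

    def test_unknown_category_is_rejected(self):
        ann = TargetAnnotations(target="T", biomarker_evidence=[("speculative", "c")])
        with pytest.raises(ValueError):
            classify_biomarker(ann)


class TestNovelty:
    def _ann(self, pub_years_ago=3, news_years_ago=1, max_phase=1, **kw):
        return TargetAnnotations(
            target="T",
            highIF_pub_dates=[TODAY - dt.timedelta(days=int(pub_years_ago * 365.25))],
            news_dates=[TODAY - dt.timedelta(days=int(news_years_ago * 365.25))],
            drugs=[drug(max_phase=max_phase)] if max_phase else [],
            source_flags={"literature"},
            **kw,
        )

    def test_all_three_criteria_met_is_novel(self):
        assert classify_novelty(self._ann(), TODAY)[0]

    def test_phase_two_trial_breaks_novelty(self):
        assert classify_novelty(self._ann(max_phase=2), TODAY) == (False, "n/a")

    def test_stale_high_impact_discussion_breaks_novelty(self):
        assert not classify_novelty(self._ann(pub_years_ago=11), TODAY)[0]

    def test_stale_news_breaks_novelty(self):
        assert not classify_novelty(self._ann(news_years_ago=6), TODAY)[0]

    def test_genomics_only_target_is_unknown_knowns(self):
        ann = self._ann()
        ann.source_flags = {"expression_analysis"}
        assert classify_novelty(ann, TODAY) == (True, "unknown_knowns")

    def test_mechanism_flag_separates_known_knowns_from_known_unknowns(self):
        with_mech = self._ann(mechanism_known=True)
        without = self._ann(mechanism_known=False)
        assert classify_novelty(with_mech, TODAY) == (True, "known_knowns")
        assert classify_novelty(without, TODAY) == (True, "known_unknowns")

    def test_raising_a_phase_never_creates_novelty(self):
        for phase in range(5):
            base = classify_novelty(self._ann(max_phase=phase), TODAY)[0]
            for higher in range(phase, 5):
                raised = classify_novelty(self._ann(max_phase=higher), TODAY)[0]
                assert raised <= base


class TestTissue:
    def _ann(self, **levels):
        return TargetAnnotations(target="T", tissue_expression=levels)

    def test_lung_only_expression_is_exclusive(self):
        ann = self._ann(lung="high", liver="not_detected", kidney="not_detected")
        assert classify_tissue(ann) == "exclusive"

    def test_low_lung_only_still_exclusive(self):
        assert classify_tissue(self._ann(lung="low", liver="not_detected")) == "exclusive"

    def test_high_lung_with_other_organ_is_shared(self):
        assert classify_tissue(self._ann(lung="high", liver="medium")) == "high_shared"

    def test_low_lung_with_dominant_other_organ_is_other(self):
        assert classify_tissue(self._ann(lung="low", kidney="high")) == "other"

    def test_missing_lung_entry_treated_as_not_detected(self):
        assert classify_tissue(self._ann(liver="high")) == "other"


class TestEnrichment:
    def test_overlap_count_is_set_intersection(self):
        assert pathway_overlap({"a", "b", "c"}, {"x"}) == 0
        assert pathway_overlap({"a", "b", "c"}, {"a", "b", "c"}) == 3
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = set(rng.choice(50, size=10, replace=False).tolist())
            d = set(rng.choice(50, size=8, replace=False).tolist())
            assert pathway_overlap(t, d) == len(t & d)

    def test_perfect_overlap_has_minimum_p(self):
        universe = [f"G{i}" for i in range(200)]
        sets = {"hit": set(universe[:10]), "miss": set(universe[50:70]),
                "half": set(universe[5:25])}
        df = enrich_pathways(universe[:10], sets, universe)
        assert df.iloc[0]["pathway"] == "hit"
        assert df.iloc[0]["p_value"] == df["p_value"].min()

    def test_p_value_equals_hypergeometric_tail_summation(self):
        universe = [f"G{i}" for i in range(100)]
        gene_set = {"pw": set(universe[:10])}
        targets = universe[:2] + universe[50:53]  # k=2 overlap, n=5
        df = enrich_pathways(targets, gene_set, universe)
        N, K, n, k = 100, 10, 5, 2
        tail = sum(
            Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
            for i in range(k, min(K, n) + 1)
        )
        assert df.iloc[0]["p_value"] == pytest.approx(float(tail), rel=1e-12)

    def test_null_target_sets_are_not_anticonservative(self):
        """Adjusted p-values from random draws dominate the uniform: the
        rejection rate at any level stays at or below that level."""
        rng = np.random.default_rng(7)
        universe = [f"G{i}" for i in range(80)]
        gene_sets = {f"pw{j}": set(rng.choice(universe, 12, replace=False).tolist())
                     for j in range(5)}
        p_fixed = []
        for _ in range(200):
            targets = rng.choice(universe, 10, replace=False).tolist()
            df = enrich_pathways(targets, gene_sets, universe).set_index("pathway")
            assert (df["p_adj"] >= df["p_value"] - 1e-12).all()
            p_fixed.append(df.loc["pw0", "p_adj"])
        p_fixed = np.asarray(p_fixed)
        for alpha in (0.05, 0.1, 0.25):
            assert (p_fixed <= alpha).mean() <= alpha + 0.05

    def test_empty_target_set_gives_empty_result(self):
        assert enrich_pathways([], {"pw": {"G1"}}, ["G1", "G2"]).empty

    def test_targets_outside_universe_are_rejected(self):
        with pytest.raises(ValueError):
            enrich_pathways(["X"], {"pw": {"G1"}}, ["G1"])


class TestCohortRecovery:
    def test_classifier_outputs_equal_planted_classes(self, small_cohort):
        """On a generated cohort the deterministic classifiers reproduce the
        generator's expected labels exactly, for every target."""
        cohort_dir, truth = small_cohort
        anns = load_annotations(
            cohort_dir / "annotations.tsv",
            drugs_tsv=cohort_dir / "drugs.tsv",
            biomarker_tsv=cohort_dir / "biomarker_evidence.tsv",
            pathways_gmt=cohort_dir / "pathways.gmt",
        )
        ref = dt.date(2023, 1, 1)
        for target, expected in truth.planted_classes.items():
            ann = anns[target]
            ann.source_flags = truth.source_flags[target]
            profile = evaluate_target(ann, truth.disease_pathways, ref)
            got = {
                "druggability": profile.druggability,
                "modality": profile.modality,
                "safety": profile.safety,
                "biomarker_categories": sorted(profile.biomarker_categories),
                "novel": profile.novel,
                "novelty_taxonomy": profile.novelty_taxonomy,
                "lung_expression": profile.lung_expression,
            }
            assert got == expected, target

    def test_each_target_gets_exactly_one_class_per_axis(self, small_cohort):
        cohort_dir, truth = small_cohort
        anns = load_annotations(cohort_dir / "annotations.tsv",
                                drugs_tsv=cohort_dir / "drugs.tsv")
        for ann in anns.values():
            p = evaluate_target(ann, truth.disease_pathways, dt.date(2023, 1, 1))
            assert p.druggability in ("highly", "potentially", "none")
            assert p.safety in ("safe", "unsafe_market_withdrawal",
                                "unsafe_clinical_withdrawal", "unsafe_essential")
            assert p.lung_expression in ("exclusive", "high_shared", "other")
            assert (p.modality != "none") == (p.druggability != "none")


def test_gmt_round_trip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("pw1\tdesc\tA\tB\nshort_line\n" "pw2\tdesc\tC\n")
    sets = read_gmt(path)
    assert sets == {"pw1": {"A", "B"}, "pw2": {"C"}}


def test_sponsor_summary_counts_trials(tmp_path, small_cohort):
    cohort_dir, _ = small_cohort
    counts = sponsor_trial_counts(cohort_dir / "trials.tsv")
    assert (counts["n_trials"] > 0).all()
    assert counts["n_trials"].is_monotonic_decreasing
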