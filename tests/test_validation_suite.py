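"""Curation, external-cohort harnesses, survival stratification,
threshold adapters."""

import numpy as np
import pandas as pd
import pytest

from mvprof.synthetic_fixtures import FixtureConfig, generate_survival_cohort
from mvprof.validation_suite import (
    ThresholdRule,
    categorize_survival,
    classify_by_threshold,
    compare_clinvar,
    curate_clinvar,
    default_tool_rules,
    fit_two_group_hazard_ratio,
    lfs_validate,
    summarize_population,
    survival_analyze,
)


def clinvar_frame(rows):
    return pd.DataFrame(
        rows, columns=["variant", "tier", "record_id", "variant_class"]
    )


def synthetic_annotation_table(
    n_records=778, n_same_label_dups=22, n_indel=8
):
    """An annotation table with planted duplicate and indel records."""
    rows = []
    tiers = ["P", "LP", "VUS", "LB", "B"]
    n_single = n_records - 2 * n_same_label_dups - n_indel
    for i in range(n_single):
        rows.append((f"V{i}", tiers[i % 5], f"r{len(rows)}", "missense"))
    for i in range(n_same_label_dups):
        tier = tiers[i % 5]
        rows.append((f"DUP{i}", tier, f"r{len(rows)}", "missense"))
        rows.append((f"DUP{i}", tier, f"r{len(rows)}", "missense"))
    for i in range(n_indel):
        rows.append((f"IND{i}", "P", f"r{len(rows)}", "indel_derived"))
    return clinvar_frame(rows)


class TestCuration:
    def test_planted_accounting(self):
        raw = synthetic_annotation_table()
        curated, acc = curate_clinvar(raw)
        assert acc["input"] == 778
        assert acc["duplicate_removed"] == 22
        assert acc["indel_removed"] == 8
        assert acc["retained"] == 748
        assert len(curated) == 748

    def test_conflicting_labels_collapse_to_vus(self):
        raw = clinvar_frame(
            [("X", "P", "r1", "missense"), ("X", "B", "r2", "missense")]
        )
        curated, _ = curate_clinvar(raw)
        assert len(curated) == 1
        assert curated.iloc[0]["tier"] == "VUS"

    def test_absent_labels_collapse_to_vus(self):
        raw = clinvar_frame(
            [("X", "", "r1", "missense"), ("X", "", "r2", "missense")]
        )
        curated, _ = curate_clinvar(raw)
        assert curated.iloc[0]["tier"] == "VUS"

    def test_clean_table_is_identity(self):
        raw = clinvar_frame(
            [("A", "P", "r1", "missense"), ("B", "B", "r2", "missense")]
        )
        curated, acc = curate_clinvar(raw)
        assert len(curated) == 2
        assert acc["duplicate_removed"] == 0

    def test_idempotent(self):
        raw = synthetic_annotation_table()
        once, _ = curate_clinvar(raw)
        twice, acc = curate_clinvar(once)
        assert len(twice) == len(once)
        assert acc["duplicate_removed"] == acc["indel_removed"] == 0

    def test_unknown_tier_rejected(self):
        raw = clinvar_frame([("A", "MAYBE", "r1", "missense")])
        with pytest.raises(ValueError, match="unknown tier"):
            curate_clinvar(raw)


class TestCompareClinvar:
    def test_five_tier_mapping_and_confusion(self):
        rows = (
            [(f"TP{i}", "P" if i % 2 else "LP", f"r{i}", "missense")
             for i in range(164)]
            + [(f"TN{i}", "B" if i % 2 else "LB", f"s{i}", "missense")
               for i in range(26)]
        )
        curated = clinvar_frame(rows)
        preds = pd.Series(
            {f"TP{i}": ("D" if i < 157 else "ND") for i in range(164)}
            | {f"TN{i}": "ND" for i in range(26)}
        )
        report = compare_clinvar(curated, preds)
        assert (report.cm.tp, report.cm.tn, report.cm.fn, report.cm.fp) == (
            157, 26, 7, 0,
        )
        assert report.accuracy == 96.32
        assert report.sensitivity == 95.73
        assert report.specificity == 100.0

    def test_all_vus_gives_split_only(self):
        curated = clinvar_frame(
            [("A", "VUS", "r1", "missense"), ("B", "VUS", "r2", "missense")]
        )
        preds = pd.Series({"A": "D", "B": "ND"})
        report = compare_clinvar(curated, preds)
        assert report.cm is None
        assert report.details["vus_predicted_D"] == 1
        assert report.details["vus_predicted_ND"] == 1

    def test_all_deleterious_on_benign_table_zero_specificity(self):
        curated = clinvar_frame([("A", "B", "r1", "missense")])
        report = compare_clinvar(curated, pd.Series({"A": "D"}))
        assert report.specificity == 0.0

    def test_uncovered_variants_excluded_and_listed(self):
        curated = clinvar_frame(
            [("A", "P", "r1", "missense"), ("Z", "P", "r2", "missense")]
        )
        report = compare_clinvar(curated, pd.Series({"A": "D"}))
        assert report.details["uncovered"] == ["Z"]
        assert report.cm.n == 1


class TestLfs:
    def test_iarc_style_accuracy(self):
        variants = [f"L{i}" for i in range(58)] + ["SNP1", "SNP2"]
        preds = pd.Series(
            {f"L{i}": ("D" if i < 54 else "ND") for i in range(58)}
            | {"SNP1": "ND", "SNP2": "ND"}
        )
        report = lfs_validate(variants, preds, excluded_snps=["SNP1", "SNP2"])
        assert report.accuracy == 93.1
        assert report.details["n_evaluated"] == 58

    def test_multicenter_style_accuracy(self):
        variants = [f"G{i}" for i in range(74)] + ["S1", "S2", "S3"]
        preds = pd.Series(
            {f"G{i}": ("D" if i < 71 else "ND") for i in range(74)}
            | {"S1": "ND", "S2": "ND", "S3": "ND"}
        )
        report = lfs_validate(variants, preds, excluded_snps=["S1", "S2", "S3"])
        assert report.accuracy == 95.9

    def test_no_exclusions_all_deleterious(self):
        preds = pd.Series({"A": "D", "B": "D"})
        report = lfs_validate(["A", "B"], preds)
        assert report.accuracy == 100.0

    def test_invariant_to_family_duplication_and_order(self):
        preds = pd.Series({"A": "D", "B": "ND", "C": "D"})
        a = lfs_validate(["A", "B", "C"], preds)
        b = lfs_validate(["C", "A", "B", "A", "A", "C"], preds)
        assert a.accuracy == b.accuracy

    def test_founder_exclusion(self):
        preds = pd.Series({"A": "D", "R337H": "D"})
        report = lfs_validate(
            ["A", "R337H"], preds, excluded_founders=["R337H"]
        )
        assert report.details["n_evaluated"] == 1

    def test_absent_exclusion_warns_only(self, caplog):
        preds = pd.Series({"A": "D"})
        report = lfs_validate(["A"], preds, excluded_snps=["GHOST"])
        assert report.accuracy == 100.0


class TestPopulation:
    def test_planted_partition(self):
        table = pd.DataFrame(
            {"variant": [f"V{i}" for i in range(196)],
             "allele_count": 1}
        )
        preds = pd.Series(
            {f"V{i}": ("D" if i < 39 else "ND") for i in range(196)}
        )
        counts, joined = summarize_population(table, preds)
        assert counts == {"D": 39, "ND": 157}
        assert len(joined) == 196

    def test_empty_table(self):
        counts, _ = summarize_population(
            pd.DataFrame({"variant": []}), pd.Series(dtype=object)
        )
        assert counts == {"D": 0, "ND": 0}

    def test_missing_prediction_is_an_error(self):
        table = pd.DataFrame({"variant": ["A"]})
        with pytest.raises(ValueError, match="lack predictions"):
            summarize_population(table, pd.Series(dtype=object))


def sample_row(sid, variants, time=10.0, event=1, tumor="BRCA", patient=None):
    return {
        "patient_id": patient or f"pat_{sid}",
        "sample_id": sid,
        "variants": variants,
        "time": time,
        "event": event,
        "tumor_type": tumor,
    }


class TestCategorize:
    def test_multi_mutation_sample_excluded(self):
        df = pd.DataFrame([
            sample_row("s1", [("A", "Missense_Mutation"),
                              ("B", "Nonsense_Mutation")]),
        ])
        out = categorize_survival(df, pd.Series({"A": "D"}))
        assert out["category"].tolist() == ["excluded"]

    def test_nonsense_is_truncating(self):
        df = pd.DataFrame([sample_row("s1", [("A", "Nonsense_Mutation")])])
        out = categorize_survival(df, pd.Series(dtype=object))
        assert out["category"].tolist() == ["truncating"]

    def test_in_frame_deletion_excluded(self):
        df = pd.DataFrame([sample_row("s1", [("A", "In_Frame_Del")])])
        out = categorize_survival(df, pd.Series(dtype=object))
        assert out["category"].tolist() == ["excluded"]

    def test_missense_classed_by_prediction(self):
        df = pd.DataFrame([
            sample_row("s1", [("A", "Missense_Mutation")]),
            sample_row("s2", [("B", "Missense_Mutation")]),
            sample_row("s3", []),
        ])
        out = categorize_survival(df, pd.Series({"A": "D", "B": "ND"}))
        assert out["category"].tolist() == [
            "missense_D", "missense_ND", "no_mutation",
        ]

    def test_duplicate_patient_excluded(self):
        df = pd.DataFrame([
            sample_row("s1", [], patient="p1"),
            sample_row("s2", [], patient="p1"),
        ])
        out = categorize_survival(df, pd.Series(dtype=object))
        assert out["category"].tolist() == ["excluded", "excluded"]

    def test_unknown_class_excluded_with_warning(self, caplog):
        df = pd.DataFrame([sample_row("s1", [("A", "Weird_Class")])])
        with caplog.at_level("WARNING"):
            out = categorize_survival(df, pd.Series(dtype=object))
        assert out["category"].tolist() == ["excluded"]
        assert any("unknown variant class" in m for m in caplog.messages)

    def test_partition_is_exhaustive(self):
        cfg = FixtureConfig(seed=5, n_samples=300)
        cohort, preds = generate_survival_cohort(cfg)
        out = categorize_survival(cohort, preds)
        assert len(out) == len(cohort)
        assert set(out["category"]) <= {
            "no_mutation", "missense_ND", "missense_D", "truncating",
            "excluded",
        }
        # generator's intended categories are recovered exactly
        assert (out["category"] == cohort["true_category"]).all()


class TestSurvivalAnalysis:
    def test_hazard_ratio_recovery(self):
        cfg = FixtureConfig(
            seed=3, category_sizes={"missense_D": 1000, "missense_ND": 1000}
        )
        cohort, preds = generate_survival_cohort(cfg)
        cat = categorize_survival(cohort, preds)
        hr = fit_two_group_hazard_ratio(cat, "missense_D", "missense_ND")
        assert 1.7 <= hr <= 2.35

    def test_four_category_analysis_runs(self):
        cfg = FixtureConfig(seed=4, n_samples=1200)
        cohort, preds = generate_survival_cohort(cfg)
        cat = categorize_survival(cohort, preds)
        analysis = survival_analyze(cat)
        assert set(analysis.km_curves) <= {
            "no_mutation", "missense_ND", "missense_D", "truncating",
        }
        strong = analysis.pairwise_p[("no_mutation", "missense_D")]
        assert strong is not None and strong < 1e-6
        assert analysis.multivariable is not None
        assert "pred_D" in analysis.multivariable.index

    def test_tumor_type_exclusion_applied_first(self):
        cfg = FixtureConfig(seed=4, n_samples=600)
        cohort, preds = generate_survival_cohort(cfg)
        cohort.loc[cohort.index[:50], "tumor_type"] = "PCPG"
        cat = categorize_survival(cohort, preds)
        analysis = survival_analyze(cat)
        total = sum(
            v for k, v in analysis.category_counts.items() if k != "excluded"
        )
        assert total == (cat["category"] != "excluded").sum() - 50

    def test_single_category_rejected(self):
        df = pd.DataFrame([
            sample_row(f"s{i}", [], time=float(i + 1)) for i in range(10)
        ])
        cat = categorize_survival(df, pd.Series(dtype=object))
        with pytest.raises(ValueError, match=">=2 categories"):
            survival_analyze(cat)

    def test_null_type_one_error_calibrated(self):
        # identical survival distributions: p<0.05 in <=7% of replicates
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(12)
        n_sig = 0
        reps = 300
        for _ in range(reps):
            t1 = rng.exponential(10, 80)
            t2 = rng.exponential(10, 80)
            e = np.ones(80)
            if logrank_test(t1, t2, e, e).p_value < 0.05:
                n_sig += 1
        assert n_sig / reps <= 0.07


class TestThresholdRules:
    def test_revel_style_cutoffs(self):
        scores = pd.Series({"A": 0.6})
        low = ThresholdRule("revel", "numeric_cutoff", cutoff=0.5)
        high = ThresholdRule("revel", "numeric_cutoff", cutoff=0.7)
        assert classify_by_threshold(scores, low)["A"] == "D"
        assert classify_by_threshold(scores, high)["A"] == "ND"

    def test_category_vocabulary(self):
        rule = default_tool_rules()["mutationassessor"]
        scores = pd.Series({"A": "medium", "B": "neutral"})
        out = classify_by_threshold(scores, rule)
        assert out["A"] == "D" and out["B"] == "ND"

    def test_uncertain_band(self):
        rule = ThresholdRule(
            "eve", "cutoff_with_uncertain_band", lower=0.3, upper=0.7
        )
        scores = pd.Series({"lo": 0.1, "mid": 0.5, "hi": 0.9})
        out = classify_by_threshold(scores, rule)
        assert out.tolist() == ["ND", "uncertain", "D"]

    def test_missing_score_is_uncertain(self):
        rule = ThresholdRule("revel", "numeric_cutoff", cutoff=0.5)
        out = classify_by_threshold(pd.Series({"A": np.nan}), rule)
        assert out["A"] == "uncertain"

    def test_monotone_in_score(self, rng):
        rule = ThresholdRule("s", "numeric_cutoff", cutoff=0.4)
        xs = np.sort(rng.random(50))
        out = classify_by_threshold(pd.Series(xs), rule)
        flips = [
            (a, b) for a, b in zip(out[:-1], out[1:]) if a == "D" and b == "ND"
        ]
        assert not flips

    def test_unmapped_category_is_an_error(self):
        rule = ThresholdRule(
            "tool", "category_map", category_map={"bad": "D"}
        )
        with pytest.raises(ValueError, match="missing from the map"):
            classify_by_threshold(pd.Series({"A": "odd"}), rule)

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ThresholdRule("x", "numeric_cutoff", cutoff=float("nan"))
        with pytest.raises(ValueError):
            ThresholdRule("x", "cutoff_with_uncertain_band", lower=0.9, upper=0.1)
        with pytest.raises(ValueError):
            ThresholdRule("x", "category_map")
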