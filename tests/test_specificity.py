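import numpy as np
import pandas as pd
import pytest

from secretomapper import preprocess, specificity
from secretomapper import synthetic_data as sim
from secretomapper.types import ParameterSet

from conftest import make_design, make_table

GROUPS = ("astrocyte", "microglia", "neuron", "oligodendrocyte")


def brute_force_classify(counts, means, min_detected=5, max_other=2, fold=5.0):
    """Plain-python re-evaluation of the two specificity rules."""
    out = {}
    for pid in counts.index:
        hits = []
        for g in counts.columns:
            if counts.loc[pid, g] < min_detected:
                continue
            others = [h for h in counts.columns if h != g]
            rule_i = all(counts.loc[pid, h] <= max_other for h in others)
            rule_ii = all(
                means.loc[pid, g] - means.loc[pid, h] >= np.log2(fold)
                for h in others
            )
            if rule_i or rule_ii:
                hits.append((g, rule_i, rule_ii))
        if len(hits) == 1:
            g, rule_i, rule_ii = hits[0]
            rule = {(True, True): "both", (True, False): "exclusive_detection",
                    (False, True): "fold_enrichment"}[(rule_i, rule_ii)]
            out[pid] = (g, rule)
        else:
            out[pid] = (None, "none")
    return out


class TestDetectionCounts:
    def test_trivial_profiles(self, design_4x6):
        values = np.full((2, 24), np.nan)
        values[0, 12:18] = 50.0  # all six neuron replicates
        table = make_table(values, design_4x6)
        counts = specificity.detection_counts(table)
        assert counts.loc["P000"].to_dict() == {
            "astrocyte": 0, "microglia": 0, "neuron": 6, "oligodendrocyte": 0}
        assert counts.loc["P001"].sum() == 0
        assert counts.attrs["totals"] == {g: 6 for g in GROUPS}

    def test_matches_brute_force_recount(self, sim_bundle):
        table = sim_bundle["table"]
        counts = specificity.detection_counts(table)
        for pid in table.protein_ids[::37]:
            for g in GROUPS:
                expected = int(sum(
                    not np.isnan(table.data.loc[pid, c])
                    for c in table.design.columns_for(g)))
                assert counts.loc[pid, g] == expected


class TestClassifySpecificity:
    def _frames(self, counts_rows, means_rows, ids=None):
        ids = ids or [f"P{i}" for i in range(len(counts_rows))]
        counts = pd.DataFrame(counts_rows, index=ids, columns=list(GROUPS))
        means = pd.DataFrame(means_rows, index=ids, columns=list(GROUPS))
        return counts, means

    def test_exclusive_detection_rule(self):
        counts, means = self._frames(
            [[1, 6, 0, 1]], [[25.0, 25.0, 25.0, 25.0]])
        calls = specificity.classify_specificity(counts, means)
        assert calls.loc["P0", "specific_group"] == "microglia"
        assert calls.loc["P0", "rule"] == "exclusive_detection"

    def test_fold_enrichment_rule(self):
        log2_5 = np.log2(5)
        counts, means = self._frames(
            [[6, 6, 6, 6]], [[25.0, 25.0, 25.0 + log2_5 + 0.01, 25.0]])
        calls = specificity.classify_specificity(counts, means)
        assert calls.loc["P0", "specific_group"] == "neuron"
        assert calls.loc["P0", "rule"] == "fold_enrichment"
        assert calls.loc["P0", "min_pairwise_fold"] >= 5.0

    def test_both_rules_and_none(self):
        counts, means = self._frames(
            [[6, 0, 0, 0], [4, 4, 4, 4]],
            [[30.0, 25.0, 25.0, 25.0], [25.0, 25.0, 25.0, 25.0]])
        calls = specificity.classify_specificity(counts, means)
        assert calls.loc["P0", "rule"] == "both"
        assert calls.loc["P1", "rule"] == "none"
        assert calls.loc["P1", "specific_group"] is None

    def test_fold_rule_requires_dominance_over_every_group(self):
        log2_5 = np.log2(5)
        counts, means = self._frames(
            [[6, 6, 6, 6]],
            [[25.0 + log2_5 + 1, 25.0 + 1.0, 25.0, 25.0]])
        calls = specificity.classify_specificity(counts, means)
        # astrocyte beats neuron/oligo five-fold but not microglia
        assert calls.loc["P0", "specific_group"] is None

    def test_matches_brute_force(self, sim_bundle):
        table, _ = preprocess.filter_by_replication(sim_bundle["table"], 5)
        counts = specificity.detection_counts(table)
        imputed = preprocess.impute_left_shifted(
            preprocess.log_transform(table), seed=13)
        means = specificity.group_means(imputed)
        calls = specificity.classify_specificity(counts, means)
        expected = brute_force_classify(counts, means)
        for pid in counts.index:
            assert (calls.loc[pid, "specific_group"],
                    calls.loc[pid, "rule"]) == expected[pid]

    def test_monotonicity_in_thresholds(self, sim_bundle):
        table, _ = preprocess.filter_by_replication(sim_bundle["table"], 5)
        counts = specificity.detection_counts(table)
        imputed = preprocess.impute_left_shifted(
            preprocess.log_transform(table), seed=13)
        means = specificity.group_means(imputed)

        def fold_set(fold):
            calls = specificity.classify_specificity(
                counts, means, ParameterSet(fold_specific=fold))
            return set(calls.index[calls["rule"].isin(["fold_enrichment", "both"])])

        assert fold_set(8.0) <= fold_set(5.0) <= fold_set(3.0)

        def excl_set(min_detected):
            calls = specificity.classify_specificity(
                counts, means, ParameterSet(min_detected=min_detected))
            return set(calls.index[
                calls["rule"].isin(["exclusive_detection", "both"])])

        assert excl_set(6) <= excl_set(5) <= excl_set(4)


class TestUniquelyDetected:
    def test_distinct_from_specificity_criterion(self):
        counts = pd.DataFrame(
            # detected 6/6 in neurons and 4/6 in astrocytes: uniquely
            # detected (only neurons reach 5) but NOT exclusive-detection
            # specific (astrocytes above 2 replicates)
            [[4, 0, 6, 0]],
            index=["P0"], columns=list(GROUPS))
        unique = specificity.uniquely_detected(counts, min_detected=5)
        assert unique.loc["P0"] == "neuron"
        means = pd.DataFrame([[25.0] * 4], index=["P0"], columns=list(GROUPS))
        calls = specificity.classify_specificity(counts, means)
        assert calls.loc["P0", "specific_group"] is None

    def test_counts_by_number_of_types(self, sim_bundle):
        counts = specificity.detection_counts(sim_bundle["table"])
        unique = specificity.uniquely_detected(counts, 5)
        reach = (counts >= 5).sum(axis=1)
        assert unique.notna().sum() == (reach == 1).sum()


class TestLysateSpecificity:
    def _table(self, mean_rows, seed=0):
        design = make_design()
        rng = np.random.default_rng(seed)
        values = np.repeat(np.asarray(mean_rows, dtype=float), 6, axis=1)
        values += rng.normal(0, 0.01, size=values.shape)
        return make_table(values, design, scale="log2")

    def test_threshold_behaviour(self):
        lo = np.log2(2.0)   # two-fold: below threshold
        hi = np.log2(3.0)   # three-fold: above
        table = self._table([[25.0, 25.0, 25.0, 25.0 + hi],
                             [25.0 + lo, 25.0, 25.0, 25.0]])
        calls = specificity.lysate_specificity(table)
        assert calls.iloc[0] == "oligodendrocyte"
        assert calls.iloc[1] is None

    def test_recovers_planted_expression_effects(self):
        config = sim.SimConfig(n_proteins=500, seed=21,
                               effect_log2=float(np.log2(4)), censor_mid=18.0)
        table, truth = sim.generate_secretome(config)
        table, _ = preprocess.filter_by_replication(table, 2)
        imputed = preprocess.impute_left_shifted(
            preprocess.log_transform(table), seed=5)
        calls = specificity.lysate_specificity(imputed)
        truth_sub = truth.specific_group.reindex(calls.index)
        # planted log2(4) effect is ~3 sigma/sqrt(n) above the log2(2.5) bar
        planted = truth_sub.notna()
        agree = (calls[planted] == truth_sub[planted]).mean()
        assert agree >= 0.9
        false_rate = calls[~planted].notna().mean()
        assert false_rate <= 0.02


class TestConcordance:
    def test_categories(self):
        calls = pd.DataFrame(
            {"specific_group": ["neuron", "neuron", "microglia", None],
             "rule": ["both", "both", "both", "none"],
             "min_pairwise_fold": [9.0, 9.0, 9.0, np.nan]},
            index=["P1", "P2", "P3", "P4"])
        lysate = pd.Series({"P1": "neuron", "P2": None, "P5": "astrocyte"})
        result = specificity.concordance(calls, lysate)
        assert result.loc["P1", "category"] == "expression_driven"
        assert result.loc["P2", "category"] == "secretion_specific"
        assert result.loc["P3", "category"] == "secretome_only"
        assert "P4" not in result.index
        assert result.attrs["expression_driven_fraction"]["neuron"] == 0.5

    def test_planted_fractions_recovered(self):
        # secretome and lysate generated from the same truth: every called
        # protein should be expression-driven up to statistical error
        config = sim.SimConfig(n_proteins=600, seed=31)
        sec_table, truth = sim.generate_secretome(config)
        lys_table, _ = sim.generate_secretome(
            sim.SimConfig(n_proteins=600, seed=31, replicate_sd=0.3))
        sec_table, _ = preprocess.filter_by_replication(sec_table, 5)
        sec_imp = preprocess.impute_left_shifted(
            preprocess.log_transform(sec_table), seed=1)
        calls = specificity.classify_specificity(
            specificity.detection_counts(sec_table),
            specificity.group_means(sec_imp))
        lys_table, _ = preprocess.filter_by_replication(lys_table, 2)
        lys_imp = preprocess.impute_left_shifted(
            preprocess.log_transform(lys_table), seed=2)
        lys_calls = specificity.lysate_specificity(lys_imp)
        result = specificity.concordance(calls, lys_calls)
        covered = result[result["category"] != "secretome_only"]
        assert (covered["category"] == "expression_driven").mean() > 0.8
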