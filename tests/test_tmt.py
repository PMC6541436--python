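"""TMT ratio analysis: bait normalization, log2 transform, replicate-
consistency classification against a brute-force oracle, abundance
ranking, and cross-time-point comparison."""

import numpy as np
import pandas as pd
import pytest

from prpflux.simulate import simulate_tmt_experiment
from prpflux.tmt import (TMTExperiment, classify_enrichment, calls_to_frame,
                         combine_timepoints, compare_timepoints, log2_ratios,
                         normalize_to_bait, rank_by_abundance)


def brute_force_classes(log2_table: pd.DataFrame, threshold: float) -> dict:
    """Independent per-protein loop: count replicates above threshold."""
    out = {}
    n_rep = log2_table.shape[1]
    for protein, row in log2_table.iterrows():
        above = sum(1 for v in row if not np.isnan(v) and v > threshold)
        quantified = sum(1 for v in row if not np.isnan(v))
        if quantified == n_rep and above == n_rep:
            out[str(protein)] = "full"
        elif above == n_rep - 1:
            out[str(protein)] = "partial"
        else:
            out[str(protein)] = "none"
    return out


@pytest.fixture(scope="module")
def planted_experiment() -> TMTExperiment:
    full = [f"P{i + 1:04d}" for i in range(10)]
    partial = [f"P{i + 1:04d}" for i in range(10, 21)]
    return simulate_tmt_experiment(1500, full, partial, effect_log2=1.0,
                                   noise_sd_log2=0.1, seed=42)


class TestNormalization:
    def test_bait_becomes_exactly_one_and_idempotent(self, planted_experiment):
        norm = normalize_to_bait(planted_experiment)
        assert norm.ratios.loc["BAIT"].eq(1.0).all()
        again = normalize_to_bait(norm)
        pd.testing.assert_frame_equal(norm.ratios, again.ratios)

    def test_already_normalized_table_unchanged(self):
        ratios = pd.DataFrame({"rep1": [1.0, 2.0], "rep2": [1.0, 0.5]},
                              index=["BAIT", "P1"])
        exp = TMTExperiment(ratios=ratios, bait="BAIT")
        pd.testing.assert_frame_equal(normalize_to_bait(exp).ratios, ratios)

    def test_missing_bait_ratio_names_replicate(self):
        ratios = pd.DataFrame({"rep1": [2.0, 2.0], "rep2": [np.nan, 0.5]},
                              index=["BAIT", "P1"])
        exp = TMTExperiment(ratios=ratios, bait="BAIT")
        with pytest.raises(ValueError, match="rep2"):
            normalize_to_bait(exp)

    def test_order_commutes_with_log2(self, planted_experiment):
        """normalize -> log2 equals log2 -> subtract bait log2."""
        a = log2_ratios(normalize_to_bait(planted_experiment))
        raw = log2_ratios(planted_experiment)
        b = raw - raw.loc["BAIT"]
        assert np.nanmax(np.abs(a.to_numpy() - b.to_numpy())) < 1e-12


class TestLog2:
    def test_values_and_threshold_note(self):
        ratios = pd.DataFrame({"rep1": [1.0, 1.4, 2.0]}, index=["BAIT", "a", "b"])
        exp = TMTExperiment(ratios=ratios, bait="BAIT")
        out = log2_ratios(exp)
        assert out.loc["BAIT", "rep1"] == 0.0
        # a ratio of 1.4 sits just below the log2 = 0.5 cutoff (2^0.5 ~ 1.414)
        assert out.loc["a", "rep1"] == pytest.approx(0.485, abs=1e-3)
        assert out.loc["a", "rep1"] < 0.5
        assert out.loc["b", "rep1"] == 1.0

    def test_non_positive_becomes_missing_with_warning(self):
        table = pd.DataFrame({"rep1": [1.0, 0.0], "rep2": [1.0, 2.0]},
                             index=["BAIT", "a"])
        with pytest.warns(UserWarning, match="non-positive"):
            out = log2_ratios(table)
        assert np.isnan(out.loc["a", "rep1"])
        assert out.loc["a", "rep2"] == 1.0


class TestClassification:
    def test_planted_fixture_recovered_and_matches_brute_force(self,
                                                               planted_experiment):
        log2 = log2_ratios(normalize_to_bait(planted_experiment))
        calls = classify_enrichment(log2, 0.5)
        frame = calls_to_frame(calls)
        full = set(frame.index[frame["class"] == "full"]) - {"BAIT"}
        partial = set(frame.index[frame["class"] == "partial"]) - {"BAIT"}
        assert full == {f"P{i + 1:04d}" for i in range(10)}
        assert partial == {f"P{i + 1:04d}" for i in range(10, 21)}
        oracle = brute_force_classes(log2, 0.5)
        for call in calls:
            assert call.klass == oracle[call.protein]

    def test_noise_free_table_any_threshold_below_effect(self):
        exp = simulate_tmt_experiment(40, ["P0001"], ["P0002"], effect_log2=1.0,
                                      noise_sd_log2=0.0, seed=3)
        log2 = log2_ratios(normalize_to_bait(exp))
        for threshold in (0.1, 0.5, 0.9):
            frame = calls_to_frame(classify_enrichment(log2, threshold))
            assert list(frame.index[frame["class"] == "full"]) == ["P0001"]
            assert list(frame.index[frame["class"] == "partial"]) == ["P0002"]

    def test_strict_inequality_at_threshold(self):
        table = pd.DataFrame({"rep1": [0.5, 0.6], "rep2": [0.6, 0.6],
                              "rep3": [0.6, 0.6]}, index=["at", "above"])
        frame = calls_to_frame(classify_enrichment(table, 0.5))
        assert frame.loc["at", "class"] == "partial"   # exactly 0.5 not counted
        assert frame.loc["above", "class"] == "full"

    def test_missing_value_policy(self):
        table = pd.DataFrame(
            {"rep1": [np.nan, np.nan, 0.6], "rep2": [0.6, 0.6, np.nan],
             "rep3": [0.6, 0.1, np.nan]},
            index=["missing_full", "missing_low", "single"])
        frame = calls_to_frame(classify_enrichment(table, 0.5))
        # above threshold in all quantified replicates numbering n-1: partial
        assert frame.loc["missing_full", "class"] == "partial"
        assert frame.loc["missing_low", "class"] == "none"
        assert frame.loc["single", "class"] == "none"

    def test_misclassification_rate_bound(self):
        """At effect 1.0 and noise 0.1, planted proteins are essentially
        never misclassified (Monte-Carlo at reduced table size)."""
        errors = 0
        planted = 0
        for seed in range(1000):
            exp = simulate_tmt_experiment(30, ["P0001"], ["P0002"],
                                          effect_log2=1.0, noise_sd_log2=0.1,
                                          seed=seed)
            frame = calls_to_frame(
                classify_enrichment(log2_ratios(normalize_to_bait(exp)), 0.5))
            planted += 2
            errors += frame.loc["P0001", "class"] != "full"
            errors += frame.loc["P0002", "class"] != "partial"
        assert errors / planted < 1e-3


class TestRanking:
    def test_rank_descending_with_lexicographic_ties(self):
        ratios = pd.DataFrame({"rep1": [1.0, 1.0, 1.0, 1.0]},
                              index=["BAIT", "b", "a", "c"])
        abundance = pd.Series({"BAIT": 100.0, "b": 5.0, "a": 5.0, "c": 10.0})
        exp = TMTExperiment(ratios=ratios, bait="BAIT", abundance=abundance)
        ranks = rank_by_abundance(exp)
        assert ranks["BAIT"] == 1
        assert ranks["c"] == 2
        assert ranks["a"] == 3 and ranks["b"] == 4  # tie broken by id

    def test_rank_invariant_to_input_order(self):
        abundance = pd.Series({"x": 3.0, "y": 9.0, "z": 1.0, "BAIT": 99.0})
        ratios = pd.DataFrame({"rep1": [1.0] * 4}, index=list(abundance.index))
        shuffled = abundance.sample(frac=1.0, random_state=1)
        a = rank_by_abundance(TMTExperiment(ratios=ratios, bait="BAIT",
                                            abundance=abundance))
        b = rank_by_abundance(TMTExperiment(ratios=ratios, bait="BAIT",
                                            abundance=shuffled))
        assert a.sort_index().equals(b.sort_index())


class TestTimepoints:
    def _experiment(self, planted_late=(), seed=0):
        base = simulate_tmt_experiment(40, [], [], effect_log2=1.0,
                                       noise_sd_log2=0.0, seed=seed)
        late = simulate_tmt_experiment(40, list(planted_late), [],
                                       effect_log2=1.0, noise_sd_log2=0.0,
                                       seed=seed)
        return combine_timepoints({0: base, 60: late}, bait="BAIT")

    def test_identical_timepoints_on_diagonal(self):
        exp = self._experiment()
        pairs = compare_timepoints(normalize_to_bait(exp), 0, 60)
        np.testing.assert_allclose(pairs["log2_x"], pairs["log2_y"], atol=1e-12)
        assert not pairs["discordant"].any()

    def test_late_only_enrichment_flagged(self):
        late = ["P0005", "P0006", "P0007"]
        exp = self._experiment(planted_late=late)
        pairs = compare_timepoints(normalize_to_bait(exp), 0, 60)
        assert set(pairs.index[pairs["discordant"]]) == set(late)
        # brute force: above threshold at exactly one time point
        for protein, row in pairs.iterrows():
            expected = (row["log2_x"] > 0.5) != (row["log2_y"] > 0.5)
            assert row["discordant"] == expected

    def test_missing_timepoint_is_error(self):
        exp = self._experiment()
        with pytest.raises(ValueError, match="not present"):
            compare_timepoints(exp, 0, 120)
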