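import numpy as np
import pandas as pd
import pytest

from tfcoop.analysis import (cluster_enrichment, cluster_models,
                             composition_correlation,
                             differential_selection_test, gini_coefficient,
                             jaccard_index, knn_region_classifier,
                             motif_composition, target_pwm_inclusion)
from tfcoop.features import DINUC_CLASSES, MotifModel
from tfcoop.synthetic import random_motif_library


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_index({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard_index({1, 2}, {3, 4}) == 0.0

    def test_counting(self):
        assert jaccard_index({1, 2}, {2, 3, 4}) == 0.25

    def test_both_empty_convention(self):
        assert jaccard_index(set(), set()) == 0.0

    def test_symmetry_and_brute_force(self, rng):
        for _ in range(50):
            a = set(rng.integers(0, 20, size=rng.integers(0, 10)).tolist())
            b = set(rng.integers(0, 20, size=rng.integers(0, 10)).tolist())
            expected = (len(a & b) / len(a | b)) if (a | b) else 0.0
            assert jaccard_index(a, b) == expected == jaccard_index(b, a)


class TestEnrichmentStatistics:
    def test_hypergeometric_closed_form(self):
        # all 5 marked drawn in a sample of 5 from 10: p = 1/C(10,5)
        p = differential_selection_test(5, 5, 0, 5, method="hypergeometric")
        assert p == pytest.approx(1 / 252)

    def test_chi2_identical_proportions(self):
        p = differential_selection_test(50, 100, 50, 100, method="chi2")
        assert p > 0.99

    def test_chi2_extreme_table(self):
        p = differential_selection_test(20, 100, 80, 100, method="chi2")
        assert p < 1e-10

    def test_fisher_symmetric_table(self):
        assert differential_selection_test(5, 10, 5, 10, method="fisher") == 1.0

    def test_hypergeometric_matches_enumeration_small_n(self):
        from math import comb
        for k in range(4):
            p = differential_selection_test(k, 5, 3 - k, 7, "hypergeometric")
            total = comb(12, 3)
            expected = sum(comb(5, x) * comb(7, 3 - x) / total
                           for x in range(k, 4))
            assert p == pytest.approx(expected)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            differential_selection_test(6, 5, 0, 5)


class TestGini:
    def test_constant_vector_is_zero(self):
        assert gini_coefficient([3.0, 3.0, 3.0]) == pytest.approx(0.0)

    def test_two_sample_closed_form(self):
        assert gini_coefficient([0.0, 1.0]) == pytest.approx(0.5)

    def test_single_spike_approaches_one(self):
        n = 1000
        v = np.zeros(n)
        v[0] = 7.0
        assert gini_coefficient(v) == pytest.approx((n - 1) / n)

    def test_matches_mean_difference_definition(self, rng):
        for _ in range(10):
            x = rng.random(30)
            direct = np.abs(x[:, None] - x[None, :]).sum() / (
                2 * len(x) ** 2 * x.mean())
            assert gini_coefficient(x) == pytest.approx(direct)


class TestClusterModels:
    def test_two_block_recovery(self):
        rows = [[1, 1, 1, 0, 0, 0]] * 5 + [[0, 0, 0, 1, 1, 1]] * 5
        S = pd.DataFrame(rows, index=[f"m{i}" for i in range(10)])
        labels, disp = cluster_models(S, k_values=[2], restarts=50, seed=0)
        lab = labels[2]
        assert len(set(lab[:5])) == 1 and len(set(lab[5:])) == 1
        assert lab.iloc[0] != lab.iloc[9]
        assert disp[2] == pytest.approx(0.0, abs=1e-12)

    def test_k1_equals_total_dispersion(self, rng):
        S = pd.DataFrame(rng.integers(0, 2, size=(12, 6)).astype(float))
        _, disp = cluster_models(S, k_values=[1], restarts=10, seed=0)
        total = ((S - S.mean()) ** 2).to_numpy().sum()
        assert disp[1] == pytest.approx(total)

    def test_dispersion_non_increasing_in_k(self, rng):
        S = pd.DataFrame(rng.integers(0, 2, size=(25, 8)).astype(float))
        _, disp = cluster_models(S, k_values=[1, 2, 3, 4], restarts=50, seed=1)
        vals = [disp[k] for k in (1, 2, 3, 4)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


class _FakeModel:
    def __init__(self, selected):
        self.selected = selected


class TestTargetPwmInclusion:
    def _scores(self, rng):
        S = pd.DataFrame(rng.normal(size=(50, 3)),
                         columns=["target", "twin", "other"])
        S["twin"] = S["target"] * 2 + 1  # perfectly correlated duplicate
        return S

    def test_target_itself_selected(self, rng):
        m = _FakeModel({"min": ["target", "other"]})
        assert target_pwm_inclusion(m, "target", self._scores(rng)) == \
            "target_selected"

    def test_correlated_surrogate_detected(self, rng):
        m = _FakeModel({"min": ["twin"]})
        assert target_pwm_inclusion(m, "target", self._scores(rng)) == \
            "similar_selected"

    def test_threshold_above_one_excludes_similarity(self, rng):
        m = _FakeModel({"min": ["twin"]})
        assert target_pwm_inclusion(m, "target", self._scores(rng),
                                    similarity_threshold=1.01) == "neither"

    def test_nothing_relevant_selected(self, rng):
        m = _FakeModel({"min": ["other"]})
        assert target_pwm_inclusion(m, "target", self._scores(rng)) == "neither"


class TestMotifComposition:
    def test_rates_normalized(self):
        m = MotifModel("t", "m", np.array(
            [[8, 1, 1, 0], [0, 5, 5, 0], [2, 2, 2, 4]], dtype=float))
        comp = motif_composition(m)
        assert comp["A|T"] + comp["G|C"] == pytest.approx(1.0)
        W = m.width
        assert comp[list(DINUC_CLASSES)].sum() == pytest.approx((W - 1) / W)

    def test_composition_correlation_groups(self):
        lib = random_motif_library(20, seed=1)
        target = lib[0]
        selected = [(lib[1], +1.0), (lib[2], +1.0), (lib[3], -1.0)]
        out = composition_correlation(target, selected, lib, seed=0)
        assert set(out) == {"r_positive", "r_negative", "r_control"}
        for v in out.values():
            assert -1.0 <= v <= 1.0

    def test_control_is_seed_reproducible(self):
        lib = random_motif_library(15, seed=2)
        sel = [(lib[1], 1.0), (lib[2], -1.0)]
        a = composition_correlation(lib[0], sel, lib, seed=5)
        b = composition_correlation(lib[0], sel, lib, seed=5)
        c = composition_correlation(lib[0], sel, lib, seed=6)
        assert a == b
        assert a["r_control"] != c["r_control"]


class TestClusterEnrichment:
    def test_enriched_term_found(self):
        clusters = {f"g{i}": (0 if i < 20 else 1) for i in range(40)}
        annotated = {f"g{i}" for i in range(18)}  # almost all in cluster 0
        table, best = cluster_enrichment(clusters, {"termA": annotated})
        assert best["termA"] < 1e-4
        row = table.loc[(table["cluster"] == 0) & (table["term"] == "termA")]
        assert row["p_value"].iloc[0] == best["termA"]

    def test_bh_q_at_least_p(self):
        clusters = {f"g{i}": i % 3 for i in range(30)}
        sets = {"t1": {f"g{i}" for i in range(0, 30, 3)},
                "t2": {f"g{i}" for i in range(5)}}
        table, _ = cluster_enrichment(clusters, sets)
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()
        assert (table["q_value"] <= 1.0).all()


class TestKnnRegions:
    def test_separable_descriptions_give_low_error(self, rng):
        prom = pd.DataFrame(rng.normal(0, 1, size=(60, 4)))
        enh = pd.DataFrame(rng.normal(4, 1, size=(60, 4)))
        errors = knn_region_classifier(prom, enh, k_values=range(1, 6),
                                       split_seed=0)
        assert (errors < 0.1).all()

    def test_uninformative_description_near_chance(self, rng):
        prom = pd.DataFrame(rng.normal(size=(80, 3)))
        enh = pd.DataFrame(rng.normal(size=(80, 3)))
        errors = knn_region_classifier(prom, enh, k_values=[5, 10],
                                       split_seed=1)
        assert (errors > 0.2).all()

    def test_no_common_columns_rejected(self, rng):
        prom = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        enh = pd.DataFrame(rng.normal(size=(10, 2)), columns=["c", "d"])
        with pytest.raises(ValueError, match="common"):
            knn_region_classifier(prom, enh, k_values=[1])
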