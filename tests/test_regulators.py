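"""miRNA-target correlations, negative-shift test and regulator nomination."""

import numpy as np
import pandas as pd
import pytest

from mirtraj import (GeneSetCollection, anticorrelated_target_enrichment,
                     nominate_regulators, pair_correlations,
                     regulator_shift_test)
from mirtraj.regulators import _shift_p

from oracles import wilcoxon_less_p


def _expr(rows, ids, n=6):
    return pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(n)])


def _edges(pairs):
    return pd.DataFrame(pairs, columns=["mirna_id", "target_gene_id"])


class TestPairCorrelations:
    def test_perfect_anticorrelation(self):
        mirna = _expr([[1, 0, -1]], ["m1"], n=3)
        mrna = _expr([[-1, 0, 1]], ["g1"], n=3)
        pairs = pair_correlations(mirna, mrna, _edges([("m1", "g1")]))
        assert pairs.iloc[0]["r"] == pytest.approx(-1.0)
        assert pairs.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_constant_endpoint_dropped(self):
        mirna = _expr([[1, 0, -1]], ["m1"], n=3)
        mrna = _expr([[5, 5, 5]], ["g1"], n=3)
        pairs = pair_correlations(mirna, mrna, _edges([("m1", "g1")]))
        assert pairs.empty

    def test_absent_endpoint_dropped(self):
        mirna = _expr([[1, 0, -1]], ["m1"], n=3)
        mrna = _expr([[1, 2, 3]], ["g1"], n=3)
        pairs = pair_correlations(mirna, mrna,
                                  _edges([("m1", "g1"), ("m1", "g_missing")]))
        assert len(pairs) == 1

    def test_sample_mismatch_rejected(self):
        mirna = _expr([[1, 0, -1]], ["m1"], n=3)
        mrna = _expr([[1, 2, 3]], ["g1"], n=3)
        mrna.columns = ["x0", "x1", "x2"]
        with pytest.raises(ValueError, match="different samples"):
            pair_correlations(mirna, mrna, _edges([("m1", "g1")]))

    def test_independent_vectors_mean_r_near_zero(self, rng):
        n_edges, n = 1000, 12
        mirna = _expr(rng.normal(size=(n_edges, n)),
                      [f"m{i}" for i in range(n_edges)], n=n)
        mrna = _expr(rng.normal(size=(n_edges, n)),
                     [f"g{i}" for i in range(n_edges)], n=n)
        pairs = pair_correlations(mirna, mrna,
                                  _edges([(f"m{i}", f"g{i}") for i in range(n_edges)]))
        se = 1 / np.sqrt(n - 1) / np.sqrt(n_edges)
        assert abs(pairs["r"].mean()) < 3 * se

    def test_agrees_with_scipy_pearson(self, rng):
        from scipy.stats import pearsonr, spearmanr
        mirna = _expr(rng.normal(size=(1, 10)), ["m1"], n=10)
        mrna = _expr(rng.normal(size=(1, 10)), ["g1"], n=10)
        pairs = pair_correlations(mirna, mrna, _edges([("m1", "g1")]))
        assert pairs.iloc[0]["r"] == pytest.approx(
            pearsonr(mirna.iloc[0], mrna.iloc[0]).statistic, abs=1e-12)
        assert pairs.iloc[0]["rho"] == pytest.approx(
            spearmanr(mirna.iloc[0], mrna.iloc[0]).statistic, abs=1e-12)


class TestShiftTest:
    def test_all_negative_ten_targets_exact_p(self):
        r = -np.linspace(0.1, 0.9, 10)
        assert _shift_p(r) == pytest.approx(1 / 1024, abs=1e-12)

    def test_symmetric_values_not_significant(self):
        r = np.array([0.3, -0.3, 0.2, -0.2, 0.1, -0.1])
        assert _shift_p(r) >= 0.4

    def test_exact_branch_matches_sign_enumeration(self, rng):
        for n in range(5, 13):
            mags = rng.uniform(0.05, 1.0, size=n)
            for _ in range(8):
                signs = rng.choice([-1.0, 1.0], size=n)
                r = signs * mags
                assert _shift_p(r) == pytest.approx(wilcoxon_less_p(r), abs=1e-12)

    def test_below_min_targets_omitted(self):
        pairs = pd.DataFrame({"mirna_id": ["m1"] * 4 + ["m2"] * 5,
                              "target_gene_id": [f"g{i}" for i in range(9)],
                              "r": [-0.5] * 9, "rho": [-0.5] * 9, "n": 12})
        shift = regulator_shift_test(pairs, min_targets=5)
        assert list(shift.index) == ["m2"]
        assert shift.loc["m2", "n_targets"] == 5


class TestNomination:
    @pytest.fixture
    def inputs(self):
        shift = pd.DataFrame(
            {"n_targets": [10, 10, 10, 10],
             "mean_r": [-0.6, -0.4, -0.6, -0.5],
             "mean_rho": [-0.5, -0.4, -0.5, -0.4],
             "p_shift": [0.001, 0.001, 1e-6, 0.2]},
            index=pd.Index(["m1", "m2", "m3", "m4"], name="mirna_id"))
        mirna_classes = pd.Series({"m1": "down_down", "m2": "down_up",
                                   "m3": "up_up", "m4": "down_down"})
        mrna_classes = pd.Series({"g1": "up_up", "g2": "up_down",
                                  "g3": "unclassified", "g4": "up_up"})
        pairs = pd.DataFrame({
            "mirna_id": ["m1", "m1", "m1", "m2", "m2", "m3"],
            "target_gene_id": ["g1", "g2", "g3", "g1", "g4", "g2"],
            "r": [-0.8, -0.5, -0.9, 0.2, -0.3, -0.9],
            "rho": [-0.7, -0.4, -0.8, 0.1, -0.2, -0.8], "n": 12})
        return shift, mirna_classes, mrna_classes, pairs

    def test_direction_filter_excludes_up_class_mirna(self, inputs):
        table = nominate_regulators(*inputs)
        assert not table.loc["m3", "candidate"]      # up_up despite p = 1e-6
        assert not table.loc["m4", "candidate"]      # down class but p = 0.2
        assert table.loc["m1", "candidate"] and table.loc["m2", "candidate"]

    def test_anticorrelated_targets_up_classes_only(self, inputs):
        table = nominate_regulators(*inputs)
        # g3 is unclassified, g1 has r > 0 for m2
        assert table.loc["m1", "anticorrelated_targets"] == "g1;g2"
        assert table.loc["m2", "anticorrelated_targets"] == "g4"

    def test_ranking_by_p_with_mean_r_tie_break(self, inputs):
        shift, mirna_classes, mrna_classes, pairs = inputs
        shift = shift.copy()
        shift.loc["m2", "p_shift"] = 0.001   # tie with m1; m1 has lower mean_r
        table = nominate_regulators(shift, mirna_classes, mrna_classes, pairs)
        assert table.loc["m1", "rank"] == 1.0
        assert table.loc["m2", "rank"] == 2.0
        assert np.isnan(table.loc["m3", "rank"])

    def test_flavor_labels(self, inputs):
        table = nominate_regulators(*inputs)
        assert table.loc["m1", "flavor"] == "down_enhanced"
        assert table.loc["m2", "flavor"] == "down_counteracted"

    def test_invariant_to_target_map_row_order(self, small_dataset):
        from mirtraj import log_cpm, standardize_features, tmm_factors
        mrna_z, _ = standardize_features(
            log_cpm(small_dataset.mrna_counts,
                    tmm_factors(small_dataset.mrna_counts)))
        mirna_z, _ = standardize_features(
            log_cpm(small_dataset.mirna_counts,
                    tmm_factors(small_dataset.mirna_counts)))
        edges = small_dataset.target_map
        shuffled = edges.sample(frac=1.0, random_state=9).reset_index(drop=True)
        p1 = pair_correlations(mirna_z, mrna_z, edges)
        p2 = pair_correlations(mirna_z, mrna_z, shuffled)
        pd.testing.assert_frame_equal(p1, p2)
        s1 = regulator_shift_test(p1)
        s2 = regulator_shift_test(p2)
        pd.testing.assert_frame_equal(s1, s2)


class TestTargetEnrichment:
    def test_pools_disjoint_and_planted_set_top(self, rng):
        genes = [f"g{i}" for i in range(200)]
        mrna_classes = pd.Series("unclassified", index=pd.Index(genes))
        mrna_classes.iloc[:40] = "up_up"
        mrna_classes.iloc[40:80] = "up_down"
        up_down_pool = genes[40:80]
        # phenotype set drawing 60% from the up_down pool
        phenotype = set(rng.choice(up_down_pool, 24, replace=False)) | set(
            rng.choice(genes[80:], 16, replace=False))
        collection = GeneSetCollection(sets={
            "phenotype": frozenset(phenotype),
            "background": frozenset(rng.choice(genes, 40, replace=False))})
        regulators = pd.DataFrame(
            {"candidate": [True], "anticorrelated_targets":
             [";".join(genes[20:30] + genes[50:70])]},
            index=pd.Index(["m1"], name="mirna_id"))
        table = anticorrelated_target_enrichment(regulators, mrna_classes,
                                                 collection, genes)
        queries = set(table["query"])
        assert queries == {"up_up_targets", "up_down_targets"}
        top_up_down = table[table["query"] == "up_down_targets"].iloc[0]
        assert top_up_down["set"] == "phenotype"

    def test_no_candidates_empty_output(self):
        regulators = pd.DataFrame(
            {"candidate": [False], "anticorrelated_targets": [""]},
            index=pd.Index(["m1"], name="mirna_id"))
        collection = GeneSetCollection(sets={"s": frozenset({"g1"})})
        table = anticorrelated_target_enrichment(
            regulators, pd.Series({"g1": "up_up"}), collection, {"g1", "g2"})
        assert table.empty
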