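"""Fisher-exact over-representation, collections, and GMT/TSV parsing."""

import numpy as np
import pytest

from mirtraj import (GeneSetCollection, enrich_collection, fisher_enrichment,
                     read_gene_sets)

from oracles import hypergeom_upper_tail

UNIVERSE = {f"g{i}" for i in range(20)}


class TestFisher:
    def test_documented_example(self):
        # universe 20, query 5, set 6, overlap 4: p = P(X=4) + P(X=5)
        query = {"g0", "g1", "g2", "g3", "g4"}
        target = {"g0", "g1", "g2", "g3", "g10", "g11"}
        rec = fisher_enrichment(query, target, UNIVERSE)
        assert rec["overlap"] == 4
        assert rec["pvalue"] == pytest.approx(0.013931, abs=1e-6)
        assert rec["pvalue"] == pytest.approx(
            hypergeom_upper_tail(4, 20, 6, 5), abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        rec = fisher_enrichment({"g0"}, {"g10", "g11"}, UNIVERSE)
        assert rec["pvalue"] == 1.0

    def test_query_equals_set_equals_universe(self):
        rec = fisher_enrichment(UNIVERSE, UNIVERSE, UNIVERSE)
        assert rec["pvalue"] == 1.0

    def test_table_sums_to_universe(self):
        rec = fisher_enrichment({"g0", "g1"}, {"g1", "g2", "g3"}, UNIVERSE)
        total = rec["overlap"] + rec["query_only"] + rec["set_only"] + rec["neither"]
        assert total == len(UNIVERSE)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            fisher_enrichment({"zzz"}, {"g0"}, UNIVERSE)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_rational_tail_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_univ = int(rng.integers(10, 2000))
        universe = [f"f{i}" for i in range(n_univ)]
        query = set(rng.choice(universe, size=int(rng.integers(1, n_univ // 2 + 1)),
                               replace=False))
        target = set(rng.choice(universe, size=int(rng.integers(1, n_univ // 2 + 1)),
                                replace=False))
        rec = fisher_enrichment(query, target, universe)
        expected = hypergeom_upper_tail(rec["overlap"], n_univ, len(target),
                                        len(query))
        assert rec["pvalue"] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_feature_relabeling(self, rng):
        universe = [f"f{i}" for i in range(100)]
        query = set(universe[:20])
        target = set(universe[10:40])
        p1 = fisher_enrichment(query, target, universe)["pvalue"]
        mapping = dict(zip(universe, rng.permutation(universe)))
        p2 = fisher_enrichment({mapping[g] for g in query},
                               {mapping[g] for g in target},
                               universe)["pvalue"]
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_random_queries_are_conservative(self, rng):
        """Discreteness makes the p distribution dominate uniform."""
        universe = [f"f{i}" for i in range(200)]
        target = set(universe[:30])
        pvals = []
        for _ in range(400):
            query = set(rng.choice(universe, size=25, replace=False))
            pvals.append(fisher_enrichment(query, target, universe)["pvalue"])
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            assert (pvals <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 400)


class TestCollection:
    def test_all_pairs_tested_with_bh_across_table(self):
        collection = GeneSetCollection(
            sets={f"set{j}": frozenset({f"g{j}", f"g{j+1}"}) for j in range(5)})
        queries = {f"q{i}": {f"g{i}", f"g{i+2}"} for i in range(4)}
        table = enrich_collection(queries, collection, UNIVERSE)
        assert len(table) == 20
        assert (table["fdr"] >= table["pvalue"] - 1e-12).all()

    def test_planted_enrichment_is_top_ranked(self, rng):
        universe = [f"f{i}" for i in range(400)]
        special = set(universe[:40])
        # query holds 50% of the special set vs ~5% background
        query = set(rng.choice(sorted(special), 20, replace=False)) | set(
            rng.choice(universe[40:], 18, replace=False))
        decoy_sets = {f"bg{j}": frozenset(rng.choice(universe, 40, replace=False))
                      for j in range(4)}
        collection = GeneSetCollection(sets={"special": frozenset(special), **decoy_sets})
        table = enrich_collection({"q": query}, collection, universe)
        assert table.iloc[0]["set"] == "special"
        assert table.iloc[0]["fdr"] == table["fdr"].min()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection(sets={"a": frozenset()})

    def test_set_outside_universe_skipped_with_warning(self):
        collection = GeneSetCollection(sets={"out": frozenset({"zzz"}),
                                             "in": frozenset({"g0", "g1"})})
        with pytest.warns(UserWarning, match="skipped"):
            table = enrich_collection({"q": {"g0"}}, collection, UNIVERSE)
        assert list(table["set"]) == ["in"]


class TestReadGeneSets:
    def test_gmt_line(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("skin\tna\tKrt14\tFlg\tLor\nbone\tna\tRunx2\tSp7\n")
        collection = read_gene_sets(path, fmt="gmt")
        assert collection.sets["skin"] == {"Krt14", "Flg", "Lor"}
        assert collection.sets["bone"] == {"Runx2", "Sp7"}

    def test_gmt_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("skin\tna\tKrt14\nshort\tna\n")
        with pytest.raises(ValueError, match=":2:"):
            read_gene_sets(path, fmt="gmt")

    def test_gmt_duplicate_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("s\tna\ta\ns\tna\tb\n")
        with pytest.raises(ValueError, match="duplicate set name"):
            read_gene_sets(path, fmt="gmt")

    def test_tsv_duplicate_pair_warns_but_set_unchanged(self, tmp_path):
        path = tmp_path / "sets.tsv"
        path.write_text("skin\tKrt14\nskin\tFlg\nskin\tKrt14\n")
        with pytest.warns(UserWarning, match="duplicate pair"):
            collection = read_gene_sets(path, fmt="tsv")
        assert collection.sets["skin"] == {"Krt14", "Flg"}

    def test_empty_file_empty_collection(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            collection = read_gene_sets(path)
        assert len(collection) == 0
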