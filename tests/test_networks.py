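import math

import numpy as np
import pandas as pd
import pytest

from acetrend.networks import (
    InteractionEdge,
    filter_by_score,
    hypergeom_enrich,
    read_edge_table,
    read_gmt,
    target_overlap,
)


def write_tsv(path, rows, header="source\ttarget\tscore"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))


class TestReadEdgeTable:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "edges.tsv"
        write_tsv(p, ["Hdac1\tTrp53\t900", "Hdac1\tE2f4\t350", "Kat2b\tSirt1\t210"])
        edges = read_edge_table(p, "ppi")
        assert len(edges) == 3
        assert all(e.evidence == "ppi" for e in edges)

    def test_malformed_score_reported_with_line(self, tmp_path):
        p = tmp_path / "edges.tsv"
        write_tsv(p, ["Hdac1\tTrp53\tNA", "Hdac1\tE2f4\t350"])
        with pytest.warns(UserWarning, match=r"line\(s\) \[2\]"):
            edges = read_edge_table(p, "ppi")
        assert len(edges) == 1

    def test_duplicate_keeps_max_score(self, tmp_path):
        p = tmp_path / "edges.tsv"
        write_tsv(p, ["Hdac1\tTrp53\t300", "Hdac1\tTrp53\t700", "Hdac1\tTrp53\t100"])
        with pytest.warns(UserWarning, match="deduplicated"):
            edges = read_edge_table(p, "ppi")
        assert len(edges) == 1
        assert edges[0].score == 700

    def test_tf_table_score_optional(self, tmp_path):
        p = tmp_path / "tf.tsv"
        write_tsv(p, ["Hdac1\tTrp53", "Kat2b\tRbpj"], header="source\ttarget")
        edges = read_edge_table(p, "tf_target")
        assert len(edges) == 2
        assert all(e.score == 1000.0 for e in edges)

    def test_missing_columns_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_edge_table(p, "ppi")

    def test_self_loops_dropped(self, tmp_path):
        p = tmp_path / "edges.tsv"
        write_tsv(p, ["Hdac1\tHdac1\t500", "Hdac1\tTrp53\t500"])
        edges = read_edge_table(p, "ppi")
        assert [e.target for e in edges] == ["Trp53"]


class TestFilterByScore:
    def test_strictly_greater(self):
        edges = [
            InteractionEdge("h", f"t{s}", s, "ppi") for s in (150.0, 200.0, 201.0)
        ]
        kept = filter_by_score(edges, 200)
        assert [e.score for e in kept] == [201.0]

    def test_empty_input(self):
        assert filter_by_score([], 200) == []

    def test_identity_when_all_pass(self):
        edges = [InteractionEdge("h", f"t{i}", 1000.0, "ppi") for i in range(5)]
        assert filter_by_score(edges, 200) == edges

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        edges = [
            InteractionEdge("h", f"t{i}", float(rng.uniform(1, 1000)), "ppi")
            for i in range(50)
        ]
        once = filter_by_score(edges)
        assert filter_by_score(once) == once


class TestTargetOverlap:
    def test_three_disjoint_sets(self):
        edges = [
            InteractionEdge("A", "x", 500, "ppi"),
            InteractionEdge("A", "y", 500, "ppi"),
            InteractionEdge("B", "y", 500, "ppi"),
            InteractionEdge("B", "z", 500, "ppi"),
        ]
        shared, a_only, b_only = target_overlap(edges, "A", "B")
        assert (shared, a_only, b_only) == ({"y"}, {"x"}, {"z"})

    def test_absent_hub_warns_and_empties(self):
        edges = [InteractionEdge("A", "x", 500, "ppi")]
        with pytest.warns(UserWarning, match="no edges"):
            shared, a_only, b_only = target_overlap(edges, "A", "Missing")
        assert shared == a_only == b_only == set()

    def test_identical_neighborhoods(self):
        edges = [
            InteractionEdge(h, t, 500, "ppi")
            for h in ("A", "B")
            for t in ("x", "y")
        ]
        shared, a_only, b_only = target_overlap(edges, "A", "B")
        assert shared == {"x", "y"} and not a_only and not b_only

    def test_undirected_neighbors(self):
        edges = [InteractionEdge("x", "A", 500, "ppi"), InteractionEdge("B", "x", 500, "ppi")]
        shared, _, _ = target_overlap(edges, "A", "B")
        assert shared == {"x"}


def brute_force_upper_tail(N, K, n, k):
    """P(X >= k) by direct combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestHypergeomEnrich:
    def test_worked_example(self):
        # N=20, K=5, n=5, k=3 -> 1126/15504
        universe = {f"g{i}" for i in range(20)}
        term = [f"g{i}" for i in range(5)]
        query = {"g0", "g1", "g2", "g10", "g11"}
        out = hypergeom_enrich(query, {"t": ("d", term)}, universe)
        assert out.iloc[0]["p_value"] == pytest.approx(1126 / 15504, rel=1e-12)

    def test_brute_force_all_small_instances(self):
        """Agrees with enumeration for every (N<=25, K, n, k) sampled grid."""
        rng = np.random.default_rng(2)
        for _ in range(60):
            N = int(rng.integers(2, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"g{i}" for i in range(N)}
            term = [f"g{i}" for i in range(K)]
            query = set(rng.choice(sorted(universe), size=n, replace=False))
            k = len(query & set(term))
            out = hypergeom_enrich(query, {"t": ("d", term)}, universe)
            assert out.iloc[0]["overlap_k"] == k
            assert out.iloc[0]["p_value"] == pytest.approx(
                brute_force_upper_tail(N, K, n, k), abs=1e-10
            )

    def test_saturated_query(self):
        universe = {f"g{i}" for i in range(10)}
        out = hypergeom_enrich(
            universe, {"t": ("d", ["g0", "g1", "g2"])}, universe
        )
        assert out.iloc[0]["overlap_k"] == 3
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_zero_overlap_is_maximal_p(self):
        universe = {f"g{i}" for i in range(15)}
        term = ["g0", "g1", "g2", "g3"]
        q_hit = {"g0", "g4", "g5"}
        q_miss = {"g4", "g5", "g6"}
        p_hit = hypergeom_enrich(q_hit, {"t": ("d", term)}, universe).iloc[0]["p_value"]
        p_miss = hypergeom_enrich(q_miss, {"t": ("d", term)}, universe).iloc[0]["p_value"]
        assert p_miss == pytest.approx(1.0)
        assert p_miss >= p_hit

    def test_bh_permutation_invariance(self):
        rng = np.random.default_rng(3)
        universe = {f"g{i}" for i in range(50)}
        terms = {
            f"term{j}": ("d", list(rng.choice(sorted(universe), size=10, replace=False)))
            for j in range(8)
        }
        query = set(rng.choice(sorted(universe), size=12, replace=False))
        out1 = hypergeom_enrich(query, terms, universe)
        shuffled = dict(reversed(list(terms.items())))
        out2 = hypergeom_enrich(query, shuffled, universe)
        pd.testing.assert_frame_equal(out1, out2)

    def test_bh_is_monotone_step_up(self):
        rng = np.random.default_rng(4)
        universe = {f"g{i}" for i in range(40)}
        terms = {
            f"t{j}": ("d", list(rng.choice(sorted(universe), size=8, replace=False)))
            for j in range(10)
        }
        query = set(rng.choice(sorted(universe), size=10, replace=False))
        out = hypergeom_enrich(query, terms, universe)
        assert out["p_value"].is_monotonic_increasing
        assert out["q_value"].between(0, 1).all()
        # step-up: q_i = min over j >= i of (m * p_j / rank_j)
        m = len(out)
        raw = (out["p_value"] * m / np.arange(1, m + 1)).to_numpy()
        expected_q = np.minimum.accumulate(raw[::-1])[::-1].clip(max=1.0)
        assert np.allclose(out["q_value"], expected_q)

    def test_stray_query_genes_dropped_with_warning(self):
        universe = {"a", "b", "c", "d"}
        with pytest.warns(UserWarning, match="outside the universe"):
            out = hypergeom_enrich({"a", "zzz"}, {"t": ("d", ["a", "b"])}, universe)
        assert out.iloc[0]["query_size_n"] == 1

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrich({"a"}, {"t": ("d", ["a"])}, set())


class TestGmt:
    def test_round_trip(self, tmp_path):
        from acetrend.simulate import write_gmt

        terms = {"cc": ("cell cycle", ["a", "b"]), "x": ("other", ["c"])}
        p = tmp_path / "t.gmt"
        write_gmt(terms, p)
        assert read_gmt(p) == terms

    def test_malformed_line_errors(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("term_only\tdescription\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(p)
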