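import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spcprof.diff import ComparisonReport, DiffRecord
from spcprof.errors import ValidationError
from spcprof.network import (
    PpiNetwork,
    color_by_state,
    hypergeom_enrich,
    induced_subnetwork,
    load_network,
)
from spcprof.profiling import CohortProfile


def hypergeom_tail_oracle(k, big_n, big_k, n):
    """Exhaustive hypergeometric upper tail from binomial coefficients."""
    total = math.comb(big_n, n)
    return sum(
        math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
        for i in range(k, min(big_k, n) + 1)
    ) / total


def bh_oracle(p_values):
    """Hand step-up BH: q_i = min_{j>=i} (m * p_(j) / j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p_values[i] / rank)
        q[i] = prev
    return q


class TestLoadNetwork:
    def test_cleaning_rules(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nB\tA\nA\tA\n")
        net = load_network(path)
        assert net.n_nodes == 2 and net.n_edges == 1

    def test_empty_file(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("")
        net = load_network(path)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_sif_dialect(self, tmp_path):
        path = tmp_path / "edges.sif"
        path.write_text("A\tpp\tB\tC\nD\tpp\tE\n")
        net = load_network(path)
        assert net.edges == {frozenset(e) for e in [("A", "B"), ("A", "C"), ("D", "E")]}

    def test_gene_symbols_uppercased(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("rac1\tvav2\n")
        net = load_network(path)
        assert net.nodes == {"RAC1", "VAV2"}

    def test_handshake_lemma_fuzz(self, tmp_path, rng):
        genes = [f"N{i}" for i in range(30)]
        lines = []
        for _ in range(100):
            a, b = rng.choice(genes, 2, replace=False)
            lines.append(f"{a}\t{b}")
        path = tmp_path / "edges.tsv"
        path.write_text("\n".join(lines) + "\n")
        net = load_network(path)
        assert sum(d for _, d in net.graph.degree) == 2 * net.n_edges


class TestInducedSubnetwork:
    def triangle(self):
        return PpiNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])

    def test_triangle_subset(self):
        sub = induced_subnetwork(self.triangle(), {"A", "B"})
        assert sub.n_nodes == 2 and sub.n_edges == 1

    def test_disjoint_query(self):
        sub = induced_subnetwork(self.triangle(), {"X", "Y"})
        assert sub.n_nodes == 0 and sub.n_edges == 0

    def test_min_degree_drops_isolated(self):
        net = PpiNetwork.from_edges([("A", "B"), ("C", "D")])
        sub = induced_subnetwork(net, {"A", "B", "C"}, min_degree=1)
        assert sub.nodes == {"A", "B"}

    def test_idempotent(self, rng):
        edges = [(f"N{rng.integers(0, 20)}", f"N{rng.integers(0, 20)}")
                 for _ in range(60)]
        net = PpiNetwork.from_edges([e for e in edges if e[0] != e[1]])
        query = {f"N{i}" for i in range(0, 20, 2)}
        once = induced_subnetwork(net, query)
        twice = induced_subnetwork(once, query)
        assert once.nodes == twice.nodes and once.edges == twice.edges

    @pytest.mark.parametrize("seed", range(20))
    def test_erdos_renyi_oracle_equivalence(self, seed):
        # subgraph edges == brute-force filter of the raw edge list
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        p = 0.2
        nodes = [f"N{i}" for i in range(n)]
        edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < p]
        if not edges:
            edges = [(nodes[0], nodes[1])]
        net = PpiNetwork.from_edges(edges)
        query = {g for g in nodes if rng.random() < 0.5}
        sub = induced_subnetwork(net, query)
        expected = {frozenset((a, b)) for a, b in edges
                    if a in query and b in query}
        assert sub.edges == expected
        assert sub.nodes == query & net.nodes


class TestColorByState:
    def _profiles(self):
        return {
            "Wt": CohortProfile("Wt", pd.Series({"A": 10.0, "B": 5.0}), 7),
            "Ho": CohortProfile("Ho", pd.Series({"A": 2.0, "B": 20.0}), 6),
        }

    def test_flag_pass_through(self):
        net = PpiNetwork.from_edges([("A", "B")])
        report = ComparisonReport(
            ("Wt", "Ho"),
            [DiffRecord("B", 5.0, 20.0, -1.2, -187.5, "up_in_Y")],
            0.4, 15.0,
        )
        table = color_by_state(net, self._profiles(), [report])
        row = table[table["node"] == "B"].iloc[0]
        assert row["state_Wt_vs_Ho"] == "up_in_Y"

    def test_missing_marker(self):
        net = PpiNetwork.from_edges([("A", "Z")])
        table = color_by_state(net, self._profiles())
        row = table[table["node"] == "Z"].iloc[0]
        assert bool(row["missing"])

    def test_row_count_matches_nodes(self, rng):
        edges = [(f"N{rng.integers(0, 15)}", f"N{15 + rng.integers(0, 15)}")
                 for _ in range(40)]
        net = PpiNetwork.from_edges(edges)
        table = color_by_state(net, self._profiles())
        assert len(table) == net.n_nodes


class TestHypergeomEnrich:
    def test_exact_combinatorial_example(self):
        # N=10, K=5, n=2, k=2 -> C(5,2)/C(10,2) = 10/45
        universe = [f"g{i}" for i in range(10)]
        terms = {g: {"T"} for g in universe[:5]}
        records = hypergeom_enrich(universe[:2], universe, terms)
        rec = records[0]
        assert (rec.k, rec.big_k, rec.n, rec.big_n) == (2, 5, 2, 10)
        assert rec.p_value == pytest.approx(10 / 45)

    def test_k_zero_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        terms = {g: {"T"} for g in universe[5:]}
        records = hypergeom_enrich(universe[:3], universe, terms)
        assert records[0].k == 0
        assert records[0].p_value == pytest.approx(1.0)

    def test_bh_hand_example(self):
        # p = (0.01, 0.02, 0.03) -> q = (0.03, 0.03, 0.03)
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        assert np.allclose(q, [0.03, 0.03, 0.03])
        assert np.allclose(bh_oracle([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrich({"x"}, {"a", "b"}, {})

    @pytest.mark.parametrize("seed", range(15))
    def test_pvalues_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        big_n = int(rng.integers(5, 31))
        universe = [f"g{i}" for i in range(big_n)]
        terms = {}
        for g in universe:
            for t in ("T1", "T2", "T3"):
                if rng.random() < 0.4:
                    terms.setdefault(g, set()).add(t)
        query = {g for g in universe if rng.random() < 0.4}
        records = hypergeom_enrich(query, universe, terms)
        for rec in records:
            expected = hypergeom_tail_oracle(rec.k, rec.big_n, rec.big_k, rec.n)
            assert rec.p_value == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_q_values_match_bh_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        big_n = 25
        universe = [f"g{i}" for i in range(big_n)]
        terms = {}
        for g in universe:
            for t in (f"T{j}" for j in range(6)):
                if rng.random() < 0.3:
                    terms.setdefault(g, set()).add(t)
        query = {g for g in universe if rng.random() < 0.5}
        records = hypergeom_enrich(query, universe, terms)
        if not records:
            return
        q_ref = bh_oracle([r.p_value for r in records])
        for rec, q in zip(records, q_ref):
            assert rec.q_value == pytest.approx(q, rel=1e-10)

    def test_bh_monotone_after_stepup(self, rng):
        universe = [f"g{i}" for i in range(30)]
        terms = {}
        for g in universe:
            for t in (f"T{j}" for j in range(8)):
                if rng.random() < 0.3:
                    terms.setdefault(g, set()).add(t)
        query = {g for g in universe if rng.random() < 0.5}
        records = hypergeom_enrich(query, universe, terms)
        by_p = sorted(records, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert all(a <= b + 1e-15 for a, b in zip(qs, qs[1:]))

    def test_significance_flag_respects_alpha(self):
        universe = [f"g{i}" for i in range(20)]
        terms = {g: {"T"} for g in universe[:10]}
        records = hypergeom_enrich(set(universe[:10]), universe, terms, alpha=1e-6)
        for rec in records:
            assert rec.significant == (rec.q_value <= 1e-6)


class TestSelfLoopInvariant:
    def test_network_refuses_self_loops(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("A", "A")
        with pytest.raises(ValidationError):
            PpiNetwork(g)
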