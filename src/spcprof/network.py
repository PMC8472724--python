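"""PPI subnetwork mapping and hypergeometric term enrichment.

Networks are simple undirected graphs over upper-cased gene symbols.
Loading cleans self-loops and duplicate edges; subnetwork extraction
induces the subgraph on a query gene set. Enrichment uses the upper-tail
hypergeometric test with Benjamini-Hochberg correction across terms.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diff import ComparisonReport, FLAG_UNCHANGED
from .errors import ParseError, ValidationError
from .profiling import CohortProfile

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001


@dataclass
class PpiNetwork:
    """Simple undirected gene-symbol graph."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loops present: {loops[:3]}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PpiNetwork":
        graph = nx.Graph()
        removed_loops = 0
        for a, b in edges:
            a, b = str(a).upper(), str(b).upper()
            if a == b:
                removed_loops += 1
                continue
            graph.add_edge(a, b)
        if removed_loops:
            logger.info("removed %d self-interaction(s)", removed_loops)
        return cls(graph)


def load_network(path) -> PpiNetwork:
    """Read a 2-column TSV or SIF edge list into a cleaned simple graph.

    SIF lines carry an interaction type in the middle column and may list
    several partners; 2-column lines are plain source/target pairs.
    """
    edges: list[tuple[str, str]] = []
    try:
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) == 1:
                    fields = line.split()
                if len(fields) == 2:
                    edges.append((fields[0], fields[1]))
                elif len(fields) >= 3:
                    source = fields[0]
                    for target in fields[2:]:  # SIF: source type target...
                        edges.append((source, target))
                else:
                    raise ParseError(f"{path}:{lineno}: malformed edge line {line!r}")
    except OSError as exc:
        raise ParseError(f"cannot read network at {path}: {exc}") from exc
    return PpiNetwork.from_edges(edges)


def induced_subnetwork(
    net: PpiNetwork, query: Iterable[str], min_degree: int = 0
) -> PpiNetwork:
    """Subgraph induced by ``query`` genes; edges internal to the query only.

    ``min_degree=1`` drops mapped nodes left isolated inside the subgraph.
    """
    query_upper = {str(g).upper() for g in query}
    sub = nx.Graph(net.graph.subgraph(query_upper & net.nodes))
    if min_degree > 0:
        drop = [n for n, d in sub.degree if d < min_degree]
        sub.remove_nodes_from(drop)
    return PpiNetwork(sub)


def color_by_state(
    subnet: PpiNetwork,
    profiles: Mapping[str, CohortProfile],
    reports: Iterable[ComparisonReport] = (),
) -> pd.DataFrame:
    """Per-node attribute table: normalized aSpC per cohort + pairwise flags.

    aSpC values are normalized to each cohort's maximum so colors are
    comparable across conditions; nodes absent from every profile are
    marked missing. One column per comparison report carries that pair's
    flag for the node.
    """
    if not profiles:
        raise ValidationError("color_by_state needs >= 1 cohort profile")
    rows = []
    flag_maps = []
    reports = list(reports)
    for report in reports:
        flag_maps.append({r.protein: r.flag for r in report.records})
    for node in sorted(subnet.nodes):
        row: dict[str, object] = {"node": node}
        seen = False
        for cohort, profile in profiles.items():
            value = float(profile.aspc.get(node, 0.0))
            peak = float(profile.aspc.max()) if len(profile.aspc) else 0.0
            row[f"aspc_{cohort}"] = value / peak if peak > 0 else 0.0
            seen = seen or node in profile.aspc.index
        row["missing"] = not seen
        for report, flags in zip(reports, flag_maps):
            col = f"state_{report.pair[0]}_vs_{report.pair[1]}"
            row[col] = flags.get(node, FLAG_UNCHANGED if seen else "missing")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's hypergeometric enrichment outcome."""

    term: str
    k: int  # hits in query
    big_k: int  # term size in universe
    n: int  # query size
    big_n: int  # universe size
    p_value: float
    q_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.big_k, self.n)):
            raise ValidationError(f"{self.term}: inconsistent counts")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(f"{self.term}: q out of [0, 1]")


def hypergeom_enrich(
    query: Iterable[str],
    universe: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric enrichment of term membership in ``query``.

    ``terms`` maps gene -> term collection; genes of the universe without
    terms still count toward N. p = P(X >= k) for X ~ Hypergeom(N, K, n);
    q-values are Benjamini-Hochberg across all tested terms; records with
    q <= ``alpha`` are flagged significant.
    """
    query_set = set(query)
    universe_set = set(universe)
    stray = query_set - universe_set
    if stray:
        raise ValidationError(f"query genes outside universe: {sorted(stray)[:5]}")
    term_members: dict[str, set[str]] = {}
    for gene in universe_set:
        for term in terms.get(gene, ()):
            term_members.setdefault(term, set()).add(gene)
    if not term_members:
        return []
    big_n = len(universe_set)
    n = len(query_set)
    names = sorted(term_members)
    p_values = []
    counts = []
    for term in names:
        members = term_members[term]
        big_k = len(members)
        k = len(members & query_set)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        p_values.append(min(p, 1.0))
        counts.append((k, big_k))
    _, q_values, _, _ = multipletests(p_values, method="fdr_bh")
    records = []
    for term, (k, big_k), p, q in zip(names, counts, p_values, q_values):
        records.append(
            EnrichmentRecord(
                term=term,
                k=k,
                big_k=big_k,
                n=n,
                big_n=big_n,
                p_value=p,
                q_value=float(q),
                significant=bool(q <= alpha),
            )
        )
    return records


def enrichment_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term, r.k, r.big_k, r.n, r.big_n, r.p_value, r.q_value, r.significant)
         for r in records],
        columns=["term", "k", "K", "n", "N", "p_value", "q_value", "significant"],
    )


__all__ = [
    "DEFAULT_ALPHA",
    "EnrichmentRecord",
    "PpiNetwork",
    "color_by_state",
    "enrichment_frame",
    "hypergeom_enrich",
    "induced_subnetwork",
    "load_network",
]
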