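"""Signed-network ascription from pairwise co-clustering evidence.

For every unordered pair of roster members, the reports yield the counts
``x_obs`` (respondents who recognized both and put them in the same cluster)
and ``y_obs`` (recognized both, different clusters).  Only RECOGNIZED-bin
placements count: CLOSE and UNKNOWN members contribute to neither tally.

A pair becomes a positive perceived tie when ``x_obs`` reaches the null-model
cutoff ``delta_plus``, and a negative tie — a "robust intransitive", i.e.
statistically supported perceived *non*-relationship — when ``y_obs`` reaches
``delta_minus``.  Pairs meeting both cutoffs are recorded as contested and
resolved by a configurable policy (by default neither sign is ascribed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .study_io import Bin, ReportSet

__all__ = [
    "PairEvidence",
    "SignedNetwork",
    "tally_pair_evidence",
    "infer_signed_network",
    "infer_from_reports",
    "network_summary",
    "signed_degree_correlation",
]


@dataclass(frozen=True)
class PairEvidence:
    """Co-placement evidence for one unordered pair."""

    pair: tuple[str, str]
    n_corecognized: int
    x_obs: int
    y_obs: int

    def __post_init__(self):
        if self.x_obs + self.y_obs != self.n_corecognized:
            raise ValueError("x_obs + y_obs must equal n_corecognized")
        if min(self.x_obs, self.y_obs) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class SignedNetwork:
    """Undirected signed network with a contested-pair ledger.

    ``nodes`` is the member universe (everyone recognized by at least one
    respondent); ``edges`` maps unordered pairs to +1/-1; ``contested`` holds
    pairs that met both cutoffs; ``evidence`` keeps the full tally table.
    """

    nodes: frozenset[str]
    edges: Mapping[tuple[str, str], int]
    contested: frozenset[tuple[str, str]]
    evidence: Mapping[tuple[str, str], PairEvidence]

    def subgraph(self, sign: int) -> nx.Graph:
        """Simple undirected graph of one sign over the full node universe."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(pair for pair, s in self.edges.items() if s == sign)
        return g

    def edge_count(self, sign: int) -> int:
        return sum(1 for s in self.edges.values() if s == sign)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (u, v, sign, self.evidence[(u, v)].x_obs, self.evidence[(u, v)].y_obs)
            for (u, v), sign in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["u", "v", "sign", "x_obs", "y_obs"])


def tally_pair_evidence(reports: ReportSet) -> dict[tuple[str, str], PairEvidence]:
    """Count same-/different-cluster placements per unordered pair.

    Pairs never co-recognized are absent (implicitly zero evidence).
    """
    same: dict[tuple[str, str], int] = {}
    diff: dict[tuple[str, str], int] = {}
    for rep in reports.reports:
        members = sorted(rep.cluster)
        for i, u in enumerate(members):
            cu = rep.cluster[u]
            for v in members[i + 1 :]:
                pair = (u, v)
                if cu == rep.cluster[v]:
                    same[pair] = same.get(pair, 0) + 1
                else:
                    diff[pair] = diff.get(pair, 0) + 1
    out = {}
    for pair in same.keys() | diff.keys():
        x, y = same.get(pair, 0), diff.get(pair, 0)
        out[pair] = PairEvidence(pair=pair, n_corecognized=x + y, x_obs=x, y_obs=y)
    return out


def _recognized_universe(reports: ReportSet) -> frozenset[str]:
    nodes = set()
    for rep in reports.reports:
        for v, b in rep.bin.items():
            if b is Bin.RECOGNIZED:
                nodes.add(v)
    return frozenset(nodes)


def infer_signed_network(
    evidence: Mapping[tuple[str, str], PairEvidence],
    delta_plus: int,
    delta_minus: int,
    *,
    policy: str = "contested_null",
    nodes: Iterable[str] | None = None,
) -> SignedNetwork:
    """Ascribe signed ties by thresholding the evidence table.

    ``policy`` resolves pairs meeting both cutoffs: ``contested_null`` drops
    them (default), ``positive_wins``/``negative_wins`` keep one sign.  The
    node universe defaults to all members appearing in the evidence table;
    pass ``nodes`` to retain evidenced-but-isolated members.
    """
    if min(delta_plus, delta_minus) < 1:
        raise ValueError("thresholds must be >= 1")
    if policy not in ("contested_null", "positive_wins", "negative_wins"):
        raise ValueError(f"unknown policy {policy!r}")
    edges: dict[tuple[str, str], int] = {}
    contested: set[tuple[str, str]] = set()
    for pair, ev in evidence.items():
        pos = ev.x_obs >= delta_plus
        neg = ev.y_obs >= delta_minus
        if pos and neg:
            contested.add(pair)
            if policy == "positive_wins":
                edges[pair] = +1
            elif policy == "negative_wins":
                edges[pair] = -1
        elif pos:
            edges[pair] = +1
        elif neg:
            edges[pair] = -1
    if nodes is None:
        universe: set[str] = set()
        for u, v in evidence:
            universe.update((u, v))
    else:
        universe = set(nodes)
    return SignedNetwork(
        nodes=frozenset(universe),
        edges=edges,
        contested=frozenset(contested),
        evidence=dict(evidence),
    )


def infer_from_reports(
    reports: ReportSet,
    delta_plus: int,
    delta_minus: int,
    *,
    policy: str = "contested_null",
) -> SignedNetwork:
    """Tally evidence and ascribe ties; node universe = recognized members."""
    return infer_signed_network(
        tally_pair_evidence(reports),
        delta_plus,
        delta_minus,
        policy=policy,
        nodes=_recognized_universe(reports),
    )


def network_summary(network: SignedNetwork, sign: int) -> dict[str, float]:
    """Summary statistics of the single-sign sub-network.

    Isolated nodes are dropped, so "nodes" counts members incident to at
    least one edge of the requested sign.  On disconnected graphs the
    diameter is that of the largest component and the mean distance averages
    within components.  Betweenness is reported unnormalized.
    """
    g = network.subgraph(sign)
    g.remove_nodes_from([v for v in g if g.degree(v) == 0])
    if g.number_of_edges() == 0:
        return {"nodes": 0, "edges": 0}
    components = [g.subgraph(c).copy() for c in nx.connected_components(g)]
    largest = max(components, key=len)
    dist_sum, dist_pairs = 0.0, 0
    for comp in components:
        if len(comp) < 2:
            continue
        for _src, dists in nx.shortest_path_length(comp):
            dist_sum += sum(dists.values())
            dist_pairs += len(dists) - 1
    return {
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
        "mean_degree": 2 * g.number_of_edges() / g.number_of_nodes(),
        "diameter": nx.diameter(largest),
        "mean_distance": dist_sum / dist_pairs if dist_pairs else float("nan"),
        "transitivity": nx.transitivity(g),
        "mean_closeness": float(np.mean(list(nx.closeness_centrality(g).values()))),
        "mean_eigenvector_centrality": float(
            np.mean(list(nx.eigenvector_centrality(largest, max_iter=1000).values()))
        ),
        "mean_betweenness": float(
            np.mean(list(nx.betweenness_centrality(g, normalized=False).values()))
        ),
    }


def signed_degree_correlation(network: SignedNetwork) -> float:
    """Pearson correlation of per-node positive vs negative degree.

    Computed over the union node universe; a node without edges of a sign has
    degree 0 there.  Returns NaN when either degree sequence is constant.
    """
    nodes = sorted(network.nodes)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    pos = dict.fromkeys(nodes, 0)
    neg = dict.fromkeys(nodes, 0)
    for (u, v), sign in network.edges.items():
        target = pos if sign > 0 else neg
        target[u] += 1
        target[v] += 1
    a = np.array([pos[v] for v in nodes], dtype=float)
    b = np.array([neg[v] for v in nodes], dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
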