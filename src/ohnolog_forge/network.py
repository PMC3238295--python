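"""Signed, partially directed signalling networks and duplicate-pair
conservation statistics.

The network model follows curated human signalling maps: *scaffold* edges are
undirected physical links, while *positive* (activating) and *negative*
(inhibiting) edges are directed regulatory links.  Multiple typed edges may
join the same node pair.  The duplicate-pair statistics quantify how much of a
paralogous pair's connectivity is parsimoniously explained by a conserved
ancestral interaction: a *shared edge* is a pair of identically typed edges
from the two paralogs to the same third node, a *bridging edge* directly links
the two paralogs, and shared regulatory edges split into conserved incoming
(CIE: regulator -> both paralogs) and conserved outgoing (COE: both paralogs
-> target) edges.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import InputError

POSITIVE = "positive"
NEGATIVE = "negative"
SCAFFOLD = "scaffold"
POLARITIES = (POSITIVE, NEGATIVE, SCAFFOLD)
REGULATORY = (POSITIVE, NEGATIVE)


@dataclass(frozen=True, order=True)
class Edge:
    """One typed edge.  Scaffold edges are undirected and stored canonically
    (endpoints sorted); regulatory edges are directed source -> target."""

    source: str
    target: str
    polarity: str

    @property
    def directed(self) -> bool:
        return self.polarity != SCAFFOLD

    def canonical(self) -> "Edge":
        if self.polarity == SCAFFOLD and self.source > self.target:
            return Edge(self.target, self.source, self.polarity)
        return self

    def touches(self, node: str) -> bool:
        return node in (self.source, self.target)

    def other(self, node: str) -> str:
        return self.target if self.source == node else self.source


class SignalNetwork:
    """A set of typed edges plus any isolated nodes."""

    def __init__(self, edges: Iterable[Edge] = (), nodes: Iterable[str] = ()):
        self._edges: list[Edge] = []
        seen: set[Edge] = set()
        for edge in edges:
            if edge.polarity not in POLARITIES:
                raise InputError(f"unknown edge polarity: {edge.polarity!r}")
            edge = edge.canonical()
            if edge not in seen:
                seen.add(edge)
                self._edges.append(edge)
        self._incident: dict[str, list[Edge]] = {}
        for node in nodes:
            self._incident.setdefault(node, [])
        for edge in self._edges:
            self._incident.setdefault(edge.source, []).append(edge)
            if edge.target != edge.source:
                self._incident.setdefault(edge.target, []).append(edge)

    # -- container basics ----------------------------------------------------
    @property
    def edges(self) -> list[Edge]:
        return list(self._edges)

    @property
    def nodes(self) -> list[str]:
        return sorted(self._incident)

    def __contains__(self, node: str) -> bool:
        return node in self._incident

    def n_edges(self) -> int:
        return len(self._edges)

    def incident(self, node: str) -> list[Edge]:
        return list(self._incident.get(node, []))

    # -- views ---------------------------------------------------------------
    def subnetwork(self, polarity_filter: str = "all") -> "SignalNetwork":
        """Restrict to one polarity; nodes keep membership only if they remain
        incident to at least one retained edge."""
        if polarity_filter == "all":
            return SignalNetwork(self._edges, self._incident)
        if polarity_filter not in POLARITIES:
            raise InputError(f"unknown polarity filter: {polarity_filter!r}")
        kept = [e for e in self._edges if e.polarity == polarity_filter]
        return SignalNetwork(kept)

    def to_networkx(self, directed: bool = False) -> nx.Graph:
        """Simple-graph projection.  Undirected: every typed edge becomes one
        undirected edge (parallel types collapse).  Directed: regulatory edges
        keep direction, scaffold edges become mutual arcs."""
        g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(self._incident)
        for e in self._edges:
            g.add_edge(e.source, e.target)
            if directed and not e.directed:
                g.add_edge(e.target, e.source)
        return g

    # -- degrees ---------------------------------------------------------------
    def degree(self, node: str) -> int:
        return len(self._incident.get(node, []))

    def indegree(self, node: str) -> int:
        return sum(
            1 for e in self._incident.get(node, [])
            if (not e.directed) or e.target == node)

    def outdegree(self, node: str) -> int:
        return sum(
            1 for e in self._incident.get(node, [])
            if (not e.directed) or e.source == node)


def read_edge_tsv(path) -> SignalNetwork:
    """Read a (source, target, polarity[, directed-flag]) TSV edge list."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("source\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"malformed edge line: {line!r}")
            edges.append(Edge(parts[0], parts[1], parts[2]))
    return SignalNetwork(edges)


def write_edge_tsv(net: SignalNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tpolarity\tdirected\n")
        for e in net.edges:
            fh.write(f"{e.source}\t{e.target}\t{e.polarity}\t{int(e.directed)}\n")


# ---------------------------------------------------------------------------
# node metrics
# ---------------------------------------------------------------------------

@dataclass
class NodeMetrics:
    degree: dict[str, int]
    indegree: dict[str, int]
    outdegree: dict[str, int]
    relative_betweenness: dict[str, float]


def node_metrics(net: SignalNetwork, directed_betweenness: bool = False) -> NodeMetrics:
    """Degree / indegree / outdegree (typed-edge counts) plus Brandes
    betweenness centrality normalised to [0, 1] by the maximum pair count.

    Betweenness runs on the undirected projection by default; pass
    ``directed_betweenness=True`` for regulatory-only analyses.
    """
    g = net.to_networkx(directed=directed_betweenness)
    bc = nx.betweenness_centrality(g, normalized=True) if g.number_of_nodes() > 2 else {
        n: 0.0 for n in g.nodes}
    return NodeMetrics(
        degree={n: net.degree(n) for n in net.nodes},
        indegree={n: net.indegree(n) for n in net.nodes},
        outdegree={n: net.outdegree(n) for n in net.nodes},
        relative_betweenness={n: float(bc.get(n, 0.0)) for n in net.nodes},
    )


_STATISTICS = ("mean_degree", "mean_indegree", "mean_outdegree", "mean_betweenness")


def _set_statistic(metrics: NodeMetrics, nodes: Sequence[str], statistic: str) -> float:
    table = {
        "mean_degree": metrics.degree,
        "mean_indegree": metrics.indegree,
        "mean_outdegree": metrics.outdegree,
        "mean_betweenness": metrics.relative_betweenness,
    }[statistic]
    return float(np.mean([table[n] for n in nodes]))


def permutation_pvalue(
    net: SignalNetwork,
    node_set: Iterable[str],
    statistic: str = "mean_degree",
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    directed_betweenness: bool = False,
) -> dict:
    """Permutation significance of a node-set connectivity statistic.

    The null resamples node labels without replacement (random same-size node
    sets).  The sampled p-value uses the (k+1)/(n+1) estimator; with
    ``exhaustive=True`` every same-size subset is enumerated and
    p = #(null >= observed) / #subsets.
    """
    node_set = sorted(set(node_set))
    if not node_set:
        raise InputError("empty node set")
    if statistic not in _STATISTICS:
        raise InputError(f"unknown statistic {statistic!r}")
    missing = [n for n in node_set if n not in net]
    if missing:
        raise InputError(f"nodes absent from network: {missing[:5]}")
    metrics = node_metrics(net, directed_betweenness=directed_betweenness)
    observed = _set_statistic(metrics, node_set, statistic)
    all_nodes = net.nodes
    k = len(node_set)
    if exhaustive:
        null = [
            _set_statistic(metrics, subset, statistic)
            for subset in itertools.combinations(all_nodes, k)
        ]
        ge = sum(1 for v in null if v >= observed - 1e-12)
        p = ge / len(null)
    else:
        rng = np.random.default_rng(seed)
        null = []
        for _ in range(int(n_perm)):
            subset = rng.choice(len(all_nodes), size=k, replace=False)
            null.append(_set_statistic(metrics, [all_nodes[i] for i in subset], statistic))
        ge = sum(1 for v in null if v >= observed - 1e-12)
        p = (1 + ge) / (1 + len(null))
    return {
        "statistic": statistic,
        "observed": observed,
        "null_mean": float(np.mean(null)),
        "p_value": float(p),
        "n_null": len(null),
    }


# ---------------------------------------------------------------------------
# duplicate-pair conservation
# ---------------------------------------------------------------------------

def _edge_signature(edge: Edge, member: str) -> tuple[str, str, str]:
    """(third node, direction relative to the pair member, polarity)."""
    third = edge.other(member)
    if not edge.directed:
        direction = "und"
    else:
        direction = "out" if edge.source == member else "in"
    return (third, direction, edge.polarity)


def _pair_signatures(net: SignalNetwork, u: str, v: str):
    """Signature sets of the two members, excluding self-loops and the pair's
    own bridging edges (which are novelties, not inherited interactions)."""
    sigs = []
    for member, partner in ((u, v), (v, u)):
        s = set()
        for e in net.incident(member):
            if e.source == e.target:
                continue
            if e.touches(partner):  # bridging edge
                continue
            s.add(_edge_signature(e, member))
        sigs.append(s)
    return sigs[0], sigs[1]


@dataclass
class PairConservation:
    pair: tuple[str, str]
    shared_edge_count: int
    total_incident_edges: int
    conserved_fraction: Optional[float]
    degree_difference: int
    bridged: bool
    bridging_polarities: list[str] = field(default_factory=list)


def _conserve_one(net: SignalNetwork, u: str, v: str) -> PairConservation:
    su, sv = _pair_signatures(net, u, v)
    shared = 2 * len(su & sv)
    total = len(su) + len(sv)
    bridges = [e for e in net.incident(u) if e.touches(v) and e.source != e.target]
    return PairConservation(
        pair=(u, v),
        shared_edge_count=shared,
        total_incident_edges=total,
        conserved_fraction=(shared / total) if total else None,
        degree_difference=abs(net.degree(u) - net.degree(v)),
        bridged=bool(bridges),
        bridging_polarities=sorted(e.polarity for e in bridges),
    )


def pair_conservation(net: SignalNetwork, pairs: Iterable[tuple[str, str]]) -> dict:
    """Shared/conserved-edge accounting for paralogous node pairs.

    Both members of a matched edge pair count toward ``shared_edge_count``.
    Returns per-pair records plus a pooled summary: pooled ratio
    (sum shared / sum total) and the mean of per-pair conserved fractions —
    two different averages of the same data, both reported.
    """
    records: list[PairConservation] = []
    dropped = 0
    for u, v in pairs:
        if u == v:
            dropped += 1
            continue
        if u not in net or v not in net:
            dropped += 1
            continue
        records.append(_conserve_one(net, u, v))
    shared = sum(r.shared_edge_count for r in records)
    total = sum(r.total_incident_edges for r in records)
    fractions = [r.conserved_fraction for r in records if r.conserved_fraction is not None]
    summary = {
        "n_pairs": len(records),
        "n_dropped": dropped,
        "shared_edges": shared,
        "total_edges": total,
        "pooled_ratio": (shared / total) if total else None,
        "mean_conserved_fraction": float(np.mean(fractions)) if fractions else None,
        "mean_degree_difference": float(
            np.mean([r.degree_difference for r in records])) if records else None,
        "frac_pairs_any_shared": (
            sum(1 for r in records if r.shared_edge_count > 0) / len(records)
            if records else None),
    }
    return {"pairs": records, "summary": summary}


def pooled_shared_edge_pct(shared: int, total: int) -> float:
    """Pooled shared-edge percentage, 100 * shared / total."""
    if total <= 0:
        raise InputError("total edge count must be positive")
    return 100.0 * shared / total


def classify_cie_coe(net: SignalNetwork, pair: tuple[str, str]) -> dict:
    """Split a pair's shared *regulatory* edges into conserved incoming edges
    (third node -> both paralogs) and conserved outgoing edges (both paralogs
    -> third node), per polarity.  Scaffold matches are ignored here."""
    u, v = pair
    su, sv = _pair_signatures(net, u, v)
    counts = {("cie", p): 0 for p in REGULATORY}
    counts.update({("coe", p): 0 for p in REGULATORY})
    for third, direction, pol in su & sv:
        if pol not in REGULATORY:
            continue
        if direction == "in":
            counts[("cie", pol)] += 1
        elif direction == "out":
            counts[("coe", pol)] += 1
    return {
        "cie": {p: counts[("cie", p)] for p in REGULATORY},
        "coe": {p: counts[("coe", p)] for p in REGULATORY},
        "cie_count": sum(counts[("cie", p)] for p in REGULATORY),
        "coe_count": sum(counts[("coe", p)] for p in REGULATORY),
    }


def find_bridged_pairs(net: SignalNetwork, pairs: Iterable[tuple[str, str]]) -> dict:
    """Pairs joined by a direct (bridging) edge, with polarity breakdown and
    the mean incident-edge count of bridged vs non-bridged pairs."""
    bridged, unbridged = [], []
    for u, v in pairs:
        if u == v or u not in net or v not in net:
            continue
        rec = _conserve_one(net, u, v)
        n_inc = rec.total_incident_edges + 2 * len(rec.bridging_polarities)
        entry = {
            "pair": (u, v),
            "polarities": rec.bridging_polarities,
            "incident_edges": n_inc,
            "conserved_fraction": rec.conserved_fraction,
        }
        (bridged if rec.bridged else unbridged).append(entry)
    def _mean(entries):
        return float(np.mean([e["incident_edges"] for e in entries])) if entries else None
    polarity_totals = {p: 0 for p in POLARITIES}
    for e in bridged:
        for p in e["polarities"]:
            polarity_totals[p] += 1
    return {
        "bridged": bridged,
        "n_bridged": len(bridged),
        "n_unbridged": len(unbridged),
        "bridging_polarity_counts": polarity_totals,
        "mean_edges_bridged": _mean(bridged),
        "mean_edges_unbridged": _mean(unbridged),
    }


def random_pair_null(
    net: SignalNetwork,
    n_samples: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> dict:
    """Null model for shared-edge statistics over uniform random node pairs.

    Returns the expected per-pair shared-edge fraction (pairs with no incident
    edges contribute 0) and the fraction of pairs with at least one shared
    edge.  ``exhaustive=True`` enumerates every unordered pair instead.
    """
    nodes = net.nodes
    if len(nodes) < 2:
        raise InputError("need at least two nodes")
    if exhaustive:
        sampled = list(itertools.combinations(nodes, 2))
    else:
        if n_samples < 1:
            raise InputError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        sampled = []
        for _ in range(int(n_samples)):
            i, j = rng.choice(len(nodes), size=2, replace=False)
            sampled.append((nodes[i], nodes[j]))
    fracs, any_shared = [], 0
    for u, v in sampled:
        rec = _conserve_one(net, u, v)
        fracs.append(rec.conserved_fraction if rec.conserved_fraction is not None else 0.0)
        if rec.shared_edge_count > 0:
            any_shared += 1
    return {
        "expected_shared_fraction": float(np.mean(fracs)),
        "frac_pairs_any_shared": any_shared / len(sampled),
        "n_sampled": len(sampled),
    }
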