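"""Tissue-specific first-order PPI networks and hub/bottleneck topology.

DEG seeds are expanded over a scored interactome into a first-order network
(seeds, their direct neighbors, and all induced edges).  Nodes are then
classified from the degree and betweenness distributions:

* hub-bottleneck: degree >= mean + 2*SD of the network degree distribution
  (population SD by default);
* nonhub-bottleneck: degree below that cutoff, positive betweenness ranking
  in the top 50% of the betweenness distribution, and at least two
  hub-bottleneck neighbors;
* other: everything else.

Betweenness is unweighted and unnormalized; edge scores are used only for
the percentile pre-filter of the interactome, never as path weights.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .differential import VennPartition, venn_partition

log = logging.getLogger(__name__)

HUB = "hub_bottleneck"
NONHUB = "nonhub_bottleneck"
OTHER = "other"

# Absolute slack on the degree-cutoff comparison: the cutoff is a float
# derived from mean/SD and must not miss an integer degree by rounding.
_CUTOFF_TOL = 1e-9


@dataclass
class Interactome:
    """Scored undirected edge table (columns node_a, node_b, score)."""

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"node_a", "node_b", "score"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing columns: {sorted(missing)}")
        if len(self.edges) == 0:
            raise ValueError("empty interactome")
        scores = self.edges["score"].to_numpy(dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValueError("edge scores must be finite")
        loops = self.edges["node_a"] == self.edges["node_b"]
        if loops.any():
            raise ValueError(f"self-loops at rows {list(self.edges.index[loops])[:5]}")
        keys = [frozenset(p) for p in zip(self.edges["node_a"], self.edges["node_b"])]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate unordered edge pairs")

    @property
    def nodes(self) -> list:
        seen = dict.fromkeys(self.edges["node_a"])
        seen.update(dict.fromkeys(self.edges["node_b"]))
        return list(seen)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b, s in self.edges[["node_a", "node_b", "score"]].itertuples(index=False):
            g.add_edge(a, b, score=float(s))
        return g


@dataclass
class Network:
    """A first-order subnetwork: seeds, neighbors, induced edges."""

    graph: nx.Graph
    seeds: frozenset
    log2_fc: dict = field(default_factory=dict)
    missing_seeds: tuple = ()


def filter_interactome(
    interactome: Interactome, top_fraction: float = 0.15, mode: str = "count"
) -> Interactome:
    """Keep the highest-|score| fraction of edges.

    ``mode="count"`` (default) retains exactly ceil(top_fraction * m)
    edges, ranked by |score| descending with ties broken by stable input
    order.  ``mode="value"`` instead thresholds at the nearest-rank
    (1 - top_fraction) percentile of |score|, keeping every edge at or
    above it.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if mode not in ("count", "value"):
        raise ValueError("mode must be 'count' or 'value'")
    edges = interactome.edges
    magnitude = edges["score"].abs().to_numpy(dtype=float)
    if mode == "count":
        n_keep = math.ceil(top_fraction * len(edges))
        order = np.argsort(-magnitude, kind="stable")
        keep = np.sort(order[:n_keep])
    else:
        ordered = np.sort(magnitude)
        rank = math.ceil((1 - top_fraction) * len(edges))
        threshold = ordered[max(rank - 1, 0)] if top_fraction < 1 else -np.inf
        keep = np.flatnonzero(magnitude >= threshold)
    return Interactome(edges.iloc[keep].reset_index(drop=True))


def _seed_table(seeds) -> dict:
    """Normalize seed input to gene -> log2FC, averaging duplicates."""
    if isinstance(seeds, pd.DataFrame):
        pairs = list(zip(seeds.iloc[:, 0], seeds.iloc[:, 1].astype(float)))
    elif isinstance(seeds, Mapping):
        pairs = [(g, float(v)) for g, v in seeds.items()]
    else:
        pairs = []
        for item in seeds:
            if isinstance(item, tuple):
                pairs.append((item[0], float(item[1])))
            else:
                pairs.append((item, float("nan")))
    acc: dict = {}
    for gene, fc in pairs:
        acc.setdefault(gene, []).append(fc)
    return {g: float(np.mean(v)) for g, v in acc.items()}


def build_first_order_network(seeds, interactome: Interactome) -> Network:
    """Expand seed genes into their first-order PPI network.

    ``seeds`` may be a mapping gene -> log2FC, a two-column DataFrame, or
    an iterable of genes / (gene, log2FC) pairs; duplicate entries are
    collapsed by the mean log2FC.  The node set is the seeds present in
    the interactome plus their direct neighbors; the edge set is every
    interactome edge with both endpoints in that node set.  Seeds absent
    from the interactome are reported on the returned network.
    """
    table = _seed_table(seeds)
    if not table:
        raise ValueError("empty seed list")
    g = interactome.graph()
    present = [s for s in table if s in g]
    absent = tuple(s for s in table if s not in g)
    if not present:
        raise ValueError(
            f"no seed maps into the interactome (missing: {list(absent)[:10]})"
        )
    if absent:
        log.warning("%d seeds absent from the interactome: %s",
                    len(absent), list(absent)[:10])
    nodes = set(present)
    for s in present:
        nodes.update(g.neighbors(s))
    sub = nx.Graph()
    sub.add_nodes_from(n for n in g.nodes if n in nodes)
    sub.add_edges_from(
        (a, b, d) for a, b, d in g.edges(data=True) if a in nodes and b in nodes
    )
    return Network(sub, frozenset(present), dict(table), absent)


def node_betweenness(network) -> dict:
    """Unnormalized betweenness centrality on unweighted shortest paths.

    Each unordered pair (s, t) contributes sigma_st(v)/sigma_st to every
    interior node v of its geodesics; disconnected pairs contribute 0.
    """
    g = network.graph if isinstance(network, Network) else network
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return nx.betweenness_centrality(g, normalized=False)


def classify_topology(network, sd_sample: bool = False) -> pd.DataFrame:
    """Classify nodes as hub-bottleneck / nonhub-bottleneck / other.

    The degree cutoff is mean + 2*SD of the network's degree distribution
    (population SD unless ``sd_sample``), frozen per network.  A node is a
    hub-bottleneck when degree >= cutoff; a nonhub-bottleneck when its
    degree is below the cutoff, its betweenness is positive and within the
    top 50% of the betweenness distribution in descending order (rank
    <= ceil(N/2); ties share the better rank), and it touches at least two
    hub-bottlenecks.

    Returns a DataFrame indexed by node with degree, betweenness,
    node_class, degree_cutoff and, when available, seed flag and log2FC.
    """
    net = network if isinstance(network, Network) else Network(network, frozenset())
    g = net.graph
    nodes = list(g.nodes)
    if not nodes:
        raise ValueError("empty network")
    degrees = np.array([g.degree(v) for v in nodes], dtype=float)
    if len(nodes) == 1:
        log.warning("single-node network: degenerate topology, all 'other'")
        cutoff = float(degrees[0])
        classes = [OTHER]
        btw = {nodes[0]: 0.0}
    else:
        ddof = 1 if sd_sample else 0
        cutoff = float(degrees.mean() + 2.0 * degrees.std(ddof=ddof))
        btw = node_betweenness(g)
        b = np.array([btw[v] for v in nodes])
        hub_mask = degrees + _CUTOFF_TOL >= cutoff
        hubs = {v for v, is_hub in zip(nodes, hub_mask) if is_hub}
        # descending competition rank: 1 + number of strictly larger values
        rank = 1 + (b[None, :] > b[:, None]).sum(axis=1)
        top_half = rank <= math.ceil(len(nodes) / 2)
        classes = []
        for v, k_hub, b_v, in_top in zip(nodes, hub_mask, b, top_half):
            if k_hub:
                classes.append(HUB)
            elif b_v > 0 and in_top and sum(u in hubs for u in g.neighbors(v)) >= 2:
                classes.append(NONHUB)
            else:
                classes.append(OTHER)
    out = pd.DataFrame(
        {
            "degree": degrees.astype(int),
            "betweenness": [btw[v] for v in nodes],
            "node_class": classes,
            "degree_cutoff": cutoff,
        },
        index=pd.Index(nodes, name="node_id"),
    )
    if net.seeds:
        out["is_seed"] = [v in net.seeds for v in nodes]
    if net.log2_fc:
        out["log2_fc"] = [net.log2_fc.get(v, np.nan) for v in nodes]
    return out


@dataclass
class ClusterComparison:
    """Cross-condition comparison of topology classes."""

    table: pd.DataFrame
    venns: dict[str, VennPartition]


def compare_clusters(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    labels: tuple[str, str] = ("a", "b"),
) -> ClusterComparison:
    """Compare hub/nonhub classifications between two conditions.

    For each topology class, reports shared and condition-specific nodes
    with their per-condition log2FC and an ``opposite_trend`` flag for
    shared nodes whose expression changes in opposite directions.
    """
    la, lb = labels
    if la == lb:
        raise ValueError("labels must differ")
    rows = []
    venns = {}
    for klass in (HUB, NONHUB):
        set_a = set(records_a.index[records_a["node_class"] == klass])
        set_b = set(records_b.index[records_b["node_class"] == klass])
        if set_a or set_b:
            venns[klass] = venn_partition({la: set_a, lb: set_b})
        for node in sorted(set_a | set_b, key=str):
            in_a, in_b = node in set_a, node in set_b
            fc_a = _node_fc(records_a, node)
            fc_b = _node_fc(records_b, node)
            opposite = (
                bool(np.sign(fc_a) * np.sign(fc_b) < 0)
                if in_a and in_b and np.isfinite(fc_a) and np.isfinite(fc_b)
                else pd.NA
            )
            rows.append({
                "node_class": klass,
                "node_id": node,
                "status": "shared" if in_a and in_b else (f"{la}_only" if in_a else f"{lb}_only"),
                f"log2_fc_{la}": fc_a,
                f"log2_fc_{lb}": fc_b,
                "opposite_trend": opposite,
            })
    columns = ["node_class", "node_id", "status",
               f"log2_fc_{la}", f"log2_fc_{lb}", "opposite_trend"]
    return ClusterComparison(pd.DataFrame(rows, columns=columns), venns)


def _node_fc(records: pd.DataFrame, node) -> float:
    if "log2_fc" in records.columns and node in records.index:
        return float(records.loc[node, "log2_fc"])
    return float("nan")
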