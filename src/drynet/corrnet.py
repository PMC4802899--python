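"""Condition-specific metabolite correlation networks and topology summaries.

An undirected edge joins two metabolites when, within one condition's
samples, |Pearson r| exceeds ``r_min`` AND the two-sided permutation p-value
is below ``alpha`` (study gate: |PCC| > 0.8, P < 0.001 with B = 2000
permutations). Topology statistics follow the Cytoscape NetworkAnalyzer
conventions: averages are taken over connected (degree >= 1) nodes, and a
node of degree < 2 contributes a local clustering coefficient of 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .stats import permutation_pvalue

__all__ = [
    "CorrelationEdge", "Network", "TopologySummary", "NetworkComparison",
    "build_condition_network", "topology_summary", "compare_conditions",
    "write_edges_tsv", "write_edges_sif", "read_edges_tsv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationEdge:
    """A significant metabolite-metabolite correlation (unordered pair)."""

    feature_a: str
    feature_b: str
    r: float
    p: float

    def __post_init__(self) -> None:
        if self.feature_a == self.feature_b:
            raise ValueError("self-edge")
        if self.feature_a > self.feature_b:
            a, b = self.feature_a, self.feature_b
            object.__setattr__(self, "feature_a", b)
            object.__setattr__(self, "feature_b", a)

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"

    @property
    def pair(self) -> tuple[str, str]:
        return (self.feature_a, self.feature_b)


@dataclass
class Network:
    """All candidate features (isolated nodes allowed) plus significant edges."""

    condition: str
    nodes: tuple[str, ...]
    edges: tuple[CorrelationEdge, ...]
    thresholds: dict = field(default_factory=dict)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.feature_a, e.feature_b, r=e.r, p=e.p, sign=e.sign)
        return g


@dataclass(frozen=True)
class TopologySummary:
    n_connected_nodes: int
    n_edges: int
    avg_degree: float
    clustering_coefficient: float
    density: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NetworkComparison:
    summary_c: TopologySummary
    summary_d: TopologySummary
    differences: dict[str, float]
    shared_edges: set[tuple[str, str]]
    unique_to_c: set[tuple[str, str]]
    unique_to_d: set[tuple[str, str]]


def build_condition_network(matrix: OmicsMatrix, condition: str,
                            r_min: float = 0.8, alpha: float = 0.001,
                            B: int = 2000, seed: int = 0,
                            log_transform: bool = False) -> Network:
    """Significant-correlation network over one condition's samples.

    Permutation p-values are only evaluated for pairs that already pass the
    |r| > r_min gate (an edge needs both, and p alone can never admit a pair
    the r gate rejects), with a per-pair RNG stream keyed by the feature ids.
    Zero-variance features are kept as isolated nodes and logged.
    """
    if condition not in set(matrix.metadata["treatment"]):
        raise ValueError(f"condition {condition!r} absent from metadata")
    if not (0 <= r_min <= 1):
        raise ValueError("r_min must be in [0, 1]")
    samples = matrix.samples_for(treatment=condition)
    if len(samples) < 3:
        raise ValueError("need >= 3 samples in the condition")
    sub = matrix.values.loc[:, samples].to_numpy(dtype=float)
    if log_transform:
        sub = np.log(sub)
    features = matrix.feature_ids
    ok = np.ptp(sub, axis=1) > 0
    for f, good in zip(features, ok):
        if not good:
            log.warning("feature %s has zero variance in condition %s; kept isolated",
                        f, condition)
    edges: list[CorrelationEdge] = []
    idx = [i for i, good in enumerate(ok) if good]
    # full correlation matrix once; permutation only for gated pairs
    if len(idx) >= 2:
        corr = np.corrcoef(sub[idx])
        for a_pos in range(len(idx)):
            for b_pos in range(a_pos + 1, len(idx)):
                r = float(np.clip(corr[a_pos, b_pos], -1.0, 1.0))
                if abs(r) <= r_min:
                    continue
                fa, fb = features[idx[a_pos]], features[idx[b_pos]]
                p = permutation_pvalue(sub[idx[a_pos]], sub[idx[b_pos]],
                                       B=B, seed=seed, key_a=fa, key_b=fb)
                if p < alpha:
                    edges.append(CorrelationEdge(fa, fb, r=r, p=p))
    edges.sort(key=lambda e: e.pair)
    return Network(condition=condition, nodes=tuple(features), edges=tuple(edges),
                   thresholds={"r_min": r_min, "alpha": alpha, "B": B, "seed": seed,
                               "log_transform": log_transform})


def topology_summary(network: Network | nx.Graph) -> TopologySummary:
    """Average degree, clustering coefficient, and density over connected nodes."""
    g = network.graph() if isinstance(network, Network) else network
    connected = [n for n, d in g.degree() if d >= 1]
    n_edges = g.number_of_edges()
    if not connected:
        return TopologySummary(0, n_edges, 0.0, 0.0, 0.0)
    degrees = [g.degree(n) for n in connected]
    avg_degree = float(np.mean(degrees))
    clustering = float(np.mean(list(nx.clustering(g, nodes=connected).values())))
    nc = len(connected)
    density = 2.0 * n_edges / (nc * (nc - 1)) if nc >= 2 else 0.0
    return TopologySummary(n_connected_nodes=nc, n_edges=n_edges,
                           avg_degree=avg_degree,
                           clustering_coefficient=clustering,
                           density=float(density))


def compare_conditions(net_c: Network, net_d: Network) -> NetworkComparison:
    """Topology contrast and edge-set Venn between the C and D networks."""
    if set(net_c.nodes) != set(net_d.nodes):
        raise ValueError("networks must share the same node universe")
    sc, sd = topology_summary(net_c), topology_summary(net_d)
    pc, pd_ = net_c.edge_pairs(), net_d.edge_pairs()
    diffs = {k: getattr(sd, k) - getattr(sc, k)
             for k in ("n_connected_nodes", "n_edges", "avg_degree",
                       "clustering_coefficient", "density")}
    return NetworkComparison(
        summary_c=sc, summary_d=sd, differences=diffs,
        shared_edges=pc & pd_, unique_to_c=pc - pd_, unique_to_d=pd_ - pc)


# --------------------------------------------------------------------------- I/O


def write_edges_tsv(network: Network, path: str | Path) -> None:
    rows = [{"feature_a": e.feature_a, "feature_b": e.feature_b,
             "r": e.r, "p": e.p, "sign": e.sign} for e in network.edges]
    pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p", "sign"]) \
        .to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_edges_tsv(path: str | Path, condition: str = "",
                   nodes: tuple[str, ...] | None = None) -> Network:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    edges = tuple(CorrelationEdge(str(r.feature_a), str(r.feature_b),
                                  r=float(r.r), p=float(r.p))
                  for r in df.itertuples(index=False))
    if nodes is None:
        nodes = tuple(sorted({e.feature_a for e in edges} | {e.feature_b for e in edges}))
    return Network(condition=condition, nodes=nodes, edges=edges)


def write_edges_sif(network: Network, path: str | Path) -> None:
    """Cytoscape SIF: `a<TAB>pcc_pos|pcc_neg<TAB>b`."""
    with open(path, "w") as fh:
        for e in network.edges:
            rel = "pcc_pos" if e.sign == "positive" else "pcc_neg"
            fh.write(f"{e.feature_a}\t{rel}\t{e.feature_b}\n")
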