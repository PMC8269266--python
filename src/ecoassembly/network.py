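"""Co-occurrence network construction, topology, and keystone scoring.

Edges connect OTU pairs whose MIC passes a strength cutoff (default 0.5)
and whose BH-adjusted p passes a significance cutoff (default 0.001); the
edge sign is carried by the pair's Spearman rho since MIC is nonnegative.
Topology: degree, Brandes betweenness, classic closeness per connected
component, diameter and average path length on the largest component, and
Louvain modules (seeded, ids ranked by descending size). Keystoneness of a
node is the mean of min-max-scaled degree, (1 - scaled betweenness), and
scaled closeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "prevalence_filter",
    "build_network",
    "network_topology",
    "keystoneness",
    "CooccurrenceNetwork",
]


def prevalence_filter(counts: pd.DataFrame, min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep OTUs detected (count >= 1) in at least ``min_fraction`` of samples."""
    if not (0 < min_fraction <= 1):
        raise InvalidArgumentError("min_fraction must lie in (0, 1]")
    frac = (counts > 0).mean(axis=1)
    out = counts.loc[frac >= min_fraction]
    if out.shape[0] < 3:
        raise InvalidArgumentError(
            f"prevalence filter at {min_fraction:.0%} leaves only {out.shape[0]} OTU(s)"
        )
    return out


@dataclass
class CooccurrenceNetwork:
    """Thresholded network plus its topology tables."""

    graph: nx.Graph
    edges: pd.DataFrame  # otu_a, otu_b, mic, rho, q, sign
    nodes: pd.DataFrame = field(default=None)  # degree, betweenness, closeness, module, keystoneness
    metrics: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.graph.number_of_edges() == 0

    def summary(self) -> str:
        g = self.metrics
        if self.empty:
            return "Co-occurrence network: no edges survived the cutoffs"
        lines = ["Co-occurrence network", "=" * 30]
        for key in (
            "n_nodes", "n_edges", "average_degree", "diameter",
            "average_path_length", "modularity", "n_modules",
            "positive_edge_fraction",
        ):
            if key in g:
                val = g[key]
                lines.append(
                    f"{key:<24s} {val:.4f}" if isinstance(val, float) else f"{key:<24s} {val}"
                )
        return "\n".join(lines)


def build_network(
    mic_result: pd.DataFrame,
    mic_cutoff: float = 0.5,
    q_cutoff: float = 0.001,
) -> CooccurrenceNetwork:
    """Threshold a MIC table into a signed co-occurrence network.

    Keeps pairs with ``mic >= mic_cutoff`` and adjusted ``q < q_cutoff``;
    isolated OTUs are not added as nodes. An empty result is returned with a
    warning, not raised.
    """
    need = {"otu_a", "otu_b", "mic", "rho", "q"}
    if not need.issubset(mic_result.columns):
        raise InvalidArgumentError(f"MIC table must have columns {sorted(need)}")
    keep = mic_result[(mic_result["mic"] >= mic_cutoff) & (mic_result["q"] < q_cutoff)]
    edges = keep.copy()
    zero_rho = edges["rho"] == 0
    if zero_rho.any():
        warnings.warn(
            f"{int(zero_rho.sum())} edge(s) with zero Spearman rho assigned "
            "positive sign",
            stacklevel=2,
        )
    edges["sign"] = np.where(edges["rho"] < 0, "-", "+")
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.otu_a, row.otu_b, mic=row.mic, rho=row.rho, q=row.q, sign=row.sign)
    if g.number_of_edges() == 0:
        warnings.warn("no edges survived the MIC/q cutoffs; network is empty", stacklevel=2)
    return CooccurrenceNetwork(graph=g, edges=edges.reset_index(drop=True))


def network_topology(network: CooccurrenceNetwork, seed: int | None = None) -> CooccurrenceNetwork:
    """Fill in per-node centralities, Louvain modules, and global metrics.

    Betweenness is unnormalized Brandes; closeness is the classic form
    within each connected component; diameter/APL are taken on the largest
    component; module ids are ranked by descending module size.
    """
    g = network.graph
    if g.number_of_edges() < 1:
        raise InvalidArgumentError("network has no edges")
    degree = dict(g.degree())
    bc = nx.betweenness_centrality(g, normalized=False)
    cc = nx.closeness_centrality(g, wf_improved=False)

    comms = nx.community.louvain_communities(g, resolution=1.0, seed=seed)
    comms = sorted(comms, key=lambda s: (-len(s), min(s)))
    module = {node: i + 1 for i, com in enumerate(comms) for node in com}
    modularity = nx.community.modularity(g, comms)

    largest = max(nx.connected_components(g), key=len)
    sub = g.subgraph(largest)
    diameter = nx.diameter(sub) if sub.number_of_nodes() > 1 else 0
    apl = nx.average_shortest_path_length(sub) if sub.number_of_nodes() > 1 else 0.0

    nodes = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "betweenness": pd.Series(bc),
            "closeness": pd.Series(cc),
            "module": pd.Series(module, dtype=int),
        }
    ).rename_axis("otu_id").sort_index()

    signs = network.edges["sign"] if len(network.edges) else pd.Series(dtype=str)
    network.nodes = nodes
    network.metrics = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "average_degree": 2.0 * g.number_of_edges() / g.number_of_nodes(),
        "diameter": int(diameter),
        "average_path_length": float(apl),
        "modularity": float(modularity),
        "n_modules": len(comms),
        "positive_edge_fraction": float((signs == "+").mean()) if len(signs) else 0.0,
    }
    return network


def _minmax(v: np.ndarray) -> np.ndarray:
    rng = v.max() - v.min()
    if rng == 0:
        return np.zeros_like(v, dtype=float)
    return (v - v.min()) / rng


def keystoneness(network: CooccurrenceNetwork, top_k: int = 10) -> pd.DataFrame:
    """Keystoneness = mean(scaled degree, 1 - scaled BC, scaled CC).

    Min-max scaling is across nodes (a constant centrality scales to 0).
    Returns the node table sorted by descending score (ties broken by OTU
    id) with a boolean ``keystone`` flag on the top ``top_k``.
    """
    if network.nodes is None:
        network_topology(network)
    nodes = network.nodes
    if len(nodes) < 2:
        raise InvalidArgumentError("keystoneness needs at least 2 nodes")
    sdeg = _minmax(nodes["degree"].to_numpy(dtype=float))
    sbc = _minmax(nodes["betweenness"].to_numpy(dtype=float))
    scc = _minmax(nodes["closeness"].to_numpy(dtype=float))
    score = (sdeg + (1.0 - sbc) + scc) / 3.0
    out = (
        nodes.assign(keystoneness=score)
        .reset_index()
        .sort_values(["keystoneness", "otu_id"], ascending=[False, True])
        .set_index("otu_id")
    )
    out["keystone"] = False
    out.iloc[: min(top_k, len(out)), out.columns.get_loc("keystone")] = True
    network.nodes = out
    return out
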