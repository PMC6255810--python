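"""Directed signaling network and random-walk-with-return proximity.

The walk update is ``p_{t+1} = (1 - r) * W p_t + r * e_seed`` with ``W`` the
column-stochastic out-edge transition operator; mass sitting on dangling
(out-degree-0) nodes is returned to the seed so total probability is
conserved.  Distances are ``-log10`` of visiting probability, so closer
means smaller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse
from scipy.stats import mannwhitneyu

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class WalkParameters:
    """Return probability and iteration count of the walk."""

    return_probability: float = 0.5
    iterations: int = 15

    def __post_init__(self):
        if not (0 < self.return_probability <= 1):
            raise ConfigurationError("return probability must be in (0, 1]")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be a positive integer")


class SignalingNetwork:
    """Directed graph over gene symbols with a walk-transition contract.

    Out-edges of a node receive equal walk probability.  Edge signs
    (stimulation/inhibition relations) are carried but ignored by the walk.
    """

    def __init__(self, edges, nodes=None):
        g = nx.DiGraph()
        if nodes:
            g.add_nodes_from(nodes)
        for edge in edges:
            if len(edge) == 2:
                src, tgt = edge
                rel = None
            else:
                src, tgt, rel = edge
            g.add_edge(src, tgt, relation=rel)
        self.graph = g
        self.nodes: tuple[str, ...] = tuple(sorted(g.nodes))
        self._index = {node: i for i, node in enumerate(self.nodes)}
        log.info("signaling network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def index_of(self, node: str) -> int:
        return self._index[node]

    def transition_matrix(self) -> tuple[sparse.csr_matrix, np.ndarray]:
        """Column-stochastic operator W and the dangling-node mask.

        ``W[j, i] = 1/outdeg(i)`` for each edge i->j; columns of dangling
        nodes are zero (their mass is handled by the walk's dangling rule).
        """
        n = self.n_nodes
        rows, cols, vals = [], [], []
        outdeg = np.zeros(n)
        for src, tgt in self.graph.edges:
            outdeg[self._index[src]] += 1
        for src, tgt in self.graph.edges:
            i = self._index[src]
            rows.append(self._index[tgt])
            cols.append(i)
            vals.append(1.0 / outdeg[i])
        W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        return W, outdeg == 0


def build_signaling_network(edge_list) -> SignalingNetwork:
    """Build a deduplicated directed network from (src, tgt[, relation]) rows."""
    if not edge_list:
        log.warning("building an empty signaling network")
    return SignalingNetwork(edge_list)


def rwr_visiting_probabilities(
    net: SignalingNetwork, seed: str, params: WalkParameters = WalkParameters()
) -> pd.Series:
    """T-iteration random walk with return from ``seed``.

    Dangling mass is sent back to the seed before the return step, so the
    output is a probability distribution over nodes.
    """
    if seed not in net:
        raise KeyError(f"seed {seed!r} not in network")
    r = params.return_probability
    W, dangling = net.transition_matrix()
    n = net.n_nodes
    e = np.zeros(n)
    e[net.index_of(seed)] = 1.0
    p = e.copy()
    for _ in range(params.iterations):
        pushed = W @ p
        pushed[net.index_of(seed)] += p[dangling].sum()
        p = (1 - r) * pushed + r * e
    return pd.Series(p, index=net.nodes, name=seed)


@dataclass
class ProximityMatrix:
    """Seed x TF visiting probabilities and the derived -log10 distances."""

    probabilities: pd.DataFrame  # rows: seeds, columns: TFs
    params: WalkParameters

    @property
    def distances(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return -np.log10(self.probabilities)


def proximity_matrix(
    net: SignalingNetwork,
    seeds: list[str],
    tfs: list[str],
    params: WalkParameters = WalkParameters(),
) -> ProximityMatrix:
    """Visiting probabilities from each seed restricted to the TF columns.

    Seeds or TFs absent from the network are dropped with a logged count.
    """
    kept_seeds = [s for s in seeds if s in net]
    kept_tfs = [t for t in tfs if t in net]
    if len(kept_seeds) < len(seeds):
        log.info("dropped %d seed(s) absent from the network", len(seeds) - len(kept_seeds))
    if len(kept_tfs) < len(tfs):
        log.info("dropped %d TF(s) absent from the network", len(tfs) - len(kept_tfs))
    rows = {
        seed: rwr_visiting_probabilities(net, seed, params)[kept_tfs]
        for seed in sorted(set(kept_seeds))
    }
    probs = pd.DataFrame(rows).T
    probs.index.name = "seed"
    probs = probs.reindex(columns=sorted(set(kept_tfs)))
    return ProximityMatrix(probabilities=probs, params=params)


def gene_tfs(gene: str, regulons: pd.DataFrame) -> list[str]:
    """TFs whose regulon contains ``gene``."""
    return sorted(set(regulons.loc[regulons["target"] == gene, "tf"]))


def gene_distance(
    protein: str,
    gene: str,
    regulons: pd.DataFrame,
    prox: ProximityMatrix,
    aggregation: str = "min",
) -> float:
    """Distance from a protein to a gene via the TFs regulating it.

    Default aggregation is the minimum over the gene's TFs present in the
    proximity matrix (one strong route suffices); "mean" is available.
    """
    tfs = [t for t in gene_tfs(gene, regulons) if t in prox.distances.columns]
    if not tfs:
        raise ValueError(f"gene {gene!r} has no TFs in the proximity matrix")
    row = prox.distances.loc[protein, tfs]
    if aggregation == "min":
        return float(row.min())
    if aggregation == "mean":
        return float(row.mean())
    raise ConfigurationError(f"unknown aggregation {aggregation!r}")


def rank_proteins_by_gene_proximity(
    gene: str,
    prox: ProximityMatrix,
    regulons: pd.DataFrame,
    k: int = 30,
    fold_changes: pd.Series | None = None,
    aggregation: str = "min",
) -> pd.DataFrame:
    """Rank proximity-matrix seeds by distance to a gene's TFs, ascending.

    Ties break lexicographically.  ``fold_changes`` (protein -> ratio-scale
    fold change of the most affected site, 1 = no change) is attached when
    supplied.
    """
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    distances = {
        protein: gene_distance(protein, gene, regulons, prox, aggregation)
        for protein in prox.distances.index
    }
    out = (
        pd.Series(distances, name="distance")
        .rename_axis("protein")
        .reset_index()
        .sort_values(["distance", "protein"], ignore_index=True)
        .head(k)
    )
    if fold_changes is not None:
        out["fold_change"] = out["protein"].map(fold_changes)
    return out


def altered_proteins(
    fcs: pd.DataFrame, fold_threshold: float = 1.5, direction: str = "both"
) -> set[str]:
    """Proteins with any phosphosite fold change beyond ``fold_threshold``.

    ``direction="up"`` counts only increases (ratio > threshold);
    ``"both"`` counts a change in either direction (ratio or its inverse
    above the threshold).
    """
    lfc = fcs["log2fc"]
    cut = np.log2(fold_threshold)
    if direction == "up":
        mask = lfc > cut
    elif direction == "both":
        mask = lfc.abs() > cut
    else:
        raise ConfigurationError(f"unknown direction {direction!r}")
    return set(fcs.loc[mask, "protein"])


def compare_altered_vs_unaltered_distances(
    prox: ProximityMatrix,
    fcs: pd.DataFrame,
    gene_set_tfs: list[str],
    fold_threshold: float = 1.5,
    alternative: str = "less",
    direction: str = "both",
) -> tuple[float, float]:
    """Mann-Whitney test: are phospho-altered proteins closer to the TFs?

    Each protein's value is its minimum distance to ``gene_set_tfs``; groups
    are proteins with any site fold change beyond ``fold_threshold`` versus
    the rest.  One-sided "altered < unaltered" by default.  Uses the exact
    null for small tie-free samples and the tie-corrected normal
    approximation otherwise.
    """
    tfs = [t for t in gene_set_tfs if t in prox.distances.columns]
    if not tfs:
        raise ValueError("none of the requested TFs are in the proximity matrix")
    per_protein = prox.distances[tfs].min(axis=1)
    altered = sorted(altered_proteins(fcs, fold_threshold, direction) & set(per_protein.index))
    unaltered = sorted(set(per_protein.index) - set(altered))
    if not altered:
        raise ValueError("altered group is empty")
    if not unaltered:
        raise ValueError("unaltered group is empty")
    x = per_protein.loc[altered].to_numpy()
    y = per_protein.loc[unaltered].to_numpy()
    if np.unique(np.concatenate([x, y])).size == 1:
        # fully tied data: U sits at its null mean and carries no evidence
        return float(len(x) * len(y) / 2), 0.5
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
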