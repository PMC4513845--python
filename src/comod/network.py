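"""Network connectivity scoring.

For each association network the score of gene i for cluster j is the
negated sum of edge weights between i and the cluster's member genes,
normalized by roster size (a per-gene cluster connection density):

    T_ij = - sum_{g in roster(j), g != i} w(i, g) / |roster(j)|

Genes with no edges into a cluster score 0; more negative is better.
Multiple networks combine as a weighted arithmetic mean using each
network's relative weight.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import AssociationNetwork
from .membership import MembershipState
from .scores import ScoreMatrix


def normalize_edge_weights(net: AssociationNetwork,
                           mode: str = "max1") -> AssociationNetwork:
    """Rescale edge weights: ``max1`` divides by the max weight, ``none`` is identity."""
    if mode == "none":
        return net
    if mode != "max1":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if not net.edges:
        return net
    top = max(net.edges.values())
    if top <= 0:
        warnings.warn(f"network {net.name!r} has all-zero weights; left inert")
        return net
    out = AssociationNetwork(net.name, network_weight=net.network_weight)
    out.edges = {k: w / top for k, w in net.edges.items()}
    return out


def single_network_scores(net: AssociationNetwork, gene_ids: list[str],
                          G: np.ndarray,
                          W: np.ndarray | None = None) -> np.ndarray:
    """T for one network; ``W`` may carry a precomputed adjacency matrix."""
    if W is None:
        W = net.adjacency(gene_ids)
    sizes = G.sum(axis=0).astype(float)
    into = W @ G.astype(float)               # includes self term, but w(i,i)=0
    with np.errstate(invalid="ignore", divide="ignore"):
        T = -into / np.maximum(sizes, 1.0)
    T[:, sizes == 0] = 0.0
    return T


def network_scores(networks: list[AssociationNetwork],
                   state: MembershipState,
                   adjacencies: list[np.ndarray] | None = None) -> ScoreMatrix:
    """Weighted-mean connection-density score over all networks."""
    if not networks:
        raise ValueError("need at least one network")
    G = state.gene_membership
    total_w = sum(net.network_weight for net in networks)
    if total_w <= 0:
        raise ValueError("network weights sum to zero")
    acc = np.zeros((len(state.gene_ids), state.k))
    for idx, net in enumerate(networks):
        W = adjacencies[idx] if adjacencies is not None else None
        acc += net.network_weight * single_network_scores(net, state.gene_ids, G, W)
    return ScoreMatrix(state.gene_ids, acc / total_w, kind="T")
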