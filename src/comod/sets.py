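"""Gene-set enrichment scoring.

At each iteration every cluster is tested against every user-supplied gene
set with a one-sided Fisher's exact test (enrichment only) over the
configured universe.  For each cluster the most significant set is chosen
for training, its p-value is clamped from below at the Bonferroni cutoff
alpha / n_sets (a low-pass filter against unstable, tiny p-values), and
gene scores are

    E_ij = log10(p*) * m_i,   m_i = 1.0  gene in cluster and in the set
                              m_i = 0.5  gene in the set but not the cluster
                              m_i = 0.0  otherwise

so E <= 0 everywhere and only genes of the chosen set are rewarded.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from .io import GeneSetCollection
from .membership import MembershipState
from .scores import ScoreMatrix


def cluster_set_pvalues(sets: GeneSetCollection,
                        roster: set[str] | list[str]) -> dict[str, float]:
    """One-sided Fisher exact (hypergeometric tail) p per set.

    The 2x2 table is (in cluster) x (in set) over the collection's universe;
    the reported p is P(overlap >= observed).  An empty roster gives p = 1
    for every set.
    """
    universe = set(sets.universe)
    roster = set(roster) & universe
    N = len(universe)
    n = len(roster)
    out: dict[str, float] = {}
    for sid, members in sets.sets.items():
        K = len(members)
        if n == 0 or K == 0:
            out[sid] = 1.0
            continue
        a = len(roster & members)
        out[sid] = float(hypergeom.sf(a - 1, N, K, n))
    return out


def set_membership_matrix(sets: GeneSetCollection,
                          gene_ids: list[str]) -> np.ndarray:
    """n_sets x n_genes boolean membership, set order = sets.set_ids."""
    index = {g: i for i, g in enumerate(gene_ids)}
    S = np.zeros((len(sets.sets), len(gene_ids)), dtype=bool)
    for r, sid in enumerate(sets.set_ids):
        for g in sets.sets[sid]:
            i = index.get(g)
            if i is not None:
                S[r, i] = True
    return S


def set_enrichment_row_scores(sets: GeneSetCollection,
                              state: MembershipState,
                              alpha: float = 0.05,
                              set_matrix: np.ndarray | None = None) -> ScoreMatrix:
    """E: gene x cluster scores from the best-enriched set per cluster.

    ``set_matrix`` may carry a precomputed output of
    :func:`set_membership_matrix` to avoid rebuilding it every iteration.
    """
    if not sets.sets:
        raise ValueError("need at least one gene set")
    S = set_membership_matrix(sets, state.gene_ids) if set_matrix is None \
        else set_matrix
    G = state.gene_membership                      # genes x k
    n_sets = len(sets.sets)
    floor = alpha / n_sets
    N = len(sets.universe)
    K = S.sum(axis=1)                              # set sizes
    n = G.sum(axis=0)                              # roster sizes
    overlap = S.astype(np.int64) @ G.astype(np.int64)   # n_sets x k
    with np.errstate(divide="ignore"):
        pv = hypergeom.sf(overlap - 1, N, K[:, None], n[None, :])
    pv[K == 0, :] = 1.0
    pv[:, n == 0] = 1.0
    E = np.zeros((len(state.gene_ids), state.k))
    best = pv.argmin(axis=0)
    for j in range(state.k):
        p_best = pv[best[j], j]
        if p_best >= 1.0:
            continue  # nothing enriched: column stays 0
        base = np.log10(max(p_best, floor))
        members = S[best[j]]
        in_cluster = G[:, j]
        E[members & in_cluster, j] = base
        E[members & ~in_cluster, j] = base * 0.5
    return ScoreMatrix(state.gene_ids, E, kind="E")
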