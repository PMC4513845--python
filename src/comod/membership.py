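"""Overlapping gene/condition memberships and the k-means-like move rule.

The optimization state is a pair of boolean membership matrices: genes x k
and conditions x k.  Each gene belongs to exactly ``v`` clusters (default 2);
each cluster is seeded with a random half of all conditions.  Once per
iteration a random subset of elements is offered a single swap: an element
moves into the non-member cluster with the highest membership probability,
and out of its worst current cluster, but only when the candidate is a
strict improvement.  Membership multiplicity is therefore conserved.
"""

from __future__ import annotations

import numpy as np


def default_k(n_genes: int, v: int = 2) -> int:
    """Default cluster count: about 20 genes per cluster, i.e. n_genes*v/20."""
    if n_genes < 20:
        raise ValueError("need at least 20 genes for the default k rule")
    return max(2, round(n_genes * v / 20))


class MembershipState:
    """Boolean membership matrices plus derived rosters."""

    def __init__(self, gene_ids: list[str], condition_ids: list[str],
                 gene_membership: np.ndarray, cond_membership: np.ndarray):
        self.gene_ids = list(gene_ids)
        self.condition_ids = list(condition_ids)
        self.gene_membership = np.asarray(gene_membership, dtype=bool)
        self.cond_membership = np.asarray(cond_membership, dtype=bool)
        self.iteration = 0
        if self.gene_membership.shape[0] != len(gene_ids):
            raise ValueError("gene membership shape mismatch")
        if self.cond_membership.shape[0] != len(condition_ids):
            raise ValueError("condition membership shape mismatch")
        if self.gene_membership.shape[1] != self.cond_membership.shape[1]:
            raise ValueError("gene and condition matrices disagree on k")

    @property
    def k(self) -> int:
        return self.gene_membership.shape[1]

    def gene_roster(self, j: int) -> list[str]:
        return [self.gene_ids[i] for i in np.flatnonzero(self.gene_membership[:, j])]

    def condition_roster(self, j: int) -> list[str]:
        return [self.condition_ids[i] for i in np.flatnonzero(self.cond_membership[:, j])]

    def cluster_sizes(self) -> np.ndarray:
        return self.gene_membership.sum(axis=0)

    def memberships_of(self, element: str, kind: str = "gene") -> list[int]:
        if kind == "gene":
            i = self.gene_ids.index(element)
            return list(np.flatnonzero(self.gene_membership[i]))
        i = self.condition_ids.index(element)
        return list(np.flatnonzero(self.cond_membership[i]))

    def copy(self) -> "MembershipState":
        out = MembershipState(self.gene_ids, self.condition_ids,
                              self.gene_membership.copy(),
                              self.cond_membership.copy())
        out.iteration = self.iteration
        return out


def seed_memberships(gene_ids: list[str], condition_ids: list[str],
                     k: int, v: int, rng: np.random.Generator) -> MembershipState:
    """Random balanced seeding.

    Gene slots (n_genes * v of them) are dealt out as evenly as possible over
    the k clusters, with the v clusters of any one gene kept distinct.  Each
    cluster's condition set starts as a uniform random half of all conditions.
    """
    n_genes, n_conds = len(gene_ids), len(condition_ids)
    if k > n_genes * v:
        raise ValueError("k exceeds the number of available gene slots")
    if v > k:
        raise ValueError("v cannot exceed k")

    total = n_genes * v
    reps = -(-total // k)  # ceil
    slots = np.tile(np.arange(k), reps)[:total]
    rng.shuffle(slots)
    G = np.zeros((n_genes, k), dtype=bool)
    order = rng.permutation(n_genes)
    pos = 0
    for gi in order:
        chosen: list[int] = []
        scan = pos
        while len(chosen) < v:
            if scan >= total:
                # ran out of distinct slots at the tail: top up with the
                # least-filled clusters not already chosen
                counts = G.sum(axis=0)
                counts[chosen] = n_genes + 1
                chosen.append(int(np.argmin(counts)))
                continue
            j = int(slots[scan])
            if j not in chosen:
                chosen.append(j)
                slots[scan], slots[pos] = slots[pos], slots[scan]
                pos += 1
            else:
                scan += 1
        G[gi, chosen] = True

    C = np.zeros((n_conds, k), dtype=bool)
    half = max(2, n_conds // 2)
    for j in range(k):
        C[rng.choice(n_conds, size=half, replace=False), j] = True

    state = MembershipState(gene_ids, condition_ids, G, C)
    return state


def apply_moves(state: MembershipState, probs: np.ndarray, kind: str,
                rng: np.random.Generator, fraction: float = 0.5,
                min_size: int = 3, max_size: int | None = 70,
                sampled: np.ndarray | None = None) -> int:
    """Offer each sampled element one membership swap; returns moves made.

    An element moves into the best non-member cluster j when p_ij strictly
    exceeds the worst of its current memberships p_ij'; it leaves that worst
    cluster.  Ties never move.  Moves that would push a roster outside
    [min_size, max_size] are skipped.  ``probs`` may contain NaN for
    (element, cluster) pairs that were not evaluated this iteration; those
    clusters are ignored as candidates and never abandoned.
    """
    M = state.gene_membership if kind == "gene" else state.cond_membership
    n, k = M.shape
    if probs.shape != (n, k):
        raise ValueError("probability matrix shape mismatch")
    if sampled is None:
        n_pick = max(1, int(round(fraction * n)))
        sampled = rng.choice(n, size=n_pick, replace=False)
    sizes = M.sum(axis=0)
    cap = max_size if max_size is not None else n
    moves = 0
    for i in sampled:
        p = probs[i]
        member = M[i]
        valid = np.isfinite(p)
        cand = valid & ~member
        own = valid & member
        if not cand.any() or not own.any():
            continue
        best_j = int(np.flatnonzero(cand)[np.argmax(p[cand])])
        worst_j = int(np.flatnonzero(own)[np.argmin(p[own])])
        if not p[best_j] > p[worst_j]:
            continue
        if sizes[best_j] + 1 > cap or sizes[worst_j] - 1 < min_size:
            continue
        sizes[best_j] += 1
        sizes[worst_j] -= 1
        M[i, worst_j] = False
        M[i, best_j] = True
        moves += 1
    return moves
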