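"""Intrinsic and extrinsic quality measures for a clustering.

Intrinsic: mean squared residue (Cheng–Church coherence; 0 for additive
submatrices) and the fraction of clusters whose best motif significance is
at most 1.  Extrinsic: recovery of reference regulons and combinatorial
regulons (genes sharing an identical combination of regulating TFs) as
precision/recall/G/F1, where a (cluster, regulon) match needs an overlap of
more than two genes at a hypergeometric p-value passing Benjamini-Hochberg
FDR <= 0.01; and counts of significantly set-enriched clusters and
recovered sets at BH p <= 0.01.  The PC1-variance filter used for human
tumor data checks each cluster's first-principal-component variance
fraction against size-matched random gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection


# ---------------------------------------------------------------------------
# mean squared residue

def mean_squared_residue(expr: ExpressionMatrix, gene_roster,
                         condition_roster) -> float | None:
    """Cheng-Church MSR of the bicluster submatrix; None when degenerate.

    Missing cells carry zero weight in the row, column and overall means and
    are excluded from the residue average.
    """
    gi = [expr.gene_ids.index(g) for g in gene_roster if g in expr.gene_ids]
    ci = [expr.condition_ids.index(c) for c in condition_roster
          if c in expr.condition_ids]
    if len(gi) < 2 or len(ci) < 2:
        return None
    A = expr.values[np.ix_(gi, ci)]
    W = np.isfinite(A)
    if W.sum() < 4 or (~W.any(axis=1)).any() or (~W.any(axis=0)).any():
        return None
    Az = np.where(W, A, 0.0)
    row_mean = Az.sum(axis=1) / W.sum(axis=1)
    col_mean = Az.sum(axis=0) / W.sum(axis=0)
    overall = Az.sum() / W.sum()
    resid = A - row_mean[:, None] - col_mean[None, :] + overall
    return float(np.where(W, resid, 0.0).__pow__(2).sum() / W.sum())


# ---------------------------------------------------------------------------
# regulon recovery

@dataclass
class RecoveryReport:
    precision: float
    recall: float
    g_measure: float
    f1: float
    n_matched_clusters: int
    n_matched_regulons: int


def build_combinatorial_regulons(table: dict[str, set[str]]) -> dict[str, set[str]]:
    """Group genes by their exact combination of regulating TFs.

    Genes regulated by no TF are excluded; singleton combinations are kept.
    The returned keys are '+'-joined sorted TF names.
    """
    signature: dict[str, tuple[str, ...]] = {}
    gene_tfs: dict[str, set[str]] = {}
    for tf, genes in table.items():
        for g in genes:
            gene_tfs.setdefault(g, set()).add(tf)
    out: dict[str, set[str]] = {}
    for gene, tfs in gene_tfs.items():
        key = "+".join(sorted(tfs))
        out.setdefault(key, set()).add(gene)
    return out


def overlap_pvalues(clusters: list[set[str]], references: list[set[str]],
                    universe: set[str]) -> np.ndarray:
    """Upper-tail hypergeometric p for every (cluster, reference) pair."""
    N = len(universe)
    P = np.ones((len(clusters), len(references)))
    for i, cl in enumerate(clusters):
        cl = cl & universe
        for j, ref in enumerate(references):
            ref_u = ref & universe
            a = len(cl & ref_u)
            if a == 0 or not cl or not ref_u:
                continue
            P[i, j] = hypergeom.sf(a - 1, N, len(ref_u), len(cl))
    return P


def regulon_recovery(clusters: list[set[str]], regulons: dict[str, set[str]],
                     universe: set[str] | None = None,
                     fdr: float = 0.01, min_overlap: int = 3) -> RecoveryReport:
    """Precision/recall/G/F1 of cluster-vs-regulon recovery.

    A match needs overlap of more than two genes and a hypergeometric
    p-value surviving BH FDR control at ``fdr`` over all (cluster, regulon)
    pairs.  The universe defaults to genes appearing in either side.
    """
    ref_sets = list(regulons.values())
    if universe is None:
        universe = set().union(*clusters) if clusters else set()
        for r in ref_sets:
            universe |= r
    P = overlap_pvalues(clusters, ref_sets, universe)
    flat = P.ravel()
    if flat.size:
        reject, _, _, _ = multipletests(flat, alpha=fdr, method="fdr_bh")
        sig = reject.reshape(P.shape)
    else:
        sig = np.zeros(P.shape, dtype=bool)
    for i, cl in enumerate(clusters):
        for j, ref in enumerate(ref_sets):
            if sig[i, j] and len((cl & universe) & (ref & universe)) < min_overlap:
                sig[i, j] = False
    matched_clusters = int(sig.any(axis=1).sum())
    matched_regulons = int(sig.any(axis=0).sum())
    precision = matched_clusters / len(clusters) if clusters else 0.0
    recall = matched_regulons / len(ref_sets) if ref_sets else 0.0
    g = float(np.sqrt(precision * recall))
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return RecoveryReport(precision, recall, g, f1,
                          matched_clusters, matched_regulons)


def gpr_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float, float]:
    """Precision, recall, G and F1 from raw TP/FP/FN counts."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    g = float(np.sqrt(precision * recall))
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, g, f1


# ---------------------------------------------------------------------------
# set recovery counts

def set_recovery_counts(clusters: list[set[str]], sets: GeneSetCollection,
                        alpha: float = 0.01) -> tuple[int, int, int, int]:
    """(clusters enriched, sets recovered, unique clusters, unique sets).

    Enrichment is a BH-corrected hypergeometric p <= alpha over all
    (cluster, set) pairs; the 'unique' variants count clusters (sets) with
    exactly one significant match.
    """
    ref_sets = [sets.sets[sid] for sid in sets.set_ids]
    universe = set(sets.universe)
    P = overlap_pvalues(clusters, ref_sets, universe)
    flat = P.ravel()
    if not flat.size:
        return (0, 0, 0, 0)
    reject, _, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    sig = reject.reshape(P.shape)
    per_cluster = sig.sum(axis=1)
    per_set = sig.sum(axis=0)
    return (int((per_cluster > 0).sum()), int((per_set > 0).sum()),
            int((per_cluster == 1).sum()), int((per_set == 1).sum()))


# ---------------------------------------------------------------------------
# PC1 variance filter

def pc1_variance_fraction(X: np.ndarray) -> float:
    """Variance explained by the first principal component (conditions as
    variables, columns centered)."""
    Xc = X - np.nanmean(X, axis=0, keepdims=True)
    Xc = np.where(np.isfinite(Xc), Xc, 0.0)
    s = np.linalg.svd(Xc, compute_uv=False)
    total = (s ** 2).sum()
    return float(s[0] ** 2 / total) if total > 0 else 0.0


def pc1_variance_filter(expr: ExpressionMatrix, roster,
                        rng: np.random.Generator, n_random: int = 1000,
                        alpha: float = 0.05,
                        null_table: dict[int, np.ndarray] | None = None) -> bool:
    """True when the cluster's PC1 variance fraction beats random gene sets.

    The null is the PC1 fraction of ``n_random`` random gene sets of
    (nearest) matched size; the cluster fails if more than ``alpha`` of the
    random sets exceed it.  ``null_table`` may carry precomputed null
    distributions keyed by size (e.g. sizes 5..65 step 5).
    """
    gi = [expr.gene_ids.index(g) for g in roster if g in expr.gene_ids]
    if len(gi) < 3:
        return False
    obs = pc1_variance_fraction(expr.values[gi])
    size = len(gi)
    if null_table:
        nearest = min(null_table, key=lambda s: abs(s - size))
        null = null_table[nearest]
    else:
        null = np.empty(n_random)
        for b in range(n_random):
            pick = rng.choice(expr.n_genes, size=size, replace=False)
            null[b] = pc1_variance_fraction(expr.values[pick])
    return float((null > obs).mean()) <= alpha


def make_pc1_null_table(expr: ExpressionMatrix, rng: np.random.Generator,
                        sizes=range(5, 70, 5), n_random: int = 1000
                        ) -> dict[int, np.ndarray]:
    """Precompute PC1 null distributions on a grid of gene-set sizes."""
    table: dict[int, np.ndarray] = {}
    for size in sizes:
        if size > expr.n_genes:
            continue
        null = np.empty(n_random)
        for b in range(n_random):
            pick = rng.choice(expr.n_genes, size=size, replace=False)
            null[b] = pc1_variance_fraction(expr.values[pick])
        table[size] = null
    return table
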