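"""Score combination, kernel membership probabilities and noise annealing.

Active score matrices are standardized (median 0, median-absolute-deviation
1 over finite entries; heavy-tailed motif log p-values make mean/sd
unreliable), combined as a weighted mean into M, perturbed with annealed
Gaussian noise, and converted per cluster column into membership
probabilities with a Gaussian-kernel empirical CDF:

    p_ij = 1 - KCDF_j(M_ij),   KCDF_j(x) = mean_g Phi((x - M_gj) / h_j)

with bandwidth h_j = h0_j * (1 + c / |roster(j)|), h0_j Silverman's rule on
the column.  The size term widens the kernel for small clusters, which
flattens their probability profile and so favours adding genes to them
rather than removing the few they have.  Lower score means higher p; all p
lie strictly inside (0, 1).

For long columns the reference sample of the kernel CDF is compressed to
equal-count bins (bin means of the sorted column); columns at or below
``max_refs`` elements use the exact full sum.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr


def standardize(X: np.ndarray) -> np.ndarray:
    """Center at the median and scale by the MAD over finite entries.

    A zero MAD (e.g. a mostly-zero set-enrichment matrix) falls back to the
    standard deviation; if that is also zero the matrix is only centered.
    """
    finite = X[np.isfinite(X)]
    if finite.size == 0:
        return X.copy()
    med = np.median(finite)
    mad = np.median(np.abs(finite - med))
    if mad <= 0:
        sd = finite.std()
        scale = sd if sd > 0 else 1.0
    else:
        scale = mad
    return (X - med) / scale


def combine_scores(matrices: list[np.ndarray], weights: list[float]) -> np.ndarray:
    """Weighted mean of standardized score matrices."""
    if len(matrices) != len(weights):
        raise ValueError("need one weight per matrix")
    if not matrices:
        raise ValueError("no matrices to combine")
    shape = matrices[0].shape
    for mat in matrices:
        if mat.shape != shape:
            raise ValueError("score matrices must share shape")
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be >= 0 and not all zero")
    acc = np.zeros(shape)
    for mat, w in zip(matrices, weights):
        if w > 0:
            acc += w * standardize(mat)
    return acc / weights.sum()


def silverman_bandwidth(col: np.ndarray) -> float:
    n = len(col)
    if n < 2:
        return 1.0
    sd = col.std()
    q75, q25 = np.percentile(col, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 1e-9
    return 0.9 * spread * n ** (-0.2)


def _reference(col: np.ndarray, max_refs: int) -> np.ndarray:
    """Kernel-CDF reference sample: exact for short columns, binned above."""
    n = len(col)
    if n <= max_refs:
        return col
    srt = np.sort(col)
    edges = np.linspace(0, n, max_refs + 1).astype(int)
    csum = np.concatenate(([0.0], np.cumsum(srt)))
    counts = np.diff(edges)
    return (csum[edges[1:]] - csum[edges[:-1]]) / counts


def kernel_membership_probs(M: np.ndarray, cluster_sizes: np.ndarray,
                            bandwidth_c: float = 20.0,
                            max_refs: int = 0,
                            rows: np.ndarray | None = None) -> np.ndarray:
    """p_ij = 1 - Gaussian-kernel CDF of column j evaluated at M_ij.

    ``rows`` restricts evaluation to a subset of elements (the reference
    distribution always uses the full column); unevaluated rows are NaN.
    ``max_refs`` = 0 disables reference binning.
    """
    n, k = M.shape
    if len(cluster_sizes) != k:
        raise ValueError("need one roster size per cluster")
    out = np.full((n, k), np.nan)
    eval_rows = np.arange(n) if rows is None else rows

    # Silverman bandwidths for every column at once
    sd = M.std(axis=0)
    q75, q25 = np.percentile(M, [75, 25], axis=0)
    iqr = q75 - q25
    spread = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
    h0 = np.where(spread > 0, 0.9 * spread * n ** (-0.2), 1e-9)
    h = h0 * (1.0 + bandwidth_c / np.maximum(cluster_sizes, 1))
    h = np.maximum(h, 1e-9)

    if max_refs and n > max_refs:
        srt = np.sort(M, axis=0)
        edges = np.linspace(0, n, max_refs + 1).astype(int)
        csum = np.concatenate([np.zeros((1, k)), np.cumsum(srt, axis=0)], axis=0)
        counts = np.diff(edges).astype(float)
        ref = (csum[edges[1:]] - csum[edges[:-1]]) / counts[:, None]  # B x k
    else:
        ref = M
    d = (M[eval_rows][:, None, :] - ref[None, :, :]) / h[None, None, :]
    p = 1.0 - ndtr(d).mean(axis=1)
    out[eval_rows] = np.clip(p, 1e-12, 1 - 1e-12)
    return out


def noise_sd(iteration: int, total: int, sd0: float = 0.25) -> float:
    """Linear decay from sd0 at iteration 1 to exactly 0 at the final iteration."""
    if not 1 <= iteration <= total:
        raise ValueError("iteration out of range")
    if total == 1:
        return 0.0
    return sd0 * (total - iteration) / (total - 1)


def anneal_noise(M: np.ndarray, iteration: int, total: int,
                 rng: np.random.Generator, sd0: float = 0.25) -> np.ndarray:
    """Add elementwise Gaussian noise whose sd anneals to zero."""
    sd = noise_sd(iteration, total, sd0)
    if sd == 0.0:
        return M.copy()
    return M + rng.normal(0.0, sd, size=M.shape)
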