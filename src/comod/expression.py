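"""Co-expression scoring.

The gene score of gene i for cluster j is the log mean squared deviation of
the gene's profile from the cluster's mean profile, taken over the cluster's
member conditions:

    R_ij = log( mean_{c in cond(j)} (x_ic - mu_jc)^2 + eps )

where mu_jc is the mean of the cluster's member genes at condition c and
eps stabilizes the log at zero deviation.  Missing values are ignored (not
imputed) in every mean.  Lower is better; the score is invariant to adding
a constant to the whole matrix.

The condition score of condition c for cluster j is the log ratio of the
member genes' variance at c to those genes' pooled variance over all
conditions; tight conditions score low.
"""

from __future__ import annotations

import numpy as np

from .io import ExpressionMatrix
from .membership import MembershipState
from .scores import ScoreMatrix

EPS = 1e-10


def _cluster_means(X: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Mean expression of each cluster's member genes, k x n_conditions.

    Missing cells carry zero weight.
    """
    finite = np.isfinite(X)
    Xz = np.where(finite, X, 0.0)
    num = G.T.astype(float) @ Xz                  # k x c
    den = G.T.astype(float) @ finite.astype(float)
    with np.errstate(invalid="ignore"):
        mu = num / den
    return mu  # NaN where no member gene has a value


def row_expression_scores(expr: ExpressionMatrix,
                          state: MembershipState) -> ScoreMatrix:
    """R: gene x cluster log mean squared deviation from the cluster mean."""
    X = expr.values
    G = state.gene_membership
    C = state.cond_membership
    mu = _cluster_means(X, G)                     # k x c
    finite = np.isfinite(X)
    k = state.k
    R = np.full((X.shape[0], k), np.nan)
    for j in range(k):
        cond = C[:, j]
        if cond.sum() < 2 or G[:, j].sum() < 2:
            continue  # unscorable column
        mu_j = mu[j, cond]
        ok = np.isfinite(mu_j)
        if not ok.any():
            continue
        sub = X[:, cond][:, ok]
        dev = (sub - mu_j[ok]) ** 2
        w = np.isfinite(sub)
        cnt = w.sum(axis=1)
        msd = np.where(cnt > 0,
                       np.where(w, dev, 0.0).sum(axis=1) / np.maximum(cnt, 1),
                       np.nan)
        R[:, j] = np.log(msd + EPS)
    return ScoreMatrix(expr.gene_ids, R, kind="R")


def condition_scores(expr: ExpressionMatrix,
                     state: MembershipState) -> ScoreMatrix:
    """Condition x cluster log variance-ratio score."""
    X = expr.values
    G = state.gene_membership
    k = state.k
    out = np.full((X.shape[1], k), np.nan)
    for j in range(k):
        members = G[:, j]
        if members.sum() < 2:
            continue
        sub = X[members]                          # m x c
        pooled = np.nanvar(sub)
        if not np.isfinite(pooled) or pooled <= 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            var_c = np.nanvar(sub, axis=0)
            counts = np.isfinite(sub).sum(axis=0)
            var_c = np.where(counts >= 2, var_c, np.nan)
            out[:, j] = np.log((var_c + EPS) / (pooled + EPS))
    return ScoreMatrix(expr.condition_ids, out, kind="R")
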