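"""Time-course expression filtering and fuzzy soft clustering.

Genes expressed below an FPKM floor in every stage are dropped; surviving
stage profiles are z-scored per gene and clustered with fuzzy c-means
(Bezdek updates, fuzzifier m), giving each gene a membership vector over
clusters. Genes with a maximum membership above 0.5 are the confident
members used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ExpressionTable


@dataclass
class SoftClustering:
    memberships: pd.DataFrame  # genes x clusters, rows sum to 1
    centroids: np.ndarray  # clusters x stages (z-score units)
    stages: list
    fuzzifier: float
    n_iter: int

    @property
    def assigned(self) -> pd.Series:
        return self.memberships.idxmax(axis=1)

    @property
    def max_membership(self) -> pd.Series:
        return self.memberships.max(axis=1)


def filter_expressed(expr: ExpressionTable, min_fpkm: float = 0.5) -> ExpressionTable:
    """Drop genes whose stage-mean FPKM stays below ``min_fpkm`` in every
    stage (unexpressed throughout the time course)."""
    sm = expr.stage_means()
    keep = (sm >= min_fpkm).any(axis=1)
    if not keep.any():
        warnings.warn("no gene passes the expression floor")
    return ExpressionTable(expr.fpkm.loc[keep], expr.samples)


def standardize_profiles(expr: ExpressionTable, pseudocount: float = 0.1) -> pd.DataFrame:
    """Per-gene z-score of log2 stage-mean FPKM across stages."""
    sm = np.log2(expr.stage_means() + pseudocount)
    mu = sm.mean(axis=1)
    sd = sm.std(axis=1, ddof=0).replace(0, 1.0)
    return sm.sub(mu, axis=0).div(sd, axis=0)


def soft_cluster(
    expr: ExpressionTable,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> SoftClustering:
    """Fuzzy c-means on standardized stage profiles.

    Minimizes sum_g sum_k u_gk^m ||x_g - v_k||^2 with the standard
    alternating membership/centroid updates; converged when the largest
    centroid shift falls below ``tol``.
    """
    x = standardize_profiles(expr)
    n, _ = x.shape
    if c >= n:
        raise ValueError(f"need more genes ({n}) than clusters ({c})")
    if m <= 1:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    data = x.to_numpy(float)
    v = data[rng.choice(n, size=c, replace=False)].copy()
    u = np.full((n, c), 1.0 / c)
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((data[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u**m
        v_new = (um.T @ data) / um.sum(axis=0)[:, None]
        shift = np.abs(v_new - v).max()
        v = v_new
        if shift < tol:
            break
    memberships = pd.DataFrame(
        u, index=x.index, columns=[f"cluster{k}" for k in range(c)]
    )
    return SoftClustering(memberships, v, list(x.columns), m, it)


def confident_members(
    clustering: SoftClustering, min_membership: float = 0.5
) -> dict[str, list[str]]:
    """Per-cluster gene lists for genes with max membership strictly above
    the floor; genes at or below it stay unassigned."""
    out: dict[str, list[str]] = {k: [] for k in clustering.memberships.columns}
    mm = clustering.max_membership
    assigned = clustering.assigned
    for gene, val in mm.items():
        if val > min_membership:
            out[assigned[gene]].append(gene)
    return out


def choose_cluster_count(
    expr: ExpressionTable,
    candidates: range = range(2, 13),
    m: float = 2.0,
    seed: int = 0,
) -> int:
    """Minimum-centroid-distance screen: the largest c whose closest
    centroid pair stays well separated (> 0.5 z-units); falls back to 2."""
    best = 2
    for c in candidates:
        try:
            cl = soft_cluster(expr, c, m=m, seed=seed)
        except ValueError:
            break
        v = cl.centroids
        dmin = min(
            float(np.linalg.norm(v[a] - v[b]))
            for a in range(c - 1)
            for b in range(a + 1, c)
        )
        if dmin > 0.5:
            best = c
    return best
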