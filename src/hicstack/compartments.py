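"""A/B compartment profiles, orientation, switching, dynamics, strength.

Compartments are read from principal components of the O/E correlation
matrix (default 100-kb bins). The component that tracks gene density is
selected and oriented so that positive values mean the gene-dense, active
"A" state; per-bin dynamics across developmental stages use one-way ANOVA
with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import BinTable, ContactMatrix, ExpressionTable, GeneModel, SignalTrack


@dataclass
class CompartmentProfile:
    bins: BinTable
    pcs: np.ndarray  # (n_bins, k); NaN on masked bins
    mask: np.ndarray
    selected_pc: Optional[int] = None  # 0-based index into pcs
    values: Optional[np.ndarray] = None  # oriented selected-PC values
    labels: Optional[np.ndarray] = None  # 'A'/'B'/'' per bin
    unresolved: bool = False
    dynamics: Optional[pd.DataFrame] = None  # F, p, q, dynamic per bin

    def ab(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("profile not oriented")
        return self.labels


def compute_pcs(corr: np.ndarray, mask: np.ndarray, k: int = 3) -> np.ndarray:
    """Top-k principal-component projections of the mean-centered
    correlation matrix, ordered by explained variance.

    Rows of the unmasked correlation block are the observations; each bin
    gets its projection onto the leading components (NaN when masked).
    """
    sub = corr[np.ix_(mask, mask)]
    sub = np.nan_to_num(sub, nan=0.0)
    if sub.shape[0] < k + 1 or not np.any(sub):
        raise ValueError("degenerate correlation matrix")
    centered = sub - sub.mean(axis=0, keepdims=True)
    # SVD of the centered row-observations; PC scores = U * S
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate correlation matrix (rank 0)")
    scores = u[:, :k] * s[:k]
    out = np.full((mask.size, k), np.nan)
    out[mask] = scores
    return out


def select_and_orient(
    pcs: np.ndarray,
    gene_density: SignalTrack,
    bins: BinTable,
    mask: np.ndarray,
    corr_floor: float = 0.1,
) -> CompartmentProfile:
    """Pick the PC tracking gene density, orient it so A = positive.

    The selected component maximizes |Pearson r| with the gene-density
    track over unmasked bins (ties to the lower index); its sign is flipped
    if the correlation is negative. If no component reaches ``corr_floor``
    the profile is flagged unresolved and carries no labels.
    """
    gd = gene_density.values
    ok = mask & np.isfinite(gd)
    rs = []
    for k in range(pcs.shape[1]):
        v = pcs[:, k]
        use = ok & np.isfinite(v)
        if use.sum() < 3 or np.std(v[use]) == 0 or np.std(gd[use]) == 0:
            rs.append(0.0)
        else:
            rs.append(float(stats.pearsonr(v[use], gd[use])[0]))
    rs = np.asarray(rs)
    best = int(np.argmax(np.abs(rs)))
    prof = CompartmentProfile(bins, pcs, mask.copy(), selected_pc=best)
    if np.abs(rs[best]) < corr_floor:
        prof.unresolved = True
        warnings.warn("no PC correlates with gene density; profile unresolved")
        return prof
    vals = pcs[:, best].copy()
    if rs[best] < 0:
        vals = -vals
    labels = np.full(bins.n_bins, "", dtype=object)
    scored = mask & np.isfinite(vals)
    labels[scored & (vals > 0)] = "A"
    labels[scored & (vals <= 0)] = "B"
    prof.values = vals
    prof.labels = labels
    return prof


def call_compartments(
    oe: ContactMatrix, gene_density: SignalTrack, k: int = 3, corr_floor: float = 0.1
) -> CompartmentProfile:
    """Convenience wrapper: correlation matrix -> PCs -> oriented profile."""
    from .matrix import correlation_matrix

    corr = correlation_matrix(oe)
    pcs = compute_pcs(corr, oe.mask, k=k)
    return select_and_orient(pcs, gene_density, oe.bins, oe.mask, corr_floor)


def classify_switches(ref: CompartmentProfile, query: CompartmentProfile) -> np.ndarray:
    """Per-bin class among {'A->A','A->B','B->A','B->B'} ('' if unscored)."""
    if ref.labels is None or query.labels is None:
        raise ValueError("both profiles must be oriented")
    n = ref.bins.n_bins
    out = np.full(n, "", dtype=object)
    both = (ref.labels != "") & (query.labels != "")
    for a in ("A", "B"):
        for b in ("A", "B"):
            sel = both & (ref.labels == a) & (query.labels == b)
            out[sel] = f"{a}->{b}"
    return out


def compartment_dynamics(
    values_by_stage: Sequence[np.ndarray],
    mask: np.ndarray,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of PC values per bin across stages.

    Each element of ``values_by_stage`` is an (n_replicates, n_bins) array
    (single-replicate stages may be stacked by the caller into pooled
    pseudo-replicates; the design used is recorded in the output attrs).
    BH adjustment runs genome-wide over scored bins; dynamic <=> q below
    the threshold.
    """
    if len(values_by_stage) < 2:
        raise ValueError("need at least two stages")
    groups = [np.atleast_2d(v) for v in values_by_stage]
    n = groups[0].shape[1]
    F = np.full(n, np.nan)
    p = np.full(n, np.nan)
    for b in range(n):
        if not mask[b]:
            continue
        obs = [g[:, b][np.isfinite(g[:, b])] for g in groups]
        if any(len(o) < 2 for o in obs):
            continue
        if np.ptp(np.concatenate(obs)) == 0:
            F[b], p[b] = 0.0, 1.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.f_oneway(*obs)
        F[b] = 0.0 if np.isnan(res.statistic) else res.statistic
        p[b] = 1.0 if np.isnan(res.pvalue) else res.pvalue
    q = np.full(n, np.nan)
    scored = np.isfinite(p)
    if scored.any():
        q[scored] = multipletests(p[scored], method="fdr_bh")[1]
    df = pd.DataFrame(
        {"F": F, "p": p, "q": q, "dynamic": (q < q_threshold) & scored}
    )
    df.attrs["design"] = "per-stage replicate one-way ANOVA, BH genome-wide"
    return df


def compartment_strength(
    oe: ContactMatrix, profile: CompartmentProfile, n_quantiles: int = 5
) -> tuple[float, np.ndarray]:
    """Saddle statistic: rank bins by the oriented PC into quantiles, average
    O/E per quantile pair, and report (AA + BB) / (2 * AB) over the outer
    quantile corners."""
    if profile.values is None:
        raise ValueError("profile must be oriented")
    vals = profile.values
    use = profile.mask & np.isfinite(vals)
    idx = np.flatnonzero(use)
    order = idx[np.argsort(vals[idx])]  # ascending: B-most ... A-most
    qs = np.array_split(order, n_quantiles)
    saddle = np.full((n_quantiles, n_quantiles), np.nan)
    m = oe.matrix
    for a in range(n_quantiles):
        for b in range(a, n_quantiles):
            block = m[np.ix_(qs[a], qs[b])]
            v = block[np.isfinite(block)]
            if v.size:
                saddle[a, b] = saddle[b, a] = float(v.mean())
    bb, aa, ab = saddle[0, 0], saddle[-1, -1], saddle[0, -1]
    strength = float((aa + bb) / (2.0 * ab))
    return strength, saddle


def switch_expression_test(
    switch_classes: np.ndarray,
    expr: ExpressionTable,
    genes: Sequence[GeneModel],
    bins: BinTable,
    ref_stage,
    query_stage,
    switch: str = "B->A",
    pseudocount: float = 0.1,
) -> dict:
    """One-sided Wilcoxon rank-sum: log-FPKM change of genes in switched
    bins vs the change of all genes (alternative: greater for B->A)."""
    sm = expr.stage_means()
    for s in (ref_stage, query_stage):
        if s not in sm.columns:
            raise ValueError(f"stage {s!r} absent from expression table")
    delta = np.log2(sm[query_stage] + pseudocount) - np.log2(sm[ref_stage] + pseudocount)
    gene_bin = {
        g.gene_id: g.promoter_bin(bins) for g in genes if g.chrom == bins.chrom
    }
    in_class, universe = [], []
    for gid, d in delta.items():
        b = gene_bin.get(gid)
        if b is None or switch_classes[b] == "":
            continue
        universe.append(d)
        if switch_classes[b] == switch:
            in_class.append(d)
    if not in_class:
        warnings.warn(f"no genes in class {switch}; test skipped")
        return {"n_class": 0, "n_all": len(universe), "statistic": np.nan, "p": np.nan}
    alternative = "greater" if switch == "B->A" else "less" if switch == "A->B" else "two-sided"
    res = stats.mannwhitneyu(in_class, universe, alternative=alternative)
    return {
        "n_class": len(in_class),
        "n_all": len(universe),
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_shift": float(np.median(in_class) - np.median(universe)),
    }
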