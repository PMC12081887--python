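"""Super-enhancer identification and interaction analysis.

H3K27ac peaks are stitched when within 12.5 kb of one another (peaks
inside a TSS exclusion zone removed first); stitched regions need more
than 2 constituents to be valid. Regions are ranked by total signal and
split into super-enhancers (SE) and typical enhancers (TE) at the point
where the slope of the rank-vs-signal curve, rescaled to the unit square,
passes 1 (the tangent cutoff of the hockey-stick curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, Interval, IntervalSet, SignalTrack


@dataclass
class StitchedRegion:
    chrom: str
    start: int
    end: int
    n_constituents: int
    signal: float = np.nan
    rank: int = -1
    klass: str = ""  # 'SE' or 'TE' after splitting

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, score=self.signal)


def stitch(
    peaks: IntervalSet,
    gap_bp: int = 12_500,
    tss_positions: Sequence[int] = (),
    tss_flank_bp: int = 2_500,
    min_constituents: int = 3,
) -> list[StitchedRegion]:
    """Transitively merge peaks separated by at most ``gap_bp``.

    Peaks fully contained in any TSS +/- flank window are excluded before
    stitching; stitched regions with fewer than ``min_constituents``
    constituents are dropped (the validity rule: constituents > 2).
    """
    tss = np.sort(np.asarray(list(tss_positions), dtype=np.int64))

    def in_tss_zone(p: Interval) -> bool:
        if tss.size == 0:
            return False
        k = np.searchsorted(tss, p.start)
        for t in tss[max(0, k - 1) : k + 2]:
            if t - tss_flank_bp <= p.start and p.end <= t + tss_flank_bp + 1:
                return True
        return False

    kept = [p for p in peaks if not in_tss_zone(p)]
    kept.sort(key=lambda p: (p.chrom, p.start, p.end))
    regions: list[StitchedRegion] = []
    cur: Optional[list[Interval]] = None
    for p in kept:
        if cur and p.chrom == cur[0].chrom and p.start - max(q.end for q in cur) <= gap_bp:
            cur.append(p)
        else:
            if cur:
                regions.append(_close(cur))
            cur = [p]
    if cur:
        regions.append(_close(cur))
    return [r for r in regions if r.n_constituents >= min_constituents]


def _close(cluster: list[Interval]) -> StitchedRegion:
    return StitchedRegion(
        cluster[0].chrom,
        min(p.start for p in cluster),
        max(p.end for p in cluster),
        len(cluster),
    )


def region_signal(region: StitchedRegion, signal: SignalTrack) -> float:
    """Total signal over the region from a fine-binned track (input-
    subtracted H3K27ac; synthetic data carries no input)."""
    bins = signal.bins
    b0 = region.start // bins.resolution
    b1 = -(-region.end // bins.resolution)
    vals = signal.values[b0:b1]
    return float(np.nansum(vals))


def rank_and_split(
    regions: Sequence[StitchedRegion], signal: SignalTrack
) -> list[StitchedRegion]:
    """Rank regions by total signal and split SE/TE at the tangent cutoff.

    Both axes of the ascending rank-signal curve are rescaled to [0, 1];
    the cutoff is the signal at the point minimizing the number of points
    below the slope-1 line through it (the tangent of the hockey stick).
    Regions with signal strictly above the cutoff are SEs. A flat curve
    yields no SEs.
    """
    regs = list(regions)
    for r in regs:
        r.signal = region_signal(r, signal)
    regs.sort(key=lambda r: r.signal)
    for rank, r in enumerate(regs):
        r.rank = rank
        r.klass = "TE"
    sig = np.array([r.signal for r in regs], dtype=float)
    n = len(sig)
    if n == 0:
        return regs
    if np.ptp(sig) == 0 or n < 2:
        return regs  # flat curve: no super-enhancers
    y = (sig - sig.min()) / np.ptp(sig)
    x = np.arange(n) / (n - 1)

    def points_below(i: int) -> int:
        b = y[i] - x[i]
        return int(np.sum(y <= x + b))

    cut_idx = min(range(n), key=points_below)
    cutoff = sig[cut_idx]
    for r in regs:
        if r.signal > cutoff:
            r.klass = "SE"
    return regs


def se_specificity(
    se_sets: dict[str, Sequence[StitchedRegion]], min_overlap_frac: float = 0.3
) -> dict[str, list[bool]]:
    """An SE is specific to its group when its best reciprocal overlap with
    every other group's SEs stays below ``min_overlap_frac``."""
    def reciprocal(a: StitchedRegion, b: StitchedRegion) -> float:
        ov = min(a.end, b.end) - max(a.start, b.start)
        if ov <= 0 or a.chrom != b.chrom:
            return 0.0
        return min(ov / (a.end - a.start), ov / (b.end - b.start))

    out = {}
    for g, ses in se_sets.items():
        flags = []
        for se in ses:
            best = 0.0
            for h, other in se_sets.items():
                if h == g:
                    continue
                for o in other:
                    best = max(best, reciprocal(se, o))
            # specific iff no other group reaches the reciprocal-overlap floor
            flags.append(best < min_overlap_frac)
        out[g] = flags
    return out


def link_regions_to_genes(
    regions: Sequence[StitchedRegion],
    interactions: pd.DataFrame,
    genes: Sequence[GeneModel],
    bins,
    promoter_flank_bp: int = 2_000,
) -> pd.DataFrame:
    """(region, gene) pairs supported by a significant interaction between
    a region-overlapping bin and the gene's promoter bin.

    Multiple genes sharing one promoter bin all link and are flagged
    ambiguous.
    """
    sig = interactions[interactions["significant"]]
    by_pair = {(int(r.bin1), int(r.bin2)) for r in sig.itertuples()}
    promoter_bins: dict[int, list[GeneModel]] = {}
    for g in genes:
        if g.chrom != bins.chrom:
            continue
        promoter_bins.setdefault(g.promoter_bin(bins), []).append(g)
    rows = []
    for ridx, reg in enumerate(regions):
        b0 = reg.start // bins.resolution
        b1 = (reg.end - 1) // bins.resolution
        for rb in range(b0, b1 + 1):
            for pb, gs in promoter_bins.items():
                if rb == pb:
                    continue
                pair = (min(rb, pb), max(rb, pb))
                if pair in by_pair:
                    for g in gs:
                        rows.append(
                            (ridx, reg.klass, g.gene_id, rb, pb, len(gs) > 1)
                        )
    return pd.DataFrame(
        rows,
        columns=["region_idx", "region_class", "gene_id", "region_bin", "promoter_bin", "ambiguous"],
    ).drop_duplicates(subset=["region_idx", "gene_id"]).reset_index(drop=True)


def se_vs_te_expression(
    se_genes: Sequence[str],
    te_genes: Sequence[str],
    fpkm: pd.DataFrame,
    pseudocount: float = 0.1,
) -> dict:
    """One-sided Wilcoxon rank-sum: SE-linked gene expression greater than
    TE-linked gene expression (mean log2-FPKM per gene)."""
    se = [g for g in set(se_genes) if g in fpkm.index]
    te = [g for g in set(te_genes) if g in fpkm.index]
    if not se or not te:
        warnings.warn("empty SE-linked or TE-linked gene class; test skipped")
        return {"n_se": len(se), "n_te": len(te), "statistic": np.nan, "p": np.nan}
    a = np.log2(fpkm.loc[se].mean(axis=1) + pseudocount)
    b = np.log2(fpkm.loc[te].mean(axis=1) + pseudocount)
    res = stats.mannwhitneyu(a, b, alternative="greater")
    return {
        "n_se": len(se),
        "n_te": len(te),
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_se": float(a.median()),
        "median_te": float(b.median()),
    }


def se_interaction_enrichment(
    se_regions: Sequence[StitchedRegion],
    te_regions: Sequence[StitchedRegion],
    oe,
    trans_matrix: Optional[np.ndarray] = None,
    trans_se_bins_other: Optional[Sequence[int]] = None,
    max_pair_dist_bp: int = 2_500_000,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Cis and trans SE-SE interaction enrichment.

    Cis: per-pair O/E between SE bins within ``max_pair_dist_bp`` (beyond
    a few Mb, single-pixel O/E is shot noise at typical depth), against a
    distance-matched sample of TE-pair O/E values; trans: observed
    inter-chromosomal SE-bin contact rate over the uniform expectation. A
    one-sided Wilcoxon compares the cis SE-SE enrichment distribution
    against the trans one.
    """
    rng = rng or np.random.default_rng(0)
    bins = oe.bins
    max_d = max_pair_dist_bp // bins.resolution
    se_bins = sorted({r.start // bins.resolution for r in se_regions})
    te_bins = sorted({r.start // bins.resolution for r in te_regions})

    def pair_oe(blist):
        vals, dists = [], []
        for a in range(len(blist) - 1):
            for b in range(a + 1, len(blist)):
                if blist[b] - blist[a] > max_d:
                    continue
                v = oe.matrix[blist[a], blist[b]]
                if np.isfinite(v):
                    vals.append(float(v))
                    dists.append(blist[b] - blist[a])
        return np.array(vals), np.array(dists)

    se_oe, se_d = pair_oe(se_bins)
    if se_oe.size == 0:
        raise ValueError("no SE pairs within range")
    te_oe, te_d = pair_oe(te_bins)
    # distance-matched TE background: nearest-distance TE pair per SE pair
    matched = []
    for d in se_d:
        if te_d.size:
            matched.append(te_oe[np.argmin(np.abs(te_d - d))])
    cis_enrichment = float(np.mean(se_oe) / np.mean(matched)) if matched else np.nan

    result = {
        "cis_se_oe": se_oe,
        "cis_te_oe": np.array(matched),
        "cis_enrichment": cis_enrichment,
    }
    if trans_matrix is not None:
        other = (
            list(trans_se_bins_other)
            if trans_se_bins_other is not None
            else list(range(trans_matrix.shape[1]))
        )
        obs = trans_matrix[np.ix_(se_bins, other)].mean()
        expect = trans_matrix.mean()
        trans_ratio = float(obs / expect) if expect > 0 else np.nan
        result["trans_enrichment"] = trans_ratio
        trans_vals = (trans_matrix[np.ix_(se_bins, other)] / max(expect, 1e-300)).ravel()
        if se_oe.size and trans_vals.size:
            res = stats.mannwhitneyu(se_oe, trans_vals, alternative="greater")
            result["cis_vs_trans_p"] = float(res.pvalue)
    return result
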