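"""Insulation scores, TAD boundaries, domains, differential insulation,
and meta-profiles of peak density around anchors.

The insulation score of a diagonal bin is the interquartile-trimmed mean
of the square of pixels linking the ``w`` bins to its left with the ``w``
bins to its right (the bin itself excluded; default square 480 kb x 480 kb
on 40-kb bins). Scores are normalized per chromosome as log2(IS / mean IS);
boundaries are valleys whose prominence against the flanking local maxima
reaches ``delta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome import BinTable, ContactMatrix, Interval, IntervalSet, SignalTrack


@dataclass
class InsulationProfile:
    bins: BinTable
    raw: np.ndarray  # NaN where unscored
    normalized: Optional[np.ndarray] = None

    @property
    def scored(self) -> np.ndarray:
        return np.isfinite(self.raw)


def insulation_score(
    cm: ContactMatrix,
    window_bp: int = 480_000,
    min_valid_frac: float = 0.5,
    decay_normalize: bool = True,
) -> InsulationProfile:
    """Sliding-square insulation on a balanced matrix.

    For bin b the square spans rows (b-w .. b-1) x cols (b+1 .. b+w); the
    score is the mean of the square's unmasked values lying within
    [Q1, Q3] (IQR-trimmed mean). By default the square is first divided by
    the chromosome-wide expected value at each pixel's distance: on raw
    decaying values the interquartile trim selects by distance instead of
    by outlier status, which blunts and displaces valleys
    (``decay_normalize=False`` restores the plain-signal variant).

    Bins within w of either chromosome end, masked bins, and bins whose
    square retains fewer than ``min_valid_frac`` usable pixels get no
    score.
    """
    if cm.state != "balanced":
        raise ValueError("insulation requires a balanced matrix")
    res = cm.bins.resolution
    if window_bp % res:
        raise ValueError("window must be an integer multiple of the resolution")
    w = window_bp // res
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    n = cm.n_bins
    m = np.nan_to_num(cm.matrix, nan=0.0)
    if decay_normalize:
        from .matrix import expected_by_distance

        exp = expected_by_distance(cm)
        dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        with np.errstate(divide="ignore", invalid="ignore"):
            m = m / exp[dist]
        m[~np.isfinite(m)] = 0.0
    valid = cm.valid_pixels()
    raw = np.full(n, np.nan)
    # a masked bin can still be scored: its square links the flanking
    # bins and never touches the bin's own row/column
    for b in range(w, n - w):
        rows = slice(b - w, b)
        cols = slice(b + 1, b + 1 + w)
        ok = valid[rows, cols]
        if ok.mean() < min_valid_frac:
            continue
        raw[b] = iqr_mean(m[rows, cols][ok])
    return InsulationProfile(cm.bins, raw)


def iqr_mean(values: np.ndarray) -> float:
    """Mean of the values within the interquartile range [Q1, Q3]."""
    q1, q3 = np.percentile(values, [25, 75])
    sel = (values >= q1) & (values <= q3)
    return float(values[sel].mean())


def normalize_insulation(profile: InsulationProfile) -> InsulationProfile:
    """log2(IS / chromosome-mean IS) over scored bins."""
    raw = profile.raw
    scored = np.isfinite(raw) & (raw > 0)
    if not scored.any():
        raise ValueError("no scored bins to normalize")
    mean = raw[scored].mean()
    norm = np.full_like(raw, np.nan)
    norm[scored] = np.log2(raw[scored] / mean)
    return InsulationProfile(profile.bins, raw.copy(), norm)


def detect_boundaries(
    profile: InsulationProfile, delta: float = 0.1, max_gap_fill: int = 2
) -> IntervalSet:
    """Valleys of the normalized insulation profile.

    A boundary is a strict local minimum (leftmost bin of an equal-value
    plateau) whose strength — the mean of the nearest flanking local maxima
    minus the minimum value — is at least ``delta``. Unscored gaps of up
    to ``max_gap_fill`` bins inside a scored stretch are bridged by linear
    interpolation so an isolated masked bin cannot split a valley.
    """
    if profile.normalized is None:
        raise ValueError("profile must be normalized first")
    x = _fill_short_gaps(profile.normalized, max_gap_fill)
    bins = profile.bins
    out = IntervalSet()
    for seg in _finite_runs(x):
        v = x[seg]
        if v.size < 3:
            continue
        minima = _plateau_minima(v)
        # segment endpoints double as flanking maxima so that a valley at
        # the edge of the scored span is not scored one-sided
        maxima = sorted(set(_plateau_maxima(v)) | {0, v.size - 1})
        for mb in minima:
            left = [mx for mx in maxima if mx < mb]
            right = [mx for mx in maxima if mx > mb]
            flank = []
            if left:
                flank.append(v[left[-1]])
            if right:
                flank.append(v[right[0]])
            if not flank:
                continue
            strength = float(np.mean(flank) - v[mb])
            if strength >= delta:
                b = seg.start + mb
                out.add(
                    Interval(
                        bins.chrom,
                        bins.bin_start(b),
                        bins.bin_end(b),
                        name=f"boundary_{b}",
                        score=strength,
                    )
                )
    return out


def _fill_short_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap that are flanked
    by finite values on both sides."""
    if max_gap <= 0:
        return x
    y = x.copy()
    n = len(y)
    i = 0
    while i < n:
        if np.isfinite(y[i]):
            i += 1
            continue
        j = i
        while j < n and not np.isfinite(y[j]):
            j += 1
        if 0 < i and j < n and (j - i) <= max_gap:
            y[i:j] = np.interp(np.arange(i, j), [i - 1, j], [y[i - 1], y[j]])
        i = j
    return y


def _finite_runs(x: np.ndarray) -> list[slice]:
    runs, start = [], None
    for i, ok in enumerate(np.isfinite(x)):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append(slice(start, i))
            start = None
    if start is not None:
        runs.append(slice(start, len(x)))
    return runs


def _plateau_minima(v: np.ndarray) -> list[int]:
    """Interior local minima; an equal-value plateau yields its leftmost bin."""
    return _plateau_extrema(v, sign=1)


def _plateau_maxima(v: np.ndarray) -> list[int]:
    return _plateau_extrema(v, sign=-1)


def _plateau_extrema(v: np.ndarray, sign: int) -> list[int]:
    y = sign * v
    out = []
    i = 1
    n = len(y)
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[j]:
            j += 1
        if y[i - 1] > y[i] and j + 1 < n and y[j + 1] > y[j]:
            out.append(i)
        i = j + 1
    return out


def tads_from_boundaries(
    boundaries: IntervalSet,
    profile: InsulationProfile,
    min_size_bp: int = 400_000,
) -> IntervalSet:
    """Domains between consecutive boundaries within the scored span.

    The first/last domain is closed by the scored ends of the chromosome;
    domains shorter than ``min_size_bp`` are dropped.
    """
    bins = profile.bins
    scored = np.flatnonzero(profile.scored)
    if scored.size == 0:
        return IntervalSet()
    span_start, span_end = int(scored[0]), int(scored[-1]) + 1
    cuts = sorted(
        iv.start // bins.resolution
        for iv in boundaries
        if span_start < iv.start // bins.resolution < span_end
    )
    edges = [span_start] + cuts + [span_end]
    out = IntervalSet()
    for k in range(len(edges) - 1):
        s, e = edges[k], edges[k + 1]
        start_bp, end_bp = bins.bin_start(s), bins.bin_start(e) if e < bins.n_bins else bins.length
        if end_bp - start_bp < min_size_bp:
            continue
        out.add(Interval(bins.chrom, start_bp, end_bp, name=f"tad_{k}"))
    return out


def differential_insulation(
    profile_a: InsulationProfile,
    profile_b: InsulationProfile,
    min_abs_diff: float = 0.5,
    min_run: int = 2,
) -> IntervalSet:
    """Maximal runs of >= min_run consecutive bins whose normalized scores
    differ by at least ``min_abs_diff``."""
    if profile_a.normalized is None or profile_b.normalized is None:
        raise ValueError("profiles must be normalized")
    diff = np.abs(profile_a.normalized - profile_b.normalized)
    hit = np.isfinite(diff) & (diff >= min_abs_diff)
    bins = profile_a.bins
    out = IntervalSet()
    for seg in _finite_runs(np.where(hit, 1.0, np.nan)):
        if seg.stop - seg.start >= min_run:
            out.add(
                Interval(
                    bins.chrom,
                    bins.bin_start(seg.start),
                    bins.bin_end(seg.stop - 1),
                    name="diff_ins",
                    score=float(np.nanmean(diff[seg])),
                )
            )
    return out


def meta_profile(
    anchors: IntervalSet,
    peaks: IntervalSet,
    flank_bp: int,
    n_bins: int = 41,
) -> np.ndarray:
    """Average peak-midpoint density in windows centered on anchor midpoints.

    Returns peak counts per window bin averaged over anchors (density per
    anchor per bin).
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    edges = np.linspace(-flank_bp, flank_bp, n_bins + 1)
    acc = np.zeros(n_bins)
    mids = np.array([p.mid for p in peaks])
    for a in anchors:
        if mids.size == 0:
            continue
        rel = mids - a.mid
        hist, _ = np.histogram(rel, bins=edges)
        acc += hist
    return acc / len(anchors)
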