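"""Feature-free comparison of contact maps with a structural-similarity
score over sliding windows.

Two O/E-normalized windows R and Q are compared with the product of a
brightness (mean), contrast (variance), and structure (correlation) term:

    S = l(R,Q) * c(R,Q) * s(R,Q)
    l = (2 mu_R mu_Q + C1) / (mu_R^2 + mu_Q^2 + C1)
    c = (2 sd_R sd_Q + C2) / (sd_R^2 + sd_Q^2 + C2)
    s = (cov_RQ + C3) / (sd_R sd_Q + C3)

S is 1 for identical windows, bounded by [-1, 1], and 0 for unrelated
windows. Windows are rescaled to equal pixel dimensions before comparison;
significance over a genome scan is empirical (rank among all windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import zoom as _zoom

from .genome import ContactMatrix, Interval, IntervalSet


@dataclass
class SimilarityWindow:
    start_bp: int
    end_bp: int
    S: float
    brightness: float
    contrast: float
    structure: float
    z: float = np.nan
    p: float = np.nan


def ssim(
    r: np.ndarray,
    q: np.ndarray,
    rel_constant: float = 0.01,
    exponents: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[float, tuple[float, float, float]]:
    """Structural similarity between two equal-size windows.

    Stabilizing constants scale with the dynamic range D of the two
    windows: C1 = C2 = (rel_constant * D)^2, C3 = C2 / 2; identical
    windows score exactly 1 regardless of the constants.
    """
    r = np.asarray(r, dtype=float)
    q = np.asarray(q, dtype=float)
    if r.shape != q.shape:
        raise ValueError(f"window shapes differ: {r.shape} vs {q.shape}")
    d_range = max(r.max() - r.min(), q.max() - q.min())
    c1 = c2 = (rel_constant * d_range) ** 2
    if c1 == 0:
        c1 = c2 = (rel_constant) ** 2  # both windows constant
    c3 = c2 / 2.0
    mu_r, mu_q = r.mean(), q.mean()
    sd_r, sd_q = r.std(), q.std()
    cov = float(((r - mu_r) * (q - mu_q)).mean())
    lum = (2 * mu_r * mu_q + c1) / (mu_r**2 + mu_q**2 + c1)
    con = (2 * sd_r * sd_q + c2) / (sd_r**2 + sd_q**2 + c2)
    stru = (cov + c3) / (sd_r * sd_q + c3)
    a, b, g = exponents
    s = float(np.sign(lum) * np.abs(lum) ** a * np.abs(con) ** b * np.sign(stru) * np.abs(stru) ** g)
    # |S| <= 1 holds analytically (AM-GM on l and c, Cauchy-Schwarz plus
    # C3 > 0 on s); clip the last-ulp float excursions
    s = float(np.clip(s, -1.0, 1.0))
    return s, (float(lum), float(con), float(stru))


def rescale_window(w: np.ndarray, target: int) -> np.ndarray:
    """Bilinear rescale of a square window to target x target pixels."""
    if w.shape[0] == target:
        return w
    return _zoom(w, target / w.shape[0], order=1)


def _extract_window(
    oe: ContactMatrix, b0: int, b1: int, max_masked_frac: float = 0.3
) -> Optional[np.ndarray]:
    """O/E submatrix with masked/undefined pixels imputed as 1 (the O/E
    expectation); None when more than ``max_masked_frac`` is undefined."""
    win = oe.matrix[b0:b1, b0:b1].copy()
    bad = ~np.isfinite(win)
    if bad.mean() > max_masked_frac:
        return None
    win[bad] = 1.0
    return win


def sliding_similarity(
    oe_a: ContactMatrix,
    oe_b: ContactMatrix,
    window_bp: int = 2_000_000,
    step_bp: int = 500_000,
    rel_constant: float = 0.01,
    min_windows_for_p: int = 10,
) -> list[SimilarityWindow]:
    """Genome-tiled SSIM between two O/E maps of the same chromosome.

    z-scores are against the mean/sd of all window scores; the empirical p
    is the left-tail rank probability of each score among all windows
    (suppressed with a warning when fewer than ``min_windows_for_p``
    windows are scored).
    """
    if oe_a.state != "oe" or oe_b.state != "oe":
        raise ValueError("sliding similarity runs on O/E matrices")
    if oe_a.bins.resolution != oe_b.bins.resolution:
        raise ValueError("matrices must share a resolution")
    res = oe_a.bins.resolution
    wbins, sbins = window_bp // res, step_bp // res
    if wbins < 2 or sbins < 1:
        raise ValueError("window/step too small for the resolution")
    n = min(oe_a.n_bins, oe_b.n_bins)
    out = []
    for b0 in range(0, n - wbins + 1, sbins):
        wa = _extract_window(oe_a, b0, b0 + wbins)
        wb = _extract_window(oe_b, b0, b0 + wbins)
        if wa is None or wb is None:
            continue
        s, (lum, con, stru) = ssim(wa, wb, rel_constant)
        out.append(
            SimilarityWindow(b0 * res, (b0 + wbins) * res, s, lum, con, stru)
        )
    scores = np.array([w.S for w in out])
    if scores.size:
        sd = scores.std()
        mean = scores.mean()
        for w in out:
            w.z = (w.S - mean) / sd if sd > 0 else 0.0
        if scores.size >= min_windows_for_p:
            for w in out:
                w.p = float(np.mean(scores <= w.S))
        else:
            warnings.warn("fewer than %d windows; empirical p suppressed" % min_windows_for_p)
    return out


def dissimilar_regions(
    windows: list[SimilarityWindow], z_threshold: float = 2.0
) -> IntervalSet:
    """Windows with z <= -z_threshold, merged when overlapping."""
    flagged = sorted(
        (w for w in windows if np.isfinite(w.z) and w.z <= -z_threshold),
        key=lambda w: w.start_bp,
    )
    out = IntervalSet()
    cur = None
    for w in flagged:
        if cur and w.start_bp <= cur[1]:
            cur = (cur[0], max(cur[1], w.end_bp), min(cur[2], w.z))
        else:
            if cur:
                out.add(Interval("", cur[0], cur[1], "dissimilar", cur[2]))
            cur = (w.start_bp, w.end_bp, w.z)
    if cur:
        out.add(Interval("", cur[0], cur[1], "dissimilar", cur[2]))
    return out


def windows_frame(windows: list[SimilarityWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.start_bp, w.end_bp, w.S, w.brightness, w.contrast, w.structure, w.z, w.p)
            for w in windows
        ],
        columns=["start", "end", "S", "brightness", "contrast", "structure", "z", "p"],
    )
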