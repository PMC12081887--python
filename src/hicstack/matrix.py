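"""Contact-matrix normalization: bin filtering, ICE balancing, distance
expectation, observed/expected, and the bin-bin correlation matrix.

ICE (iterative correction) removes multiplicative per-bin biases by
equalizing matrix marginals. Weights follow the multiplicative convention:
``balanced_ij = raw_ij * w_i * w_j``, with the mean weight over unmasked
bins normalized to 1, so recovered weights are proportional to the inverse
of the planted biases.
"""

from __future__ import annotations

import logging

import numpy as np

from .genome import ContactMatrix

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, last_cv: float):
        super().__init__(msg)
        self.last_cv = last_cv


def marginals(cm: ContactMatrix) -> np.ndarray:
    """Row sums over unmasked columns (NaN-safe)."""
    m = np.nan_to_num(cm.matrix, nan=0.0)
    return m[:, cm.mask].sum(axis=1)


def mask_low_coverage(cm: ContactMatrix, min_quantile: float = 0.02) -> ContactMatrix:
    """Mask bins whose marginal total is zero or in the lowest quantile of
    nonzero marginals; entries touching masked bins are dropped.
    """
    if cm.state != "raw":
        raise ValueError("coverage filtering applies to raw matrices")
    marg = marginals(cm)
    bad = marg <= 0
    nz = marg[marg > 0]
    if nz.size and min_quantile > 0:
        thr = np.quantile(nz, min_quantile)
        bad |= marg < thr
    new_mask = cm.mask & ~bad
    if not new_mask.any():
        raise ValueError("all bins masked by coverage filter")
    out = cm.copy()
    out.mask = new_mask
    out.matrix[~new_mask, :] = 0.0
    out.matrix[:, ~new_mask] = 0.0
    log.info("masked %d/%d bins", int((~new_mask).sum()), cm.n_bins)
    return out


def ice_balance(
    cm: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """ICE-balance a masked raw matrix.

    Converged when the coefficient of variation of unmasked marginals drops
    below ``tol``. Total mass is preserved up to a global rescale fixed by
    normalizing the mean weight over unmasked bins to 1.
    """
    if cm.state != "raw":
        raise ValueError("ICE input must be a raw matrix")
    mask = cm.mask
    if mask.sum() < 2:
        raise ValueError("need at least 2 unmasked bins to balance")
    a = np.nan_to_num(cm.matrix, nan=0.0).copy()
    a[~mask, :] = 0.0
    a[:, ~mask] = 0.0
    b = np.ones(cm.n_bins)
    cv = np.inf
    for _ in range(max_iter):
        s = a.sum(axis=1)
        sm = s[mask]
        mean = sm.mean()
        if mean <= 0:
            raise ValueError("unmasked matrix has no mass")
        cv = sm.std() / mean
        if cv < tol:
            break
        step = np.ones(cm.n_bins)
        step[mask] = sm / mean
        a /= np.outer(step, step)
        b *= step
    else:
        raise ConvergenceError(
            f"ICE did not reach CV < {tol} in {max_iter} iterations (CV={cv:.3g})",
            cv,
        )
    w = np.full(cm.n_bins, np.nan)
    w[mask] = (1.0 / b[mask])
    w[mask] /= np.nanmean(w[mask])
    raw = np.nan_to_num(cm.matrix, nan=0.0)
    balanced = raw * np.outer(np.nan_to_num(w, nan=0.0), np.nan_to_num(w, nan=0.0))
    balanced[~mask, :] = 0.0
    balanced[:, ~mask] = 0.0
    return ContactMatrix(cm.bins, balanced, mask.copy(), w, state="balanced")


def expected_by_distance(cm: ContactMatrix) -> np.ndarray:
    """Mean value over unmasked pixels at each diagonal offset.

    Stored zeros between unmasked bins count toward the mean (sparse
    storage makes this ambiguous; absent entries within the unmasked span
    are zeros). Returns a length-n vector; distances with no unmasked
    pixels are NaN.
    """
    if cm.state != "balanced":
        raise ValueError("expected profile is computed on balanced matrices")
    n = cm.n_bins
    m = np.nan_to_num(cm.matrix, nan=0.0)
    valid = cm.valid_pixels()
    exp = np.full(n, np.nan)
    for d in range(n):
        vm = np.diagonal(valid, offset=d)
        if vm.any():
            exp[d] = np.diagonal(m, offset=d)[vm].mean()
    return exp


def observed_over_expected(cm: ContactMatrix) -> ContactMatrix:
    """Divide each pixel by the distance expectation; zero-expected
    distances and masked pixels become NaN."""
    exp = expected_by_distance(cm)
    n = cm.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    denom = exp[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.nan_to_num(cm.matrix, nan=0.0) / denom
    oe[~np.isfinite(oe)] = np.nan
    oe[~cm.mask, :] = np.nan
    oe[:, ~cm.mask] = np.nan
    return ContactMatrix(cm.bins, _symmetrize_nan(oe), cm.mask.copy(), cm.weights, "oe")


def _symmetrize_nan(m: np.ndarray) -> np.ndarray:
    up = np.triu(np.nan_to_num(m, nan=0.0)) + np.triu(np.nan_to_num(m, nan=0.0), 1).T
    nan_up = np.triu(np.isnan(m)) | np.triu(np.isnan(m), 1).T
    up[nan_up] = np.nan
    return up


def correlation_matrix(oe: ContactMatrix) -> np.ndarray:
    """Pearson correlation between O/E rows over unmasked columns.

    Non-finite O/E pixels (zero-expected distances) are treated as the
    neutral value 1 before correlating. Masked rows/columns are NaN;
    the diagonal of the unmasked block is 1.
    """
    if oe.state != "oe":
        raise ValueError("correlation matrix is computed on O/E matrices")
    mask = oe.mask
    sub = oe.matrix[np.ix_(mask, mask)].copy()
    sub[~np.isfinite(sub)] = 1.0
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(sub)
    # constant rows give NaN correlation; leave them NaN but fix diagonal
    np.fill_diagonal(c, 1.0)
    out = np.full((oe.n_bins, oe.n_bins), np.nan)
    out[np.ix_(mask, mask)] = c
    return out
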