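"""Core genomic data containers shared by every pipeline stage.

All coordinates are 0-based half-open, BED-style. Contact matrices are
symmetric and stored densely with an explicit upper-triangle sparse
interchange format (see :mod:`hicstack.io`); per-bin validity is tracked
with a boolean mask so that filtered (repetitive / low-coverage) bins are
distinguishable from bins that simply have zero counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
import pandas as pd

MatrixState = Literal["raw", "balanced", "oe"]


@dataclass(frozen=True)
class BinTable:
    """Uniform binning of one chromosome.

    Bins tile ``[0, length)`` without gaps or overlaps; the last bin may be
    shorter than ``resolution``.
    """

    chrom: str
    length: int
    resolution: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_bins(self) -> int:
        return -(-self.length // self.resolution)

    def bin_index(self, pos: int) -> int:
        """Bin containing position ``pos`` (0-based)."""
        if not 0 <= pos < self.length:
            raise ValueError(f"position {pos} outside [0, {self.length})")
        return pos // self.resolution

    def bin_start(self, i: int) -> int:
        return i * self.resolution

    def bin_end(self, i: int) -> int:
        return min((i + 1) * self.resolution, self.length)

    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.resolution

    def ends(self) -> np.ndarray:
        return np.minimum(self.starts() + self.resolution, self.length)

    def mids(self) -> np.ndarray:
        return (self.starts() + self.ends()) // 2


@dataclass
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """Ordered collection of genomic intervals (peaks, TADs, SEs, ...)."""

    def __init__(self, intervals: Sequence[Interval] = ()) -> None:
        self.intervals: list[Interval] = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    def add(self, iv: Interval) -> None:
        self.intervals.append(iv)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
                for iv in self.intervals
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalSet":
        ivs = [
            Interval(
                str(r.chrom),
                int(r.start),
                int(r.end),
                str(getattr(r, "name_", getattr(r, "name", "."))),
                float(getattr(r, "score", 0.0)),
                str(getattr(r, "strand", ".")),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(ivs)


@dataclass
class SignalTrack:
    """One numeric value per bin; missing values are NaN, never silent zeros."""

    bins: BinTable
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.bins.n_bins,):
            raise ValueError("one value per bin required")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class GeneModel:
    """Gene with a deterministic promoter derived from its TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if self.start >= self.end:
            raise ValueError("gene start >= end")
        if not self.symbol:
            self.symbol = self.gene_id

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, flank: int = 2000) -> Interval:
        return Interval(
            self.chrom,
            max(0, self.tss - flank),
            self.tss + flank + 1,
            name=self.gene_id,
            strand=self.strand,
        )

    def promoter_bin(self, bins: BinTable) -> int:
        return bins.bin_index(min(self.tss, bins.length - 1))


@dataclass
class ExpressionTable:
    """Genes x samples FPKM matrix with per-sample stage/region metadata."""

    fpkm: pd.DataFrame  # index = gene ids, columns = sample ids
    samples: pd.DataFrame  # index = sample ids; columns: stage, region

    def __post_init__(self) -> None:
        if not set(self.fpkm.columns) <= set(self.samples.index):
            raise ValueError("every expression column needs sample metadata")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        for col in ("stage", "region"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks {col!r}")

    @property
    def genes(self) -> pd.Index:
        return self.fpkm.index

    def stages(self) -> list:
        order = self.samples.loc[self.fpkm.columns, "stage"]
        seen: list = []
        for s in order:
            if s not in seen:
                seen.append(s)
        return seen

    def stage_means(self) -> pd.DataFrame:
        """Mean FPKM per gene per stage (averaging regions/replicates)."""
        stage_of = self.samples.loc[self.fpkm.columns, "stage"]
        return self.fpkm.T.groupby(stage_of.values).mean().T[self.stages()]


class ContactMatrix:
    """Symmetric per-chromosome contact matrix.

    Stored as a dense symmetric float array together with a per-bin validity
    mask. ``state`` tracks the normalization stage (raw counts, ICE-balanced,
    or observed/expected); balancing weights (multiplicative, cooler-style:
    ``balanced_ij = raw_ij * w_i * w_j``) accompany every non-raw state.
    """

    def __init__(
        self,
        bins: BinTable,
        matrix: np.ndarray,
        mask: Optional[np.ndarray] = None,
        weights: Optional[np.ndarray] = None,
        state: MatrixState = "raw",
    ) -> None:
        n = bins.n_bins
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (n, n):
            raise ValueError(f"matrix shape {matrix.shape} != ({n}, {n})")
        if not np.allclose(matrix, matrix.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        if state == "raw":
            if weights is not None:
                raise ValueError("raw matrices carry no weights")
            with np.errstate(invalid="ignore"):
                if np.nanmin(matrix) < 0:
                    raise ValueError("raw counts must be non-negative")
        elif weights is None:
            raise ValueError(f"state {state!r} requires weights")
        self.bins = bins
        self.matrix = matrix
        self.mask = (
            np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        )
        if self.mask.shape != (n,):
            raise ValueError("mask must have one flag per bin")
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.state: MatrixState = state

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @classmethod
    def from_triples(
        cls,
        bins: BinTable,
        i: np.ndarray,
        j: np.ndarray,
        values: np.ndarray,
    ) -> "ContactMatrix":
        """Build a raw matrix from (i, j, count) triples.

        Lower-triangle entries are folded onto the upper triangle and
        duplicate pixels are summed, so mirrored inputs accumulate.
        """
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        n = bins.n_bins
        if i.size and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
            raise ValueError("bin index out of range for bin table")
        if values.size and values.min() < 0:
            raise ValueError("negative contact count")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        m = np.zeros((n, n))
        np.add.at(m, (lo, hi), values)
        upper = np.triu(m)
        m = upper + np.triu(upper, 1).T
        return cls(bins, m, state="raw")

    def triples(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle (i <= j) nonzero pixels as index/value arrays."""
        upper = np.triu(np.nan_to_num(self.matrix, nan=0.0))
        i, j = np.nonzero(upper)
        return i, j, upper[i, j]

    def valid_pixels(self) -> np.ndarray:
        """Boolean (n, n) matrix: both bins unmasked."""
        return np.outer(self.mask, self.mask)

    def symmetric_sum(self) -> float:
        """Total mass counting each off-diagonal pixel twice."""
        m = np.nan_to_num(self.matrix, nan=0.0)
        return float(m.sum())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bins,
            self.matrix.copy(),
            self.mask.copy(),
            None if self.weights is None else self.weights.copy(),
            self.state,
        )
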