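"""Readers and writers for the plain-text interchange formats.

Canonical formats: 3-column sparse matrix triples (bin_i, bin_j, count),
BED3+/BED6, BEDPE, bedGraph, 2-column chrom.sizes, and TSV tables with a
header row for genes, expression, and SNPs. Coordinates are 0-based
half-open throughout.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .genome import (
    BinTable,
    ContactMatrix,
    ExpressionTable,
    GeneModel,
    Interval,
    IntervalSet,
    SignalTrack,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def read_contact_matrix(path: PathLike, bins: BinTable) -> ContactMatrix:
    """Read sparse triples (i, j, count) into a raw contact matrix.

    Lower-triangle entries fold to the upper triangle; duplicates sum.
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=["i", "j", "count"], comment="#"
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({"i": [], "j": [], "count": []})
    try:
        return ContactMatrix.from_triples(
            bins,
            df["i"].to_numpy(np.int64),
            df["j"].to_numpy(np.int64),
            df["count"].to_numpy(float),
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_contact_matrix(path: PathLike, cm: ContactMatrix) -> None:
    i, j, v = cm.triples()
    df = pd.DataFrame({"i": i, "j": j, "count": v})
    if cm.state == "raw":
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def read_intervals(path: PathLike, fmt: str = "BED") -> Union[IntervalSet, list]:
    """Read BED3+/BED6 intervals or BEDPE anchor pairs.

    Records with ``start >= end`` are rejected with a logged warning rather
    than aborting the run.
    """
    fmt = fmt.upper()
    if fmt == "BED":
        out = IntervalSet()
        for ln, parts in _fields(path):
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            if start >= end:
                log.warning("%s:%d: rejected interval with start >= end", path, ln)
                warnings.warn(f"{path}:{ln}: start >= end, record skipped")
                continue
            out.add(Interval(chrom, start, end, name, score, strand))
        return out
    if fmt == "BEDPE":
        pairs = []
        for ln, parts in _fields(path):
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: BEDPE needs >= 6 columns")
            a = (parts[0], int(parts[1]), int(parts[2]))
            b = (parts[3], int(parts[4]), int(parts[5]))
            if a[1] >= a[2] or b[1] >= b[2]:
                log.warning("%s:%d: rejected pair with start >= end", path, ln)
                warnings.warn(f"{path}:{ln}: start >= end, record skipped")
                continue
            pairs.append((a, b, parts[6:]))
        return pairs
    raise ValueError(f"unknown interval format {fmt!r}")


def _fields(path: PathLike):
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield ln, line.split("\t") if "\t" in line else line.split()


def write_bed(path: PathLike, ivs: IntervalSet) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def write_bedpe(path: PathLike, rows: Iterable[tuple]) -> None:
    """Rows of ((chrom, s1, e1), (chrom, s2, e2), *extra columns)."""
    with open(path, "w") as fh:
        for a, b, *extra in rows:
            cols = [a[0], a[1], a[2], b[0], b[1], b[2]]
            if extra:
                cols.extend(extra[0] if len(extra) == 1 and isinstance(extra[0], (list, tuple)) else extra)
            fh.write("\t".join(str(c) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def read_bedgraph(path: PathLike, bins: BinTable) -> SignalTrack:
    """Read a bedGraph whose records align with the bin grid."""
    vals = np.full(bins.n_bins, np.nan)
    for ln, parts in _fields(path):
        if len(parts) < 4:
            raise FormatError(f"{path}:{ln}: bedGraph needs 4 columns")
        chrom, start, end, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if chrom != bins.chrom:
            continue
        b0, b1 = start // bins.resolution, -(-end // bins.resolution)
        vals[b0:b1] = v
    return SignalTrack(bins, vals)


def write_bedgraph(path: PathLike, track: SignalTrack) -> None:
    bins = track.bins
    with open(path, "w") as fh:
        for b in range(bins.n_bins):
            v = track.values[b]
            if np.isfinite(v):
                fh.write(f"{bins.chrom}\t{bins.bin_start(b)}\t{bins.bin_end(b)}\t{v:.6g}\n")


def bin_signal(
    intervals: IntervalSet,
    bins: BinTable,
    reducer: str = "count",
    use_scores: bool = False,
) -> SignalTrack:
    """Aggregate intervals onto the bin grid.

    ``count`` adds 1 to every overlapped bin per interval; ``sum`` distributes
    the interval's weight (its score when ``use_scores`` else its length in
    bp) proportionally to the overlap fraction in each bin; ``mean`` is the
    overlap-weighted mean score.
    """
    if reducer not in ("sum", "mean", "count"):
        raise ValueError(f"unknown reducer {reducer!r}")
    acc = np.zeros(bins.n_bins)
    wsum = np.zeros(bins.n_bins)
    for iv in intervals:
        if iv.chrom != bins.chrom:
            continue
        start, end = max(0, iv.start), min(bins.length, iv.end)
        if start >= end:
            continue
        b0, b1 = start // bins.resolution, (end - 1) // bins.resolution
        for b in range(b0, b1 + 1):
            ov = min(end, bins.bin_end(b)) - max(start, bins.bin_start(b))
            if ov <= 0:
                continue
            frac = ov / iv.length
            if reducer == "count":
                acc[b] += 1
            elif reducer == "sum":
                acc[b] += (iv.score if use_scores else iv.length) * frac
            else:
                acc[b] += iv.score * ov
                wsum[b] += ov
    if reducer == "mean":
        with np.errstate(invalid="ignore"):
            vals = np.where(wsum > 0, acc / np.maximum(wsum, 1e-300), np.nan)
        return SignalTrack(bins, vals)
    return SignalTrack(bins, acc)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_genes(path: PathLike) -> list[GeneModel]:
    """TSV with header: gene_id, chrom, start, end, strand[, symbol]."""
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples(index=False):
        genes.append(
            GeneModel(
                str(r.gene_id),
                str(r.chrom),
                int(r.start),
                int(r.end),
                str(r.strand),
                str(getattr(r, "symbol", "") or ""),
            )
        )
    return genes


def write_genes(path: PathLike, genes: Iterable[GeneModel]) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.symbol) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand", "symbol"],
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: PathLike, samples_path: PathLike) -> ExpressionTable:
    fpkm = pd.read_csv(path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionTable(fpkm, samples)


def write_expression(path: PathLike, samples_path: PathLike, expr: ExpressionTable) -> None:
    expr.fpkm.to_csv(path, sep="\t")
    expr.samples.to_csv(samples_path, sep="\t")


def read_snps(path: PathLike) -> pd.DataFrame:
    """TSV with header: rsid, chrom, pos, pvalue, trait[, provenance]."""
    df = pd.read_csv(path, sep="\t")
    required = {"rsid", "chrom", "pos", "pvalue", "trait"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: SNP table needs columns {sorted(required)}")
    if "provenance" not in df.columns:
        df["provenance"] = "index"
    return df


def validate(path: PathLike, fmt: str, bins: BinTable | None = None) -> bool:
    """Light-weight format check used by ``bh io validate``."""
    fmt = fmt.lower()
    if fmt == "matrix":
        if bins is None:
            raise ValueError("matrix validation needs a bin table")
        read_contact_matrix(path, bins)
    elif fmt in ("bed", "bedpe"):
        read_intervals(path, fmt.upper())
    elif fmt == "bedgraph":
        if bins is None:
            raise ValueError("bedGraph validation needs a bin table")
        read_bedgraph(path, bins)
    elif fmt == "snps":
        read_snps(path)
    elif fmt == "genes":
        read_genes(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return True
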