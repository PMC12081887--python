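"""Synthetic Hi-C datasets with planted ground truth.

The generator emulates the statistical structure of binned mammalian Hi-C
and its companion assays: power-law distance decay, plaid compartment
structure coupled to gene density, TAD blocks with enriched internal
contacts, focal loops with shoulders, multiplicative per-bin biases,
H3K27ac peak clusters that stitch into super-enhancers, CTCF peaks at
domain boundaries, expression coupled to compartment status / loop
strength / developmental stage, and intergenic GWAS SNPs looped to gene
promoters. Every planted feature is recorded once in :class:`GroundTruth`
so downstream callers can be scored for recovery and calibration.

Counts are Poisson draws around the composed intensity

    lambda_ij = L * f(|i-j|) * (1 + a*c_i*c_j) * T_ij * P_ij * b_i*b_j

with f(d) ~ d^-alpha, T the within-TAD enrichment, P the focal loop
enrichment (phi at the loop pixel, phi/2 on its 1-bin shoulder ring), and
b the hidden per-bin biases. The same seed reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

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


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic chromosome / dataset.

    Defaults describe a 20-Mb chromosome at the working resolution of the
    stage under study; amplitudes are the study conditions, not tuning
    knobs (see docs/methods.md).
    """

    chrom: str = "chrS"
    length: int = 20_000_000
    resolution: int = 40_000
    library_size: float = 5e6  # expected total counts (upper triangle)
    alpha: float = 1.0  # decay exponent of f(d) ~ d^-alpha
    plaid_amplitude: float = 0.4  # a in (1 + a*c_i*c_j)
    compartment_block_mean_bp: int = 1_500_000
    tad_min_bp: int = 400_000
    tad_max_bp: int = 1_200_000
    tau: float = 2.5  # within-TAD fold enrichment
    n_loops: int = 25
    loop_fold: float = 5.0  # phi
    loop_min_dist_bp: int = 200_000
    loop_max_dist_bp: int = 800_000
    bias_log2_halfwidth: float = 1.0  # biases log-uniform in [0.5, 2]
    with_biases: bool = True
    overdispersion: float = 0.0  # Gamma CV^2 of optional per-pixel multiplier
    # tracks
    n_se: int = 6
    se_constituents: tuple[int, int] = (3, 6)
    se_peak_score: tuple[float, float] = (15.0, 40.0)
    te_count: int = 40
    te_peak_score: tuple[float, float] = (2.0, 8.0)
    peak_width_bp: tuple[int, int] = (800, 2000)
    peak_gap_bp: tuple[int, int] = (2000, 8000)
    ctcf_background_per_mb: float = 1.0
    n_genes: int = 400
    gene_density_contrast: float = 3.0  # TSS rate ratio A:B
    # expression
    n_stages: int = 5
    n_regions: int = 1
    switch_frac: float = 0.10  # bins flipping compartment early -> late
    beta_comp: float = 1.0  # log2-FPKM boost in A
    beta_loop: float = 1.0  # log2-FPKM per unit loop-strength multiplier
    beta_se: float = 1.5  # log2-FPKM boost for SE-linked genes
    traj_amplitude: float = 2.0  # log2-FPKM span of stage trends
    expr_noise_sd: float = 0.5
    silent_gene_frac: float = 0.1
    # SNPs
    n_index_snps: int = 40
    snp_linked_frac: float = 0.6
    snp_loop_fold: float = 6.0
    n_nonsig_snps: int = 10
    ld_window_bp: int = 50_000
    seed: int = 0

    def bin_table(self) -> BinTable:
        return BinTable(self.chrom, self.length, self.resolution)

    @property
    def n_bins(self) -> int:
        return self.bin_table().n_bins

    def validate(self) -> None:
        if not 0 <= self.plaid_amplitude < 1:
            raise ValueError("plaid amplitude must lie in [0, 1)")
        for name in ("tau", "loop_fold", "library_size", "snp_loop_fold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tad_min_bp < 2 * self.resolution:
            raise ValueError("TADs must span at least 2 bins")


@dataclass
class GroundTruth:
    """Everything that was planted, exactly once per feature."""

    resolution: int
    n_bins: int
    compartment_sign: np.ndarray  # +1 (A-like) / -1 per bin
    compartment_sign_late: np.ndarray  # after developmental switching
    boundaries: list  # interior TAD-junction bin indices
    tads: list  # (start_bin, end_bin) half-open
    loops: list  # dicts: i, j, fold, kind
    biases: np.ndarray
    se_sites: list = field(default_factory=list)  # dicts: bin, peaks
    te_sites: list = field(default_factory=list)
    genes: list = field(default_factory=list)  # dicts incl. drivers
    snp_links: list = field(default_factory=list)  # (rsid, gene_id)
    loop_stage_mult: Optional[np.ndarray] = None  # (n_loops, n_stages)
    cluster_of_gene: dict = field(default_factory=dict)

    def loop_pixels(self) -> set[tuple[int, int]]:
        return {(l["i"], l["j"]) for l in self.loops}

    def to_json(self, path) -> None:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, default=enc)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("compartment_sign", "compartment_sign_late", "biases"):
            d[k] = np.asarray(d[k])
        if d.get("loop_stage_mult") is not None:
            d["loop_stage_mult"] = np.asarray(d["loop_stage_mult"])
        d["cluster_of_gene"] = {k: int(v) for k, v in d["cluster_of_gene"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, stream])


def _tad_aligned_blocks(
    tads: list[tuple[int, int]], n: int, mean_bins: float, rng
) -> np.ndarray:
    """Alternating-sign blocks whose edges coincide with TAD boundaries."""
    sign = np.empty(n, dtype=int)
    s = rng.choice([-1, 1])
    acc = 0
    target = max(2, rng.geometric(1.0 / mean_bins))
    for (st, en) in tads:
        sign[st:en] = s
        acc += en - st
        if acc >= target:
            s = -s
            acc = 0
            target = max(2, rng.geometric(1.0 / mean_bins))
    return sign


def _tad_segments(n: int, lo: int, hi: int, rng) -> list[tuple[int, int]]:
    tads = []
    pos = 0
    while pos < n:
        ln = int(rng.integers(lo, hi + 1))
        end = min(n, pos + ln)
        if n - end < lo:  # absorb the stub into the last domain
            end = n
        tads.append((pos, end))
        pos = end
    return tads


def plan_layout(spec: SyntheticSpec) -> GroundTruth:
    """Plant compartments, TADs, loops, SE/TE loci, genes, and SNP wiring."""
    spec.validate()
    rng = _rng(spec, 1)
    n = spec.n_bins
    res = spec.resolution
    tads = _tad_segments(n, spec.tad_min_bp // res, spec.tad_max_bp // res, rng)
    boundaries = [e for _, e in tads[:-1]]
    # compartment blocks are unions of consecutive TADs: compartment
    # transitions fall on domain boundaries, as in real chromatin
    sign = _tad_aligned_blocks(tads, n, spec.compartment_block_mean_bp / res, rng)

    # developmental switch: flip a fraction of compartment blocks, and
    # guarantee at least one switch in each direction so the planted
    # feature always exists
    late = sign.copy()
    block_starts = [0] + list(np.flatnonzero(np.diff(sign)) + 1)
    bounds = block_starts + [n]
    flip = rng.random(len(block_starts)) < spec.switch_frac
    if spec.switch_frac > 0:
        for want in (-1, 1):  # -1: a B block flips to A, +1: A flips to B
            blocks = [
                k for k, st in enumerate(block_starts) if sign[st] == want
            ]
            if blocks and not any(flip[k] for k in blocks):
                sizes = [bounds[k + 1] - block_starts[k] for k in blocks]
                flip[blocks[int(np.argmax(sizes))]] = True
    for k, st in enumerate(block_starts):
        if flip[k]:
            late[st : bounds[k + 1]] *= -1

    # SE loci first: in A bins, mutually separated so each planted cluster
    # stitches into its own region
    a_bins = np.flatnonzero(sign > 0)
    cluster_span = max(1, -(-60_000 // res))  # bins an H3K27ac cluster may cover
    min_sep = max(10, 2 * cluster_span)
    se_bins: list[int] = []
    for b in rng.permutation(a_bins):
        if len(se_bins) == spec.n_se:
            break
        if all(abs(int(b) - s) >= min_sep for s in se_bins):
            se_bins.append(int(b))
    se_bins = np.asarray(sorted(se_bins))

    # gene bins: A-biased density, kept out of SE cluster footprints so a
    # TSS-exclusion zone cannot dismember a planted enhancer cluster
    rate = np.where(sign > 0, spec.gene_density_contrast, 1.0)
    for s in se_bins:
        rate[s : s + cluster_span + 1] = 0.0
    gene_bins = rng.choice(n, size=spec.n_genes, p=rate / rate.sum())

    te_pool = np.setdiff1d(np.arange(n), se_bins)
    te_bins = rng.choice(te_pool, size=min(spec.te_count, te_pool.size), replace=False)

    genes = [
        {
            "gene_id": f"G{k:04d}",
            "bin": int(b),
            "tss": int(b * res + rng.integers(0, min(res, spec.length - b * res))),
            "strand": "+" if rng.random() < 0.5 else "-",
            "drivers": {"loop": 0.0, "se": False, "te": False},
        }
        for k, b in enumerate(gene_bins)
    ]

    # loops: plain intra-TAD loops + SE->gene + SE-SE + SNP->gene
    lo_d = max(2, spec.loop_min_dist_bp // res)
    hi_d = max(lo_d + 1, spec.loop_max_dist_bp // res)
    loops: list[dict] = []
    used: set[tuple[int, int]] = set()

    def try_add(i: int, j: int, fold: float, kind: str) -> bool:
        i, j = int(min(i, j)), int(max(i, j))
        if j - i < 2 or (i, j) in used or not (0 <= i < n and 0 <= j < n):
            return False
        # keep planted loops separated by more than a caller neighborhood
        # (default window 5 plus shoulders) so recovery scoring is
        # unambiguous and planted peaks do not share local backgrounds
        for (pi, pj) in used:
            if abs(pi - i) <= 8 and abs(pj - j) <= 8:
                return False
        used.add((i, j))
        loops.append({"i": i, "j": j, "fold": float(fold), "kind": kind})
        return True

    tad_of = np.empty(n, dtype=int)
    for k, (s, e) in enumerate(tads):
        tad_of[s:e] = k

    # SE->gene loops and SE-SE pairs; regulatory contacts stay intra-TAD
    se_genes = []
    for b in se_bins:
        cand = [
            g
            for g in genes
            if lo_d <= abs(g["bin"] - b) <= hi_d and tad_of[g["bin"]] == tad_of[b]
        ]
        if not cand:
            cand = [g for g in genes if lo_d <= abs(g["bin"] - b) <= hi_d]
        if cand:
            g = cand[int(rng.integers(len(cand)))]
            if try_add(b, g["bin"], spec.loop_fold, "se"):
                g["drivers"]["se"] = True
                se_genes.append(g["gene_id"])
    for k in range(len(se_bins) - 1):
        for m in range(k + 1, len(se_bins)):
            d = abs(int(se_bins[k]) - int(se_bins[m]))
            if lo_d <= d <= 3 * hi_d:
                try_add(se_bins[k], se_bins[m], spec.loop_fold, "se_se")

    # TE-linked genes (no expression boost) for the SE-vs-TE contrast
    for b in te_bins[: max(5, len(se_bins))]:
        cand = [g for g in genes if lo_d <= abs(g["bin"] - b) <= hi_d and not g["drivers"]["se"]]
        if cand:
            cand[int(rng.integers(len(cand)))]["drivers"]["te"] = True

    # SNP anchor loops: intergenic anchor bin <-> gene promoter bin
    n_linked = int(round(spec.n_index_snps * spec.snp_linked_frac))
    gene_bin_set = {g["bin"] for g in genes}
    snp_links = []
    tries = 0
    while len(snp_links) < n_linked and tries < 50 * n_linked:
        tries += 1
        g = genes[int(rng.integers(len(genes)))]
        d = int(rng.integers(lo_d, hi_d + 1)) * (1 if rng.random() < 0.5 else -1)
        b = g["bin"] + d
        if not 0 <= b < n or b in gene_bin_set:
            continue
        if tad_of[b] != tad_of[g["bin"]]:
            continue  # distal regulatory contacts stay within the domain
        if try_add(b, g["bin"], spec.snp_loop_fold, "snp"):
            snp_links.append({"anchor_bin": int(b), "gene_id": g["gene_id"]})

    # plain intra-TAD loops fill the remaining space last, so the
    # functionally wired loops (SE/SNP) always find room
    big_tads = [t for t in tads if t[1] - t[0] > lo_d + 2]
    attempts = 0
    while len([l for l in loops if l["kind"] == "plain"]) < spec.n_loops and attempts < 50 * spec.n_loops:
        attempts += 1
        if not big_tads:
            break
        s, e = big_tads[rng.integers(len(big_tads))]
        d = int(rng.integers(lo_d, min(hi_d, e - s - 1) + 1))
        i = int(rng.integers(s, e - d))
        try_add(i, i + d, spec.loop_fold, "plain")

    # loop x stage strength multipliers (monotone trends, loop-specific)
    mult = np.empty((len(loops), spec.n_stages))
    trend = np.linspace(-0.5, 0.5, spec.n_stages)
    for k in range(len(loops)):
        slope = rng.uniform(-1.0, 1.0)
        mult[k] = 1.0 + slope * trend
        g_hit = [
            g
            for g in genes
            if g["bin"] in (loops[k]["i"], loops[k]["j"])
            and loops[k]["kind"] in ("plain", "se")
        ]
        for g in g_hit:
            g["drivers"]["loop"] = float(slope)

    biases = (
        np.exp2(rng.uniform(-spec.bias_log2_halfwidth, spec.bias_log2_halfwidth, n))
        if spec.with_biases
        else np.ones(n)
    )

    # developmental expression trajectory per gene (two canonical shapes)
    clusters = {g["gene_id"]: int(rng.integers(2)) for g in genes}

    return GroundTruth(
        resolution=res,
        n_bins=n,
        compartment_sign=sign,
        compartment_sign_late=late,
        boundaries=boundaries,
        tads=tads,
        loops=loops,
        biases=biases,
        se_sites=[{"bin": int(b)} for b in se_bins],
        te_sites=[{"bin": int(b)} for b in te_bins],
        genes=genes,
        snp_links=snp_links,
        loop_stage_mult=mult,
        cluster_of_gene=clusters,
    )


# ---------------------------------------------------------------------------
# contact matrix
# ---------------------------------------------------------------------------

def intensity_matrix(spec: SyntheticSpec, truth: GroundTruth, late: bool = False) -> np.ndarray:
    """Expected (Poisson-mean) matrix implied by the planted features."""
    n = truth.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    lam = 1.0 / np.maximum(d, 0.5) ** spec.alpha
    sign = truth.compartment_sign_late if late else truth.compartment_sign
    lam *= 1.0 + spec.plaid_amplitude * np.outer(sign, sign)
    tad_id = np.empty(n, dtype=int)
    for k, (s, e) in enumerate(truth.tads):
        tad_id[s:e] = k
    lam *= np.where(np.equal.outer(tad_id, tad_id), spec.tau, 1.0)
    P = np.ones((n, n))
    for l in truth.loops:
        i, j, phi = l["i"], l["j"], l["fold"]
        i0, i1 = max(0, i - 1), min(n, i + 2)
        j0, j1 = max(0, j - 1), min(n, j + 2)
        P[i0:i1, j0:j1] = np.maximum(P[i0:i1, j0:j1], phi / 2.0)
        P[i, j] = max(P[i, j], phi)
    P = np.maximum(P, P.T)
    lam *= P
    lam *= np.outer(truth.biases, truth.biases)
    upper_mass = np.triu(lam).sum()
    lam *= spec.library_size / upper_mass
    if not np.isfinite(lam).all() or lam.max() > 1e12:
        raise ValueError("spec implies overflowing intensities")
    return lam


def generate_hic(
    spec: SyntheticSpec,
    truth: Optional[GroundTruth] = None,
    late: bool = False,
    stream: int = 2,
) -> tuple[ContactMatrix, GroundTruth]:
    """Draw a raw contact matrix around the planted intensity surface."""
    if truth is None:
        truth = plan_layout(spec)
    rng = _rng(spec, stream)
    lam = intensity_matrix(spec, truth, late=late)
    if spec.overdispersion > 0:
        shape = 1.0 / spec.overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    upper = np.triu(rng.poisson(lam)).astype(float)
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(spec.bin_table(), counts, state="raw"), truth


def generate_trans_background(
    spec: SyntheticSpec, n_bins_other: int, mean_count: float = 0.5, stream: int = 9
) -> np.ndarray:
    """Uniform inter-chromosomal background (no planted structure)."""
    rng = _rng(spec, stream)
    return rng.poisson(mean_count, size=(spec.n_bins, n_bins_other)).astype(float)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def generate_tracks(truth: GroundTruth, spec: SyntheticSpec) -> dict:
    """Materialize CTCF/H3K27ac peaks, gene models, and the gene-density
    track implied by the planted layout."""
    rng = _rng(spec, 3)
    res = spec.resolution
    bins = spec.bin_table()

    ctcf = IntervalSet()
    for b in truth.boundaries:
        mid = b * res + int(rng.integers(-res // 4, res // 4 + 1))
        mid = int(np.clip(mid, 200, spec.length - 200))
        ctcf.add(Interval(spec.chrom, mid - 150, mid + 150, "ctcf_b", 10.0))
    n_bg = rng.poisson(spec.ctcf_background_per_mb * spec.length / 1e6)
    for k in range(n_bg):
        p = int(rng.integers(200, spec.length - 200))
        ctcf.add(Interval(spec.chrom, p - 150, p + 150, f"ctcf_bg{k}", 2.0))

    def peak_cluster(center_bp: int, k: int, score_range) -> list[Interval]:
        out = []
        pos = center_bp
        for m in range(k):
            w = int(rng.integers(*spec.peak_width_bp))
            s = float(rng.uniform(*score_range))
            start = int(np.clip(pos, 0, spec.length - w - 1))
            out.append(Interval(spec.chrom, start, start + w, "h3k27ac", s))
            pos = start + w + int(rng.integers(*spec.peak_gap_bp))
        return out

    h3k27ac = IntervalSet()
    for site in truth.se_sites:
        k = int(rng.integers(spec.se_constituents[0], spec.se_constituents[1] + 1))
        peaks = peak_cluster(site["bin"] * res + res // 4, k, spec.se_peak_score)
        site["peaks"] = [(p.start, p.end, p.score) for p in peaks]
        for p in peaks:
            h3k27ac.add(p)
    for site in truth.te_sites:
        # typical-enhancer loci carry 1-4 weak peaks; the multi-peak ones
        # survive stitching and form the flat part of the ranking curve
        k = int(rng.integers(1, 5))
        peaks = peak_cluster(site["bin"] * res + res // 3, k, spec.te_peak_score)
        site["peaks"] = [(p.start, p.end, p.score) for p in peaks]
        for p in peaks:
            h3k27ac.add(p)

    fine = BinTable(spec.chrom, spec.length, 1000)
    from .io import bin_signal  # local import to avoid a cycle at module load

    h3_signal = bin_signal(h3k27ac, fine, reducer="sum", use_scores=True)

    gene_models = []
    for g in truth.genes:
        tss = g["tss"]
        glen = int(rng.integers(5_000, 100_000))
        if g["strand"] == "+":
            start, end = tss, min(spec.length, tss + glen)
        else:
            start, end = max(0, tss + 1 - glen), tss + 1
        gene_models.append(
            GeneModel(g["gene_id"], spec.chrom, start, end, g["strand"])
        )

    tss_iv = IntervalSet(
        [Interval(spec.chrom, g.tss, g.tss + 1, g.gene_id) for g in gene_models]
    )
    gene_density = bin_signal(tss_iv, bins, reducer="count")

    return {
        "ctcf": ctcf,
        "h3k27ac": h3k27ac,
        "h3k27ac_signal": h3_signal,
        "genes": gene_models,
        "gene_density": gene_density,
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(truth: GroundTruth, spec: SyntheticSpec) -> ExpressionTable:
    """FPKM table over stages (x regions) with recorded drivers.

    log2-FPKM = baseline + beta_comp*1[A] + beta_se*1[SE-linked]
              + beta_loop*(loop stage multiplier - 1) + stage trend + noise,
    with the compartment sign switching from the early to the late profile
    halfway through the stages.
    """
    rng = _rng(spec, 4)
    stages = [f"s{t}" for t in range(spec.n_stages)]
    regions = [f"R{r+1}" for r in range(spec.n_regions)]
    cols = [f"{r}_{s}" for r in regions for s in stages]
    switch_at = spec.n_stages // 2
    trend = np.linspace(-0.5, 0.5, spec.n_stages)

    base = rng.normal(3.0, 1.0, len(truth.genes))
    silent = rng.random(len(truth.genes)) < spec.silent_gene_frac
    base[silent] = rng.normal(-3.0, 0.5, silent.sum())

    log2 = np.zeros((len(truth.genes), len(cols)))
    for gi, g in enumerate(truth.genes):
        shape = truth.cluster_of_gene[g["gene_id"]]
        loop_slope = g["drivers"]["loop"]
        for ci, col in enumerate(cols):
            t = stages.index(col.split("_")[1])
            sign = (
                truth.compartment_sign_late if t >= switch_at else truth.compartment_sign
            )[g["bin"]]
            v = base[gi]
            v += spec.beta_comp * (sign > 0)
            v += spec.beta_se * g["drivers"]["se"]
            v += spec.beta_loop * loop_slope * trend[t]
            v += spec.traj_amplitude * (trend[t] if shape == 0 else -trend[t])
            log2[gi, ci] = v
    log2 += rng.normal(0.0, spec.expr_noise_sd, log2.shape)

    fpkm = pd.DataFrame(
        np.exp2(log2), index=[g["gene_id"] for g in truth.genes], columns=cols
    )
    samples = pd.DataFrame(
        {
            "stage": [c.split("_")[1] for c in cols],
            "region": [c.split("_")[0] for c in cols],
        },
        index=cols,
    )
    return ExpressionTable(fpkm, samples)


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def generate_snps(truth: GroundTruth, spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Index SNPs (some looped to promoters), LD proxies, and decoys.

    Returns (snp table, LD table). Intended SNP->gene links are recorded in
    ``truth.snp_links`` as rsids.
    """
    rng = _rng(spec, 5)
    res = truth.resolution
    rows, ld_rows = [], []
    k = 0

    def new_rsid():
        nonlocal k
        k += 1
        return f"rs{100000 + k}"

    for link in truth.snp_links:
        rsid = new_rsid()
        link["rsid"] = rsid
        pos = link["anchor_bin"] * res + int(rng.integers(res // 4, 3 * res // 4))
        logp = rng.uniform(8, 12)
        rows.append((rsid, spec.chrom, pos, 10.0 ** -logp, "traitA", "index"))
        for _ in range(int(rng.integers(0, 3))):
            off = int(rng.integers(-spec.ld_window_bp, spec.ld_window_bp))
            r2 = float(rng.uniform(0.5, 1.0))
            ld_rows.append((rsid, new_rsid(), spec.chrom, max(1, pos + off), r2))

    n_unlinked = spec.n_index_snps - len(truth.snp_links)
    for _ in range(max(0, n_unlinked)):
        pos = int(rng.integers(0, spec.length))
        logp = rng.uniform(6.5, 10)
        rows.append((new_rsid(), spec.chrom, pos, 10.0 ** -logp, "traitA", "index"))
    for _ in range(spec.n_nonsig_snps):
        pos = int(rng.integers(0, spec.length))
        logp = rng.uniform(3, 5.9)
        rows.append((new_rsid(), spec.chrom, pos, 10.0 ** -logp, "traitA", "index"))
    # duplicate-position record to exercise the dedupe rule
    if rows:
        r0 = rows[0]
        rows.append((new_rsid(), r0[1], r0[2], r0[3] * 10, r0[4], "index"))

    snps = pd.DataFrame(
        rows, columns=["rsid", "chrom", "pos", "pvalue", "trait", "provenance"]
    )
    ld = pd.DataFrame(
        ld_rows, columns=["index_rsid", "proxy_rsid", "chrom", "pos", "r2"]
    )
    return snps, ld
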