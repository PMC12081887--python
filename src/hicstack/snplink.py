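"""GWAS SNP ingestion, LD expansion, and interaction-based gene assignment.

Index SNPs pass an association threshold (default p < 1e-6), are expanded
with externally supplied LD proxies at r^2 >= 0.8, and deduplicated by
genomic position (smallest association p wins). A SNP links to a gene
when the SNP's 10-kb bin has a significant chromatin interaction with the
gene's promoter bin in a sample; a SNP sharing its bin with the promoter
is never linked through the diagonal.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import BinTable, GeneModel, SignalTrack

SNP_COLUMNS = ["rsid", "chrom", "pos", "pvalue", "trait", "provenance"]


def load_and_filter_snps(table: pd.DataFrame, p_threshold: float = 1e-6) -> pd.DataFrame:
    """Keep rows with association p <= threshold; collapse duplicate
    positions to the record with the smallest p."""
    df = table.copy()
    if "provenance" not in df.columns:
        df["provenance"] = "index"
    df = df[df["pvalue"] <= p_threshold]
    return dedupe_by_position(df)


def dedupe_by_position(df: pd.DataFrame) -> pd.DataFrame:
    return (
        df.sort_values(["pvalue", "rsid"])
        .drop_duplicates(subset=["chrom", "pos"], keep="first")
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )


def expand_ld(
    index_snps: pd.DataFrame, ld_table: pd.DataFrame, r2_min: float = 0.8
) -> pd.DataFrame:
    """Append LD proxies with r^2 >= r2_min for present index SNPs, then
    position-dedupe the union (the LD table is an input; no external
    lookups are performed)."""
    keep = ld_table[
        (ld_table["r2"] >= r2_min)
        & ld_table["index_rsid"].isin(index_snps["rsid"])
    ]
    pmap = dict(zip(index_snps["rsid"], index_snps["pvalue"]))
    tmap = dict(zip(index_snps["rsid"], index_snps["trait"]))
    proxies = pd.DataFrame(
        {
            "rsid": keep["proxy_rsid"].to_numpy(),
            "chrom": keep["chrom"].to_numpy(),
            "pos": keep["pos"].to_numpy(),
            "pvalue": [pmap[r] for r in keep["index_rsid"]],
            "trait": [tmap[r] for r in keep["index_rsid"]],
            "provenance": "LD-proxy",
        }
    )
    merged = pd.concat([index_snps[SNP_COLUMNS], proxies], ignore_index=True)
    # index records outrank proxies at the same position (same pvalue)
    merged["_prio"] = (merged["provenance"] != "index").astype(int)
    merged = (
        merged.sort_values(["pvalue", "_prio", "rsid"])
        .drop_duplicates(subset=["chrom", "pos"], keep="first")
        .drop(columns="_prio")
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return merged


def link_genes(
    snps: pd.DataFrame,
    interactions: pd.DataFrame,
    genes: Sequence[GeneModel],
    bins: BinTable,
    sample: str = "sample",
    min_raw: float = 5.0,
    min_oe: float = 2.0,
) -> pd.DataFrame:
    """Emit (SNP, gene) links supported by a significant interaction
    between the SNP bin and the gene promoter bin.

    Self-bin pairs (SNP and promoter in one bin) are excluded: the
    diagonal is not interaction evidence. SNPs falling in bins absent from
    the interaction universe simply yield no links. When the interaction
    table carries raw counts and O/E ratios, a supporting interaction must
    additionally rest on at least ``min_raw`` raw contacts and a
    ``min_oe``-fold enrichment over the distance expectation — a
    significance call carried by a handful of reads on favourably
    weighted bins is not linkage evidence.
    """
    sig = interactions[interactions["significant"]]
    if "raw" in sig.columns and min_raw is not None:
        sig = sig[sig["raw"].isna() | (sig["raw"] >= min_raw)]
    if "oe" in sig.columns and min_oe is not None:
        sig = sig[sig["oe"].isna() | (sig["oe"] >= min_oe)]
    pmap: dict[tuple[int, int], float] = {}
    for r in sig.itertuples():
        pmap[(int(r.bin1), int(r.bin2))] = float(r.p)
    promoter_bins: dict[int, list[GeneModel]] = {}
    for g in genes:
        if g.chrom == bins.chrom:
            promoter_bins.setdefault(g.promoter_bin(bins), []).append(g)
    rows = []
    for s in snps.itertuples():
        if s.chrom != bins.chrom or not 0 <= s.pos < bins.length:
            continue
        sb = bins.bin_index(int(s.pos))
        for pb, gs in promoter_bins.items():
            if pb == sb:
                continue  # self-bin rule
            key = (min(sb, pb), max(sb, pb))
            if key in pmap:
                for g in gs:
                    rows.append(
                        (
                            s.rsid,
                            s.trait,
                            g.gene_id,
                            sample,
                            pmap[key],
                            abs(pb - sb) * bins.resolution,
                            sb,
                            pb,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "rsid",
            "trait",
            "gene_id",
            "sample",
            "interaction_p",
            "distance",
            "snp_bin",
            "promoter_bin",
        ],
    )


def nearest_gene(
    snps: pd.DataFrame, genes: Sequence[GeneModel], chrom: str
) -> pd.DataFrame:
    """Nearest-TSS annotation, offered for comparison with interaction
    linkage (the two frequently disagree for distal variants)."""
    gs = [g for g in genes if g.chrom == chrom]
    tss = np.array([g.tss for g in gs])
    order = np.argsort(tss)
    tss_sorted = tss[order]
    rows = []
    for s in snps.itertuples():
        if s.chrom != chrom or tss_sorted.size == 0:
            continue
        k = np.searchsorted(tss_sorted, s.pos)
        best, bd = None, None
        for j in (k - 1, k):
            if 0 <= j < tss_sorted.size:
                d = abs(int(tss_sorted[j]) - int(s.pos))
                if bd is None or d < bd:
                    best, bd = gs[order[j]], d
        rows.append((s.rsid, best.gene_id, bd))
    return pd.DataFrame(rows, columns=["rsid", "gene_id", "tss_distance"])


def disorder_set_ops(links_by_trait_region: dict[tuple, pd.DataFrame]) -> dict:
    """Per-trait union of linked genes over regions, plus pairwise and
    k-way intersection / exclusive counts."""
    per_trait: dict[str, set] = {}
    for (trait, _region), df in links_by_trait_region.items():
        per_trait.setdefault(trait, set()).update(df["gene_id"])
    traits = sorted(per_trait)
    pairwise = pd.DataFrame(
        [
            [len(per_trait[a] & per_trait[b]) for b in traits]
            for a in traits
        ],
        index=traits,
        columns=traits,
    )
    kway = set.intersection(*per_trait.values()) if per_trait else set()
    exclusive = {
        t: per_trait[t] - set.union(*(per_trait[u] for u in traits if u != t))
        if len(traits) > 1
        else per_trait[t]
        for t in traits
    }
    return {
        "genes_by_trait": per_trait,
        "pairwise_overlap": pairwise,
        "kway_intersection": kway,
        "exclusive": exclusive,
    }


def snp_density(snps: pd.DataFrame, bins: BinTable) -> SignalTrack:
    """SNP count per bin; the track total equals the in-range SNP count."""
    vals = np.zeros(bins.n_bins)
    for s in snps.itertuples():
        if s.chrom == bins.chrom and 0 <= s.pos < bins.length:
            vals[bins.bin_index(int(s.pos))] += 1
    return SignalTrack(bins, vals)
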