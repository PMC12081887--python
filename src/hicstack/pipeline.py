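"""End-to-end orchestration: simulate -> normalize -> call -> score.

A single YAML-able config names the stages to run, their parameters, and
the seed. Stages execute in dependency order; outputs carry a provenance
manifest (config hash, package version, per-stage record counts) and
reruns with an identical config are byte-identical for deterministic
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from typing import Any, Optional

import numpy as np

from . import __version__
from . import compartments as comp
from . import insulation as ins
from . import interactions as ia
from . import matrix as mx
from . import simulate as sim
from . import snplink as sl
from .genome import ContactMatrix

log = logging.getLogger(__name__)

STAGE_DEPS = {
    "simulate": [],
    "normalize": ["simulate"],
    "insulation": ["normalize"],
    "compartments": ["normalize"],
    "loops": ["normalize"],
    "sigint": ["normalize"],
    "snplink": ["sigint"],
    "score": ["simulate"],
}

DEFAULT_STAGES = [
    "simulate",
    "normalize",
    "insulation",
    "compartments",
    "loops",
    "sigint",
    "snplink",
    "score",
]


class MissingStageError(RuntimeError):
    def __init__(self, stage: str, missing: str):
        super().__init__(f"stage {stage!r} requires output of absent stage {missing!r}")
        self.stage, self.missing = stage, missing


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; returns a result bundle with a
    provenance manifest."""
    stages = config.get("stages", DEFAULT_STAGES)
    seed = int(config.get("seed", 0))
    spec_kwargs = dict(config.get("simulate", {}))
    spec_kwargs.setdefault("seed", seed)
    spec = sim.SyntheticSpec(**spec_kwargs)
    results: dict[str, Any] = {}
    manifest = {
        "config_hash": config_hash(config),
        "version": __version__,
        "seed": seed,
        "stages": {},
    }

    done: set[str] = set()
    for stage in stages:
        for dep in STAGE_DEPS.get(stage, []):
            if dep not in done:
                raise MissingStageError(stage, dep)
        t0 = time.perf_counter()
        n_records = _run_stage(stage, spec, config, results)
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "records": n_records,
        }
        done.add(stage)
    results["manifest"] = manifest
    return results


def _run_stage(stage: str, spec: sim.SyntheticSpec, config: dict, r: dict) -> int:
    if stage == "simulate":
        cm, truth = sim.generate_hic(spec)
        r["raw"], r["truth"] = cm, truth
        r["tracks"] = sim.generate_tracks(truth, spec)
        r["expression"] = sim.generate_expression(truth, spec)
        r["snps"], r["ld"] = sim.generate_snps(truth, spec)
        return cm.n_bins
    if stage == "normalize":
        p = config.get("normalize", {})
        masked = mx.mask_low_coverage(r["raw"], p.get("min_quantile", 0.02))
        r["balanced"] = mx.ice_balance(
            masked, p.get("tol", 1e-5), p.get("max_iter", 200)
        )
        r["expected"] = mx.expected_by_distance(r["balanced"])
        r["oe"] = mx.observed_over_expected(r["balanced"])
        return int(r["balanced"].mask.sum())
    if stage == "insulation":
        p = config.get("insulation", {})
        prof = ins.normalize_insulation(
            ins.insulation_score(r["balanced"], p.get("window_bp", 480_000))
        )
        r["insulation"] = prof
        r["boundaries"] = ins.detect_boundaries(prof, p.get("delta", 0.1))
        r["tads"] = ins.tads_from_boundaries(
            r["boundaries"], prof, p.get("min_tad_bp", 400_000)
        )
        return len(r["boundaries"])
    if stage == "compartments":
        p = config.get("compartments", {})
        r["compartments"] = comp.call_compartments(
            r["oe"], r["tracks"]["gene_density"], corr_floor=p.get("corr_floor", 0.1)
        )
        return int((np.asarray(r["compartments"].labels) != "").sum()) if r["compartments"].labels is not None else 0
    if stage == "loops":
        p = config.get("loops", {})
        r["loops"] = ia.sweep_and_merge(
            r["balanced"],
            grid=p.get("grid", ia.DEFAULT_SWEEP),
            merge_radius=p.get("merge_radius", 1),
            min_dist=p.get("min_dist", 2),
            max_dist=p.get("max_dist", None),
        )
        return len(r["loops"])
    if stage == "sigint":
        p = config.get("sigint", {})
        bg = ia.weibull_background(
            r["balanced"],
            fit_percentile=p.get("fit_percentile", 95.0),
            min_dist=p.get("min_dist", 1),
            max_dist=p.get("max_dist", None),
        )
        r["weibull_background"] = bg
        r["sigint"] = ia.significant_interactions(
            r["balanced"],
            bg,
            alpha=p.get("alpha", 1e-4),
            min_dist=p.get("min_dist", 1),
            max_dist=p.get("max_dist", None),
            expected=r["expected"],
        )
        return int(r["sigint"]["significant"].sum())
    if stage == "snplink":
        snps = sl.expand_ld(
            sl.load_and_filter_snps(r["snps"]), r["ld"]
        )
        r["snp_links"] = sl.link_genes(
            snps, r["sigint"], r["tracks"]["genes"], r["raw"].bins
        )
        return len(r["snp_links"])
    if stage == "score":
        r["scorecard"] = score_against_truth(r, r["truth"])
        return len(r["scorecard"])
    raise ValueError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------

def _pr(called: set, truth: set, within) -> tuple[float, float]:
    if not truth:
        return float("nan"), float("nan")
    tp_r = sum(any(within(t, c) for c in called) for t in truth)
    recall = tp_r / len(truth)
    precision = (
        sum(any(within(t, c) for t in truth) for c in called) / len(called)
        if called
        else float("nan")
    )
    return precision, recall


def score_against_truth(results: dict, truth: sim.GroundTruth) -> dict:
    """Precision/recall of called features against the planted truth:
    boundaries within +/-1 bin, loops within +/-1 bin per anchor,
    compartment label agreement, and SNP-link identity."""
    card: dict[str, float] = {}
    res = truth.resolution

    if "boundaries" in results:
        called = {iv.start // res for iv in results["boundaries"]}
        p, r = _pr(called, set(truth.boundaries), lambda t, c: abs(t - c) <= 1)
        card["boundary_precision"], card["boundary_recall"] = p, r

    if "loops" in results:
        called = {(int(x.bin1), int(x.bin2)) for x in results["loops"].itertuples()}
        near = lambda t, c: abs(t[0] - c[0]) <= 1 and abs(t[1] - c[1]) <= 1
        mask = results["balanced"].mask if "balanced" in results else None
        analyzable = lambda i, j: mask is None or (mask[i] and mask[j])
        plain = {
            (l["i"], l["j"])
            for l in truth.loops
            if l["kind"] == "plain" and analyzable(l["i"], l["j"])
        }
        planted_any = truth.loop_pixels()
        # recall on the standard planted loops; precision against every
        # planted focal enrichment (SNP/SE anchors are real loops too)
        _, card["loop_recall"] = _pr(called, plain, near)
        if called:
            card["loop_precision"] = sum(
                any(near(t, c) for t in planted_any) for c in called
            ) / len(called)
        else:
            card["loop_precision"] = float("nan")

    if "compartments" in results:
        prof = results["compartments"]
        if prof.labels is not None:
            scored = np.asarray(prof.labels) != ""
            want = np.where(truth.compartment_sign > 0, "A", "B")
            if scored.any():
                card["compartment_agreement"] = float(
                    (np.asarray(prof.labels)[scored] == want[scored]).mean()
                )

    if "snp_links" in results:
        links = results["snp_links"]
        called = {(x.rsid, x.gene_id) for x in links.itertuples()}
        intended = {
            (l["rsid"], l["gene_id"]) for l in truth.snp_links if "rsid" in l
        }
        if intended:
            card["snplink_recall"] = len(called & intended) / len(intended)
        # precision counts a link as supported when a planted focal contact
        # joins the SNP bin and the promoter bin (LD proxies of an index
        # SNP legitimately inherit its contacts)
        pixels = truth.loop_pixels()
        if len(links):
            sup = 0
            for x in links.itertuples():
                a, b = sorted((int(x.snp_bin), int(x.promoter_bin)))
                if any(abs(a - i) <= 1 and abs(b - j) <= 1 for i, j in pixels):
                    sup += 1
            card["snplink_precision"] = sup / len(links)

    return card
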