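"""Super-enhancer stitching, ranking, specificity, linkage, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicstack import enhancers as enh
from hicstack import matrix as mx
from hicstack import simulate as sim
from hicstack.genome import BinTable, GeneModel, Interval, IntervalSet, SignalTrack

from conftest import as_balanced


def peaks_at(positions, width=1000, score=5.0):
    return IntervalSet(
        [Interval("chrS", p, p + width, score=score) for p in positions]
    )


def stitch_oracle(peaks, gap):
    """Union-find over the interval graph: order-independent fixed point."""
    ivs = sorted((p.start, p.end) for p in peaks)
    parent = list(range(len(ivs)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(len(ivs)):
        for b in range(a + 1, len(ivs)):
            if ivs[b][0] - ivs[a][1] <= gap and ivs[a][0] - ivs[b][1] <= gap:
                parent[find(a)] = find(b)
    groups = {}
    for k in range(len(ivs)):
        groups.setdefault(find(k), []).append(ivs[k])
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g), len(g))
        for g in groups.values()
    )


class TestStitch:
    def test_close_peaks_merge_into_one_region(self):
        regions = enh.stitch(peaks_at([0, 5000, 10_000]), gap_bp=12_500)
        assert len(regions) == 1
        assert regions[0].n_constituents == 3

    def test_distant_singletons_dropped_by_constituent_filter(self):
        regions = enh.stitch(peaks_at([0, 14_000, 28_000]), gap_bp=12_500)
        assert regions == []

    def test_peak_inside_tss_zone_excluded(self):
        regions = enh.stitch(
            peaks_at([0, 5000, 10_000, 15_000]),
            gap_bp=12_500,
            tss_positions=[400],
            tss_flank_bp=2_500,
        )
        assert len(regions) == 1
        assert regions[0].n_constituents == 3  # first peak removed pre-stitch

    @given(
        st.lists(
            st.integers(min_value=0, max_value=200_000), min_size=4, max_size=25
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_interval_graph_oracle(self, starts):
        pk = peaks_at(sorted(set(starts)))
        got = enh.stitch(pk, gap_bp=12_500, min_constituents=1)
        want = stitch_oracle(pk, 12_500)
        assert [(r.start, r.end, r.n_constituents) for r in got] == want


class TestRankAndSplit:
    def _signal(self, length=100_000):
        bins = BinTable("chrS", length, 1000)
        return SignalTrack(bins, np.zeros(bins.n_bins))

    def _regions_with_signals(self, signals):
        track = self._signal(10_000 * (len(signals) + 1))
        regs = []
        for k, s in enumerate(signals):
            start = k * 10_000
            regs.append(enh.StitchedRegion("chrS", start, start + 3000, 3))
            track.values[start // 1000 : (start + 3000) // 1000] = s / 3.0
        return regs, track

    def test_single_outlier_is_the_only_se(self):
        regs, track = self._regions_with_signals([1, 1, 1, 1, 10])
        out = enh.rank_and_split(regs, track)
        classes = sorted(r.klass for r in out)
        assert classes.count("SE") == 1
        top = max(out, key=lambda r: r.signal)
        assert top.klass == "SE"

    def test_flat_curve_gives_no_se(self):
        regs, track = self._regions_with_signals([3, 3, 3, 3, 3])
        out = enh.rank_and_split(regs, track)
        assert all(r.klass == "TE" for r in out)

    def test_geometric_signals_match_slope_scan_oracle(self):
        signals = [2.0**k for k in range(20)]
        regs, track = self._regions_with_signals(signals)
        out = enh.rank_and_split(regs, track)
        sig = np.sort([r.signal for r in out])
        # oracle: first rank where the rescaled discrete slope exceeds 1
        y = (sig - sig.min()) / np.ptp(sig)
        x = np.arange(len(sig)) / (len(sig) - 1)
        slopes = np.diff(y) / np.diff(x)
        cut_rank = int(np.argmax(slopes > 1.0))
        n_se_oracle = int((sig > sig[cut_rank]).sum())
        assert sum(r.klass == "SE" for r in out) == n_se_oracle

    def test_ranking_consistency_every_se_above_every_te(self):
        rng = np.random.default_rng(0)
        regs, track = self._regions_with_signals(
            list(rng.gamma(1.0, 2.0, 30) + 0.1)
        )
        out = enh.rank_and_split(regs, track)
        se = [r.signal for r in out if r.klass == "SE"]
        te = [r.signal for r in out if r.klass == "TE"]
        if se and te:
            assert min(se) >= max(te)


class TestSpecificity:
    def _r(self, start, end):
        return enh.StitchedRegion("chrS", start, end, 3)

    def test_unique_se_is_specific(self):
        out = enh.se_specificity({"a": [self._r(0, 10_000)], "b": []})
        assert out["a"] == [True]

    def test_identical_se_everywhere_is_shared(self):
        out = enh.se_specificity(
            {"a": [self._r(0, 10_000)], "b": [self._r(0, 10_000)]}
        )
        assert out["a"] == [False]

    def test_quarter_overlap_below_threshold_is_specific(self):
        # reciprocal overlap 25% < 0.3
        out = enh.se_specificity(
            {"a": [self._r(0, 10_000)], "b": [self._r(7_500, 17_500)]},
            min_overlap_frac=0.3,
        )
        assert out["a"] == [True]


class TestLinkage:
    def test_planted_se_gene_link_recovered(self, loop_dataset):
        spec = loop_dataset["spec"]
        truth = loop_dataset["truth"]
        bal = loop_dataset["balanced"]
        tracks = loop_dataset["tracks"]
        from hicstack import interactions as ia

        regions = enh.rank_and_split(
            enh.stitch(
                tracks["h3k27ac"],
                tss_positions=[g.tss for g in tracks["genes"]],
            ),
            tracks["h3k27ac_signal"],
        )
        bg = ia.weibull_background(bal, max_dist=150)
        calls = ia.significant_interactions(bal, bg, max_dist=150)
        # classification noise is not under test here: offer every stitched
        # region to the linker and score recovery of the planted pairs
        links = enh.link_regions_to_genes(
            regions, calls, tracks["genes"], spec.bin_table()
        )
        linked = set(links["gene_id"])
        intended = {
            g["gene_id"]
            for g in truth.genes
            if g["drivers"]["se"] and bal.mask[g["bin"]]
        }
        assert intended
        assert len(intended & linked) / len(intended) >= 0.5

    def test_two_genes_in_one_promoter_bin_flagged_ambiguous(self):
        bins = BinTable("chrS", 400_000, 10_000)
        genes = [
            GeneModel("g1", "chrS", 101_000, 150_000, "+"),
            GeneModel("g2", "chrS", 102_000, 160_000, "+"),
        ]
        calls = pd.DataFrame(
            {"bin1": [2], "bin2": [10], "p": [1e-6], "significant": [True]}
        )
        reg = enh.StitchedRegion("chrS", 20_000, 25_000, 3, klass="SE")
        links = enh.link_regions_to_genes([reg], calls, genes, bins)
        assert set(links["gene_id"]) == {"g1", "g2"}
        assert links["ambiguous"].all()

    def test_region_without_interactions_has_no_links(self):
        bins = BinTable("chrS", 400_000, 10_000)
        genes = [GeneModel("g1", "chrS", 101_000, 150_000, "+")]
        calls = pd.DataFrame(
            {"bin1": [], "bin2": [], "p": [], "significant": []}
        )
        reg = enh.StitchedRegion("chrS", 20_000, 25_000, 3, klass="SE")
        assert len(enh.link_regions_to_genes([reg], calls, genes, bins)) == 0


class TestExpressionContrast:
    def test_planted_boost_detected_with_pooled_genes(self):
        rng = np.random.default_rng(1)
        n = 25
        se = [f"se{k}" for k in range(n)]
        te = [f"te{k}" for k in range(n)]
        fpkm = pd.DataFrame(
            {
                "s0": np.concatenate(
                    [2.0 ** (3 + 1.5 + rng.standard_normal(n)),
                     2.0 ** (3 + rng.standard_normal(n))]
                )
            },
            index=se + te,
        )
        res = enh.se_vs_te_expression(se, te, fpkm)
        assert res["p"] < 0.05
        assert res["median_se"] > res["median_te"]

    def test_empty_class_skipped(self):
        fpkm = pd.DataFrame({"s0": [1.0]}, index=["g"])
        with pytest.warns(UserWarning):
            res = enh.se_vs_te_expression([], ["g"], fpkm)
        assert np.isnan(res["p"])


class TestInteractionEnrichment:
    def test_cis_planted_pairs_beat_trans_background(self, loop_dataset):
        spec = loop_dataset["spec"]
        tracks = loop_dataset["tracks"]
        bal = loop_dataset["balanced"]
        oe = mx.observed_over_expected(bal)
        regions = enh.rank_and_split(
            enh.stitch(
                tracks["h3k27ac"],
                tss_positions=[g.tss for g in tracks["genes"]],
            ),
            tracks["h3k27ac_signal"],
        )
        ses = [r for r in regions if r.klass == "SE"]
        tes = [r for r in regions if r.klass == "TE"]
        trans = sim.generate_trans_background(spec, 400, mean_count=0.5)
        res = enh.se_interaction_enrichment(ses, tes, oe, trans_matrix=trans)
        assert res["trans_enrichment"] == pytest.approx(1.0, abs=0.15)
        assert np.mean(res["cis_se_oe"]) > 1.0

    def test_no_pairs_in_range_is_an_error(self):
        oe = as_balanced(np.ones((50, 50)))
        oe.state = "oe"
        ses = [enh.StitchedRegion("chrT", 0, 5000, 3)]
        with pytest.raises(ValueError):
            enh.se_interaction_enrichment(ses, [], oe)
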