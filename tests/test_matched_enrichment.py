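import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rloopshift import matched_enrichment as me
from rloopshift.core_io import (
    BinnedTrack,
    FeatureSet,
    Gene,
    GenomicInterval,
    ValidationError,
)
from rloopshift.peakcall_hmm import Peak


def _ap(pid, chrom="chr1", start=10_000, length=1500, strand="+",
        gene_id="g", gene_class="none", compartment="body",
        gene_length=50_000, expression=10.0, offset=0):
    p = Peak(GenomicInterval(chrom, start, start + length, strand), id=pid)
    return me.AnnotatedPeak(p, gene_id, gene_class, compartment,
                            gene_length, expression, offset)


class TestMatching:
    def test_within_tolerance_eligible(self):
        t = _ap("t", gene_id="gt", gene_class="RLG", gene_length=50_000,
                expression=10.0)
        cands = [_ap(f"c{i}", start=100_000 + 5_000 * i, gene_id=f"gc{i}",
                     gene_length=52_000, expression=11.0) for i in range(3)]
        out = me.select_matched_controls([t], cands, n_matches=3, seed=0)
        assert set(c.id for c in out.controls["t"]) == {"c0", "c1", "c2"}

    def test_affected_genes_never_selected(self):
        t = _ap("t", gene_id="gt", gene_class="RLG")
        cands = [_ap(f"c{i}", gene_id=f"gc{i}", gene_class="RLL")
                 for i in range(20)]
        out = me.select_matched_controls([t], cands, n_matches=2, seed=0)
        assert out.dropped == ["t"]

    def test_deterministic_under_seed(self):
        t = _ap("t", gene_id="gt", gene_class="RLG")
        cands = [_ap(f"c{i}", start=50_000 + i * 3000, gene_id=f"gc{i}")
                 for i in range(30)]
        a = me.select_matched_controls([t], cands, n_matches=5, seed=9)
        b = me.select_matched_controls([t], cands, n_matches=5, seed=9)
        assert [c.id for c in a.controls["t"]] == [c.id for c in b.controls["t"]]

    def test_tolerance_relaxation(self):
        t = _ap("t", gene_id="gt", gene_class="RLG", gene_length=50_000)
        # only eligible after one doubling of tol_len (ratio 1.9 ~ 0.93 log2)
        cands = [_ap(f"c{i}", gene_id=f"gc{i}", gene_length=95_000)
                 for i in range(5)]
        out = me.select_matched_controls([t], cands, n_matches=3, seed=0)
        assert len(out.controls["t"]) == 3
        assert out.tolerance_used["t"] == 2.0

    def test_promoter_control_repositioned(self):
        # target promoter peak 500 bp downstream of its TSS
        t = _ap("t", gene_id="gt", gene_class="RLG", compartment="promoter",
                start=20_500, offset=500)
        c = _ap("c", gene_id="gc", compartment="promoter",
                start=101_000, offset=1000)
        out = me.select_matched_controls([t], [c] * 10, n_matches=3, seed=0,
                                         chrom_sizes={"chr1": 1_000_000})
        ctrl = out.controls["t"][0]
        # control gene anchor is at 101000 - 1000 = 100000; repositioned
        # peak starts at anchor + target offset
        assert ctrl.interval.start == 100_500
        assert ctrl.interval.length == 1500


class TestOverlapEnrichment:
    def _matched(self, n=40, inside=True, feature_span=(0, 1_000_000)):
        targets, controls = {}, {}
        for i in range(n):
            t = _ap(f"t{i}", start=10_000 + 20_000 * i)
            targets[t.id] = t
            controls[t.id] = [_ap(f"t{i}_c{j}", chrom="chr2",
                                  start=10_000 + 20_000 * i + 997 * j)
                              for j in range(10)]
        return me.MatchedControlSet(targets, controls, {t: 1.0 for t in targets})

    def test_saturating_feature(self):
        m = self._matched()
        feat = FeatureSet("all", [GenomicInterval("chr1", 0, 10_000_000),
                                  GenomicInterval("chr2", 0, 10_000_000)])
        er = me.overlap_enrichment(m, feat, n_mc=99, seed=0)
        assert er.observed == 1.0 and er.expected == 1.0
        assert er.ratio == 1.0 and er.p_value == 1.0

    def test_planted_enrichment_p_floor(self):
        # targets always inside the feature, controls never: with
        # n_mc = 124 the one-sided p attains its floor 1/125 = 0.008
        m = self._matched()
        feat = FeatureSet("f", [GenomicInterval("chr1", 0, 1_000_000)])
        er = me.overlap_enrichment(m, feat, n_mc=124, seed=0)
        assert er.observed == 1.0 and er.expected == 0.0
        assert er.p_enrich == pytest.approx(1 / 125)
        assert er.p_enrich == pytest.approx(0.008)

    def test_empty_feature_flagged(self):
        m = self._matched()
        er = me.overlap_enrichment(m, FeatureSet("empty", []), n_mc=9, seed=0)
        assert er.flagged and np.isnan(er.ratio)

    @pytest.mark.parametrize("obs,star", [
        (0.05, ""), (0.10, "*"), (0.24, "*"), (0.30, "**"), (0.50, "**"),
        (0.51, "***"), (0.95, "***"),
    ])
    def test_star_classes(self, obs, star):
        assert me.star_class(obs) == star


class TestDistanceToNearest:
    def test_edge_gap(self):
        peaks = [Peak(GenomicInterval("chr1", 100, 200), id="p")]
        feat = FeatureSet("f", [GenomicInterval("chr1", 300, 400)])
        assert me.distance_to_nearest(peaks, feat)[0] == 100

    def test_overlap_zero(self):
        peaks = [Peak(GenomicInterval("chr1", 100, 200), id="p")]
        feat = FeatureSet("f", [GenomicInterval("chr1", 150, 400)])
        assert me.distance_to_nearest(peaks, feat)[0] == 0

    def test_missing_chromosome_inf(self):
        peaks = [Peak(GenomicInterval("chr9", 100, 200), id="p")]
        feat = FeatureSet("f", [GenomicInterval("chr1", 0, 10)])
        assert np.isinf(me.distance_to_nearest(peaks, feat)[0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = [Peak(GenomicInterval("chr1", int(s), int(s) + int(w)), id=str(i))
                 for i, (s, w) in enumerate(zip(rng.integers(0, 100_000, 5),
                                                rng.integers(1, 5000, 5)))]
        feat_ivs = [GenomicInterval("chr1", int(s), int(s) + int(w))
                    for s, w in zip(rng.integers(0, 100_000, 8),
                                    rng.integers(1, 8000, 8))]
        feat = FeatureSet("f", feat_ivs)
        got = me.distance_to_nearest(peaks, feat)
        for i, p in enumerate(peaks):
            brute = min(
                0 if (iv.start < p.end and p.start < iv.end)
                else (iv.start - p.end if iv.start >= p.end else p.start - iv.end)
                for iv in feat_ivs)
            assert got[i] == brute


class TestCompareDistanceSets:
    def test_exact_enumeration_example(self):
        # all of b above all of a: two-sided exact p = 2/C(6,3) = 0.1
        _, _, p = me.compare_distance_sets([1, 2, 3], [10, 20, 30])
        assert p == pytest.approx(0.1)

    def test_exact_matches_full_enumeration(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 4)
        b = rng.uniform(0, 1, 5)
        _, _, p = me.compare_distance_sets(a, b)
        # enumeration oracle over all C(9,4) group assignments
        pooled = np.concatenate([a, b])
        def ustat(idx_a):
            aa = pooled[list(idx_a)]
            bb = np.delete(pooled, list(idx_a))
            return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
        obs = ustat(range(4))
        n_more = 0
        total = 0
        m = len(pooled)
        null_mean = 4 * 5 / 2
        for comb in itertools.combinations(range(m), 4):
            u = ustat(comb)
            if abs(u - null_mean) >= abs(obs - null_mean) - 1e-12:
                n_more += 1
            total += 1
        assert p == pytest.approx(n_more / total)

    def test_symmetry(self):
        a, b = [1.0, 5.0, 9.0], [2.0, 3.0, 50.0, 60.0]
        _, _, p1 = me.compare_distance_sets(a, b)
        _, _, p2 = me.compare_distance_sets(b, a)
        assert p1 == pytest.approx(p2)

    def test_identical_large_samples(self):
        a = np.arange(100.0)
        _, _, p = me.compare_distance_sets(a, a)
        assert p > 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            me.compare_distance_sets([], [1.0])


class TestFoldChangeBins:
    def test_equal_occupancy(self):
        ids = [f"p{i}" for i in range(100)]
        lfc = np.linspace(-2, 2, 100)
        bins, r, p = me.foldchange_bins(ids, lfc, lfc, n_bins=10)
        assert all(len(b.peak_ids) == 10 for b in bins)

    def test_identity_covariate_r1(self):
        ids = [f"p{i}" for i in range(60)]
        lfc = np.linspace(-1, 1, 60)
        _, r, _ = me.foldchange_bins(ids, lfc, lfc, n_bins=6)
        assert r == pytest.approx(1.0)

    def test_occupancy_differs_at_most_one(self):
        ids = [f"p{i}" for i in range(103)]
        rng = np.random.default_rng(0)
        lfc = rng.normal(size=103)
        bins, _, _ = me.foldchange_bins(ids, lfc, rng.normal(size=103), n_bins=10)
        sizes = [len(b.peak_ids) for b in bins]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 103

    def test_constant_lfc_degenerate(self):
        with pytest.raises(ValidationError):
            me.foldchange_bins(list("abcdefghij"), np.ones(10),
                               np.arange(10), n_bins=2)


def _phase_tracks(values_by_phase, n_bins=100, bin_width=100):
    out = {}
    for ph, v in values_by_phase.items():
        vals = np.full(n_bins, float(v))
        out[ph] = {"chr1": BinnedTrack(chrom="chr1", bin_width=bin_width,
                                       strand=".", values=vals,
                                       chrom_length=n_bins * bin_width)}
    return out


class TestRepliseqPhase:
    def test_single_phase_signal(self):
        tracks = _phase_tracks({ph: 0 for ph in me.REPLI_PHASES} | {"G1b": 5})
        peaks = [Peak(GenomicInterval("chr1", 100, 300), id="p")]
        calls, n_un = me.repliseq_phase_assignment(peaks, tracks)
        assert calls["p"] == "G1b" and n_un == 0

    def test_tie_breaks_earlier_phase(self):
        tracks = _phase_tracks(
            {ph: 0 for ph in me.REPLI_PHASES} | {"S1": 3, "S3": 3})
        peaks = [Peak(GenomicInterval("chr1", 100, 300), id="p")]
        calls, _ = me.repliseq_phase_assignment(peaks, tracks)
        assert calls["p"] == "S1"

    def test_all_zero_unassigned(self):
        tracks = _phase_tracks({ph: 0 for ph in me.REPLI_PHASES})
        peaks = [Peak(GenomicInterval("chr1", 100, 300), id="p")]
        calls, n_un = me.repliseq_phase_assignment(peaks, tracks)
        assert calls["p"] is None and n_un == 1
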