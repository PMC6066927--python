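import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rloopshift import diff_rloop as dr
from rloopshift.core_io import BinnedTrack, Gene, GenomicInterval, ValidationError
from rloopshift.peakcall_hmm import Peak

COND = {"c1": "control", "c2": "control", "d1": "depleted", "d2": "depleted"}


def _cm(rows, columns=("c1", "c2", "d1", "d2")):
    df = pd.DataFrame(rows, columns=list(columns))
    df.index = [f"p{i}" for i in range(len(df))]
    return dr.CountMatrix(df, {c: COND[c] for c in columns})


def _null_cm(n=2000, mean=100.0, alpha=0.05, seed=0, sf=(1.0, 1.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(mean), 1.0, n)
    r = 1 / alpha
    m = mu[:, None] * np.asarray(sf)[None, :]
    k = rng.negative_binomial(r, r / (r + m))
    return _cm(k)


class TestCountInPeaks:
    def _tracks(self, values):
        tr = BinnedTrack(chrom="chr1", bin_width=100, strand="+",
                         values=np.asarray(values, dtype=float),
                         chrom_length=100 * len(values))
        return {"s1": {("chr1", "+"): tr}}

    def test_summation(self):
        peaks = [Peak(GenomicInterval("chr1", 0, 300, "+"), id="p0")]
        cm = dr.count_in_peaks(peaks, self._tracks([3, 4, 5, 9]), {"s1": "control"})
        assert cm.counts.loc["p0", "s1"] == 12

    def test_empty_peaks(self):
        cm = dr.count_in_peaks([], self._tracks([1, 2]), {"s1": "control"})
        assert cm.counts.empty

    def test_linearity(self):
        peaks = [Peak(GenomicInterval("chr1", 0, 400, "+"), id="p0")]
        a = dr.count_in_peaks(peaks, self._tracks([1, 2, 3, 4]), {"s1": "control"})
        b = dr.count_in_peaks(peaks, self._tracks([2, 4, 6, 8]), {"s1": "control"})
        assert (b.counts.values == 2 * a.counts.values).all()

    def test_out_of_bounds(self):
        peaks = [Peak(GenomicInterval("chr1", 0, 900, "+"), id="p0")]
        with pytest.raises(ValidationError):
            dr.count_in_peaks(peaks, self._tracks([1, 2]), {"s1": "control"})

    def test_masked_bins_excluded(self):
        tracks = self._tracks([3, 4, 5, 9])
        tracks["s1"][("chr1", "+")].mask[1] = True
        peaks = [Peak(GenomicInterval("chr1", 0, 300, "+"), id="p0")]
        cm = dr.count_in_peaks(peaks, tracks, {"s1": "control"})
        assert cm.counts.loc["p0", "s1"] == 8


class TestSizeFactors:
    def test_hand_example(self):
        # [[10, 20], [100, 200]] -> (1/sqrt(2), sqrt(2))
        df = pd.DataFrame([[10, 20], [100, 200]], columns=["a", "b"])
        sf = dr.size_factors(df)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_identical_columns(self):
        df = pd.DataFrame([[5, 5], [80, 80], [13, 13]], columns=["a", "b"])
        assert np.allclose(dr.size_factors(df).values, 1.0)

    @given(st.integers(0, 1000), st.floats(0.25, 4.0))
    @settings(max_examples=30, deadline=None)
    def test_column_scaling_scales_factor_ratio(self, seed, c):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 500, size=(50, 3)).astype(float)
        base = dr.size_factors(pd.DataFrame(k, columns=list("abc")))
        k2 = k.copy()
        k2[:, 1] = np.round(k[:, 1] * c)
        scaled = dr.size_factors(pd.DataFrame(k2, columns=list("abc")))
        # ratios between column factors scale with c (up to rounding noise)
        assert scaled["b"] / scaled["a"] == pytest.approx(
            c * base["b"] / base["a"], rel=0.05)


class TestDispersion:
    def test_poisson_rows_small_alpha(self):
        cm = _null_cm(n=4000, mean=200, alpha=1e-9, seed=1)
        sf = dr.size_factors(cm)
        disp = dr.estimate_dispersion(cm, sf)
        assert np.median(disp) <= 0.01

    def test_nb_alpha_recovery(self):
        cm = _null_cm(n=4000, mean=500, alpha=0.2, seed=2)
        sf = dr.size_factors(cm)
        disp = dr.estimate_dispersion(cm, sf)
        assert 0.1 <= np.median(disp) <= 0.4

    def test_constant_rows_zero_mom(self):
        df = pd.DataFrame(np.full((10, 4), 7), columns=list(COND))
        cm = dr.CountMatrix(df, COND)
        sf = pd.Series(np.ones(4), index=df.columns)
        disp = dr.estimate_dispersion(cm, sf, trend_weight=0.0)
        # alpha_hat = 0 for constant rows; with zero trend weight the floor
        # is half the (tiny) trend
        assert (disp <= 1e-2).all()

    def test_single_replicate_rejected(self):
        df = pd.DataFrame([[1, 2], [3, 4]], columns=["c1", "d1"])
        cm = dr.CountMatrix(df, {"c1": "control", "d1": "depleted"})
        with pytest.raises(ValidationError):
            dr.estimate_dispersion(cm, pd.Series([1.0, 1.0], index=df.columns))


class TestNbWaldTest:
    def test_symmetric_counts_zero_lfc(self):
        cm = _cm([[50, 50, 50, 50], [200, 200, 200, 200]])
        sf = pd.Series(np.ones(4), index=cm.counts.columns)
        disp = pd.Series([1e-8, 1e-8], index=cm.counts.index)
        res = dr.nb_wald_test(cm, sf, disp)
        assert np.allclose(res["log2FoldChange"], 0.0, atol=1e-6)

    def test_planted_lfc_recovery(self):
        rng = np.random.default_rng(3)
        n = 2000
        mu = np.full(n, 500.0)
        alpha = 0.02
        r = 1 / alpha
        ctrl = rng.negative_binomial(r, r / (r + mu), size=(2, n)).T
        depl = rng.negative_binomial(r, r / (r + 2 * mu), size=(2, n)).T
        cm = _cm(np.hstack([ctrl, depl]))
        sf = pd.Series(np.ones(4), index=cm.counts.columns)
        disp = dr.estimate_dispersion(cm, sf)
        res = dr.nb_wald_test(cm, sf, disp)
        assert res["log2FoldChange"].mean() == pytest.approx(1.0, abs=0.1)

    def test_null_calibration_small(self):
        cm = _null_cm(n=4000, alpha=0.05, seed=4, sf=(1.0, 1.1, 0.9, 1.05))
        sf = dr.size_factors(cm)
        disp = dr.estimate_dispersion(cm, sf)
        res = dr.nb_wald_test(cm, sf, disp)
        frac = np.mean(res["pvalue"].values < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_all_zero_row_is_nan(self):
        cm = _cm([[0, 0, 0, 0], [10, 10, 10, 10]])
        sf = pd.Series(np.ones(4), index=cm.counts.columns)
        disp = pd.Series([0.1, 0.1], index=cm.counts.index)
        res = dr.nb_wald_test(cm, sf, disp)
        assert np.isnan(res["pvalue"].iloc[0])
        assert np.isfinite(res["pvalue"].iloc[1])


class TestBhAdjust:
    def test_hand_example(self):
        # p*m/rank then cumulative minimum from the right
        out = dr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert dr.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_nan_excluded_from_m(self):
        out = dr.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.01 * 2 / 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            dr.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.integers(0, 10**6))
    @settings(max_examples=100, deadline=None)
    def test_properties_and_reference(self, ps, _):
        ps = np.asarray(ps)
        out = dr.bh_adjust(ps)
        assert (out >= ps - 1e-12).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()
        from statsmodels.stats.multitest import multipletests
        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(out, ref)


class TestCalls:
    @pytest.mark.parametrize("padj,fc,expected", [
        (0.05, 1.30, "gain"),
        (0.05, 0.70, "loss"),
        (0.20, 3.00, "nochange"),
        (0.05, 1.25, "nochange"),   # strict inequality
        (0.05, 0.80, "nochange"),
    ])
    def test_thresholds(self, padj, fc, expected):
        res = pd.DataFrame({"log2FoldChange": [np.log2(fc)],
                            "pvalue": [padj], "padj": [padj]})
        out = dr.call_diff_peaks(res)
        assert out["call"].iloc[0] == expected


class TestClassifyGenes:
    def _gene(self, gid="g1", start=0, end=10_000, strand="+"):
        return Gene(gid, GenomicInterval("chr1", start, end, strand))

    def _setup(self, n_gain, n_loss, gene_length=10_000):
        gene = self._gene(end=gene_length)
        peaks, calls = [], {}
        pos = 100
        for i in range(n_gain + n_loss):
            pid = f"p{i}"
            peaks.append(Peak(GenomicInterval("chr1", pos, pos + 200, "+"), id=pid))
            calls[pid] = "gain" if i < n_gain else "loss"
            pos += 300
        diff = pd.DataFrame({"call": pd.Series(calls)})
        return diff, peaks, [gene]

    @pytest.mark.parametrize("n_gain,n_loss,expected", [
        (6, 1, "RLG"), (5, 1, "RLG"), (4, 1, "mixed"), (1, 6, "RLL"),
        (1, 0, "RLG"), (0, 1, "RLL"), (0, 0, "none"), (3, 3, "mixed"),
    ])
    def test_five_to_one_rule(self, n_gain, n_loss, expected):
        diff, peaks, genes = self._setup(n_gain, n_loss)
        out = dr.classify_genes(diff, peaks, genes)
        assert out[0].rl_class == expected
        assert (out[0].n_gain, out[0].n_loss) == (n_gain, n_loss)

    def test_short_gene_excluded(self):
        diff, peaks, _ = self._setup(6, 0)
        genes = [self._gene(end=4000)]
        assert dr.classify_genes(diff, peaks, genes) == []

    def test_strand_mismatch_not_assigned(self):
        diff, peaks, _ = self._setup(6, 0)
        genes = [self._gene(strand="-")]
        out = dr.classify_genes(diff, peaks, genes)
        assert out[0].rl_class == "none"


class TestRnaseqDe:
    def test_thresholds(self):
        rng = np.random.default_rng(7)
        n = 300
        mu = np.full(n, 800.0)
        r = 1 / 0.01
        data = np.empty((n, 4))
        data[:, :2] = rng.negative_binomial(r, r / (r + mu), size=(2, n)).T
        eff = np.ones(n)
        eff[:50] = 2.0     # clearly up
        eff[50:100] = 1.3  # below the 1.5x gate
        data[:, 2:] = rng.negative_binomial(r, r / (r + mu * eff), size=(2, n)).T
        cm = _cm(data.astype(int))
        res = dr.rnaseq_de(cm)
        assert (res["call"].iloc[:50] == "up").mean() > 0.9
        assert (res["call"].iloc[50:100] == "up").mean() < 0.5
        assert (res["call"].iloc[100:] == "nochange").mean() > 0.95


class TestChromosomeRatio:
    def _classes(self, spec):
        out, genes = [], []
        i = 0
        for chrom, (n_rlg, n_rll, n_other) in spec.items():
            for k in range(n_rlg + n_rll + n_other):
                gid = f"g{i}"
                i += 1
                cls = "RLG" if k < n_rlg else ("RLL" if k < n_rlg + n_rll else "none")
                out.append(dr.GeneRLClass(gid, 0, 0, cls))
                genes.append(Gene(gid, GenomicInterval(chrom, 1000 * k + 1,
                                                       1000 * k + 900, "+")))
        return out, genes

    def test_direction(self):
        spec = {"chr1": (2, 20, 60), "chr2": (5, 10, 30), "chr3": (10, 5, 10),
                "chr4": (20, 2, 5)}
        classes, genes = self._classes(spec)
        sizes = {c: 1_000_000 for c in spec}
        df = dr.chromosome_gain_loss_ratio(classes, genes, sizes)
        assert df.attrs["pearson_r"] < 0

    def test_too_few_chromosomes(self):
        classes, genes = self._classes({"chr1": (2, 5, 10), "chr2": (2, 5, 10)})
        with pytest.raises(ValidationError):
            dr.chromosome_gain_loss_ratio(classes, genes,
                                          {"chr1": 1_000_000, "chr2": 1_000_000})

    def test_zero_variance_flagged(self):
        classes, genes = self._classes(
            {"chr1": (2, 2, 10), "chr2": (2, 2, 10), "chr3": (2, 2, 10)})
        with pytest.raises(ValidationError):
            dr.chromosome_gain_loss_ratio(
                classes, genes, {c: 1_000_000 for c in ("chr1", "chr2", "chr3")})
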