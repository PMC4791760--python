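import numpy as np
import pytest

from dsdseq import gcnorm
from dsdseq.cnv import (
    CopyStatePath,
    NBParams,
    batch_calibrate,
    call_cnvs,
    fit_nb,
    hmm_copy_number,
    sample_qc,
    segment_cnv,
)
from dsdseq.regions import GenomicInterval, Window, window_span
from dsdseq.simulate import SimConfig, simulate_depth

from .oracles import enumerate_best_path, enumerate_best_score


def _contiguous_windows(n, chrom="chr1", start=0):
    return [
        Window(GenomicInterval(chrom, start + i * 25, start + i * 25 + 30), gc=0.5)
        for i in range(n)
    ]


def _nb(n, mean=300.0, size=30.0):
    return [NBParams(mean=mean, size=size) for _ in range(n)]


class TestSampleQC:
    def test_clean_sample_passes(self, clean_batch):
        dm, _ = clean_batch
        qc = sample_qc(dm, dm.samples[0])
        assert qc.passed
        assert qc.mean_corr > 0.6

    def test_permuted_sample_fails_mean_correlation(self, clean_batch):
        dm, _ = clean_batch
        rng = np.random.default_rng(0)
        corrupted = gcnorm.DepthMatrix(samples=dm.samples, windows=dm.windows, raw=dm.raw.copy())
        corrupted.corrected = dm.corrected.copy()
        corrupted.low_confidence = dm.low_confidence
        # permute every chromosome's windows for sample 0
        chroms = dm.chroms
        for chrom in dict.fromkeys(chroms):
            idx = np.flatnonzero(chroms == chrom)
            corrupted.corrected[0, idx] = corrupted.corrected[0, rng.permutation(idx)]
        qc = sample_qc(corrupted, dm.samples[0])
        assert not qc.passed
        assert "mean correlation" in qc.reason

    def test_five_degraded_chromosomes_fail_count_rule(self):
        # sample 0 keeps a decent overall mean correlation but five of the
        # eight chromosomes fall below 4/5 of the other samples' level
        rng = np.random.default_rng(1)
        chrom_names = [f"chr{i}" for i in range(1, 7)] + ["chrX", "chrY"]
        per_chrom = 60
        windows, cols = [], []
        profiles = {c: rng.normal(300.0, 80.0, per_chrom).clip(20) for c in chrom_names}
        for c in chrom_names:
            for i in range(per_chrom):
                windows.append(Window(GenomicInterval(c, i * 25, i * 25 + 30), gc=0.5))
        n_samples = 8
        mat = np.empty((n_samples, len(windows)))
        for si in range(n_samples):
            parts = []
            for c in chrom_names:
                shared = profiles[c]
                degraded = si == 0 and c in chrom_names[:5]
                indep = rng.normal(0.0, 80.0, per_chrom) if degraded else 0.0
                parts.append(shared + indep + rng.normal(0.0, 25.0, per_chrom))
            mat[si] = np.concatenate(parts).clip(1)
        dm = gcnorm.DepthMatrix(samples=[f"s{i}" for i in range(n_samples)],
                                windows=windows, raw=mat)
        dm.corrected = mat.copy()
        qc = sample_qc(dm, "s0")
        assert qc.mean_corr >= 0.6  # the mean rule alone would pass
        assert not qc.passed
        assert "more than four chromosomes" in qc.reason

    def test_tiny_batch_skips_with_warning(self, clean_batch):
        dm, _ = clean_batch
        small = gcnorm.DepthMatrix(samples=dm.samples[:2], windows=dm.windows, raw=dm.raw[:2])
        small.corrected = dm.corrected[:2]
        qc = sample_qc(small, small.samples[0])
        assert qc.passed
        assert "skipped" in qc.reason


class TestFitNB:
    def test_closed_form_size(self):
        # m = 100, v = 300 -> size = 100^2 / (300 - 100) = 50
        a = np.sqrt(300.0)  # deviations (-a, 0, a) give ddof=1 variance 300
        counts = np.array([100.0 - a, 100.0, 100.0 + a])
        p = fit_nb(counts)
        assert p.mean == pytest.approx(100.0)
        assert p.size == pytest.approx(50.0)

    def test_underdispersed_poisson_fallback(self):
        p = fit_nb(np.array([100.0, 100.0, 100.0, 101.0]))
        assert p.poisson_fallback
        assert p.size is None

    def test_parameter_recovery(self):
        rng = np.random.default_rng(123)
        mu, size = 200.0, 20.0
        counts = rng.negative_binomial(n=size, p=size / (size + mu), size=200)
        p = fit_nb(counts)
        assert 10 <= p.size <= 40
        assert p.mean == pytest.approx(mu, rel=0.1)

    def test_uncovered_window_rejected(self):
        with pytest.raises(ValueError, match="uncovered"):
            fit_nb(np.zeros(5))


class TestBatchCalibrate:
    def test_homogeneous_batch_unit_ratios(self):
        windows = _contiguous_windows(6)
        dm = gcnorm.DepthMatrix(samples=["a", "b", "c"], windows=windows,
                                raw=np.full((3, 6), 250.0))
        dm.corrected = dm.raw.copy()
        _, ratios, masked = batch_calibrate(dm)
        assert np.allclose(ratios, 1.0)
        assert not masked.any()

    def test_three_copy_region_ratios(self, panel_and_windows):
        panel, windows = panel_and_windows
        iv = GenomicInterval("chr1", 100_000, 100_200)
        cfg = SimConfig(seed=2, karyotypes={f"B{i}": "XY" for i in range(12)},
                        panel=panel, windows=windows, cnvs=[("B0", iv, 3)])
        dm, _ = simulate_depth(cfg)
        gcnorm.correct_matrix(dm)
        _, ratios, _ = batch_calibrate(dm)
        in_cnv = np.array([
            w.interval.chrom == "chr1" and w.interval.start < iv.end and iv.start < w.interval.end
            for w in windows
        ])
        assert ratios[0, in_cnv].mean() == pytest.approx(1.5, rel=0.15)
        assert ratios[1:, in_cnv].mean() == pytest.approx(1.0, rel=0.1)

    def test_masked_windows_never_called(self):
        windows = _contiguous_windows(8)
        raw = np.full((3, 8), 300.0)
        raw[:, 4] = 0.0  # uncovered in every sample
        dm = gcnorm.DepthMatrix(samples=["a", "b", "c"], windows=windows, raw=raw)
        dm.corrected = dm.raw.copy()
        _, _, masked = batch_calibrate(dm)
        assert masked[4]
        calls = call_cnvs(dm, "a")
        assert all(c.copy_number != 0 or c.n_windows < 5 for c in calls)


class TestViterbi:
    def test_stationary_path_at_batch_mean(self):
        nb = _nb(50)
        path = hmm_copy_number(np.ones(50), 2, nb)
        assert (path.states == 2).all()

    def test_duplication_block_decoded(self):
        ratios = np.ones(40)
        ratios[20:28] = 1.5
        path = hmm_copy_number(ratios, 2, _nb(40))
        assert (path.states[20:28] == 3).all()
        assert (path.states[:20] == 2).all() and (path.states[28:] == 2).all()

    def test_homozygous_deletion_decoded(self):
        ratios = np.ones(40)
        ratios[10:30] = 0.0
        path = hmm_copy_number(ratios, 2, _nb(40))
        assert (path.states[10:30] == 0).all()

    def test_empty_input(self):
        path = hmm_copy_number(np.array([]), 2, [])
        assert len(path.states) == 0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 8))
            nb = [
                NBParams(mean=float(rng.uniform(50, 500)), size=float(rng.uniform(5, 100)))
                if rng.random() > 0.15
                else NBParams(mean=float(rng.uniform(50, 500)), size=None, poisson_fallback=True)
                for _ in range(n)
            ]
            ratios = rng.uniform(0.0, 2.5, n)
            expected = int(rng.integers(1, 3))
            stay = float(rng.uniform(0.9, 0.999))
            path = hmm_copy_number(ratios, expected, nb, stay_prob=stay)
            oracle_states, oracle_score = enumerate_best_path(ratios, expected, nb, stay)
            assert path.loglik == pytest.approx(oracle_score, abs=1e-9)
            assert np.array_equal(path.states, oracle_states)

    def test_matches_enumeration_at_ten_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            nb = _nb(10, mean=float(rng.uniform(100, 400)))
            ratios = rng.uniform(0.0, 2.0, 10)
            path = hmm_copy_number(ratios, 2, nb, stay_prob=0.98)
            assert path.loglik == pytest.approx(
                enumerate_best_score(ratios, 2, nb, 0.98), abs=1e-9
            )


class TestSegmentCNV:
    def _path(self, states):
        return CopyStatePath(states=np.asarray(states), loglik=0.0)

    def test_run_of_four_not_called(self):
        windows = _contiguous_windows(10)
        states = [2] * 3 + [3] * 4 + [2] * 3
        assert segment_cnv(self._path(states), windows, 2) == []

    def test_run_of_five_spans_130bp(self):
        windows = _contiguous_windows(10)
        states = [2] * 2 + [3] * 5 + [2] * 3
        (call,) = segment_cnv(self._path(states), windows, 2)
        assert call.n_windows == 5
        assert call.interval.length == 130 == window_span(5)
        # outer bounds reach the flanking normal windows
        assert call.outer_start == windows[1].interval.start
        assert call.outer_end == windows[7].interval.end

    def test_gross_duplication_size(self):
        # captured targets at the edges of the duplicated region: the call's
        # window-bounded interval spans the outermost captured windows
        from dsdseq.regions import make_windows

        start, end = 30322539, 30749577
        first = GenomicInterval("chrX", start, start + 80)
        last = GenomicInterval("chrX", end - 80, end)  # length 80 tiles exactly
        windows = make_windows(first) + make_windows(last)
        states = [3] * len(windows)
        (call,) = segment_cnv(self._path(states), windows, 2)
        assert call.interval == GenomicInterval("chrX", start, end)
        assert call.interval.length == 427038

    def test_no_call_shorter_than_minimum_span(self):
        rng = np.random.default_rng(3)
        windows = _contiguous_windows(60)
        for _ in range(20):
            states = np.full(60, 2)
            i = int(rng.integers(0, 50))
            states[i : i + int(rng.integers(1, 10))] = 3
            for call in segment_cnv(self._path(states), windows, 2):
                assert call.interval.length >= 130
                assert call.n_windows >= 5


class TestBatchSymmetry:
    def test_sample_order_does_not_change_calls(self, panel_and_windows):
        panel, windows = panel_and_windows
        iv = GenomicInterval("chr2", 100_000, 100_200)
        cfg = SimConfig(seed=9, karyotypes={f"B{i}": "XY" for i in range(8)},
                        panel=panel, windows=windows, cnvs=[("B3", iv, 3)])
        dm, _ = simulate_depth(cfg)
        gcnorm.correct_matrix(dm)
        calls = call_cnvs(dm, "B3", expected_copies_of={"chrX": 1, "chrY": 1})
        order = list(reversed(range(8)))
        dm2 = gcnorm.DepthMatrix(
            samples=[dm.samples[i] for i in order], windows=windows, raw=dm.raw[order]
        )
        dm2.corrected = dm.corrected[order]
        dm2.low_confidence = dm.low_confidence[order]
        calls2 = call_cnvs(dm2, "B3", expected_copies_of={"chrX": 1, "chrY": 1})
        assert [(str(c.interval), c.copy_number, c.n_windows) for c in calls] == [
            (str(c.interval), c.copy_number, c.n_windows) for c in calls2
        ]
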