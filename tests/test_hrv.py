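"""HRV indices: closed forms, naive-implementation oracles, scaling exponents."""

from math import log, sqrt

import numpy as np
import pytest

import fcgbeats as f
from fcgbeats.core import InsufficientDataError, Tachogram


def _tacho(rr_ms, t0=0.0):
    rr = np.asarray(rr_ms, dtype=float)
    times = t0 + np.cumsum(rr) / 1000.0
    return Tachogram(intervals=rr, times=times)


def _rw_tacho(rng, n=500, mean=900.0, sd=30.0):
    return _tacho(mean + sd * rng.standard_normal(n))


class TestArtifactCorrection:
    def test_clean_tachogram_unchanged(self, rng):
        tacho = _rw_tacho(rng, n=100, sd=20)
        res = f.correct_artifacts(tacho)
        assert res.n_corrected == 0
        assert np.array_equal(res.tachogram.intervals, tacho.intervals)

    def test_doubled_interval_flagged_and_repaired(self, rng):
        tacho = _rw_tacho(rng, n=100, sd=10)
        original = tacho.intervals[50]
        tacho.intervals[50] *= 2.0
        res = f.correct_artifacts(tacho)
        assert res.n_corrected == 1
        assert abs(res.tachogram.intervals[50] - original) / original < 0.10

    def test_constant_series_with_one_outlier(self):
        rr = np.full(60, 800.0)
        rr[30] = 1600.0
        res = f.correct_artifacts(_tacho(rr))
        assert res.n_corrected == 1
        assert not res.quality_warning

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            f.correct_artifacts(_tacho(np.full(5, 800.0)))


class TestTimeDomain:
    def test_constant_series(self):
        td = f.time_domain(_tacho([1000.0, 1000.0, 1000.0]))
        assert td["mean_rr"] == 1000.0
        assert td["sdnn"] == 0.0
        assert td["mean_hr"] == 60.0
        assert td["rmssd"] == 0.0
        assert td["nn50"] == 0

    def test_direct_formula_case(self):
        td = f.time_domain(_tacho([800.0, 860.0, 800.0]))
        assert td["nn50"] == 2
        assert td["pnn50"] == 100.0
        assert td["rmssd"] == pytest.approx(60.0)

    def test_matches_naive_reference(self, rng):
        rr = 900 + 40 * rng.standard_normal(300)
        td = f.time_domain(_tacho(rr))
        drr = np.diff(rr)
        hr = 60000.0 / rr
        assert td["mean_rr"] == pytest.approx(rr.mean(), abs=1e-9)
        assert td["sdnn"] == pytest.approx(rr.std(ddof=1), abs=1e-9)
        assert td["mean_hr"] == pytest.approx(hr.mean(), abs=1e-9)
        assert td["sd_hr"] == pytest.approx(hr.std(ddof=1), abs=1e-9)
        assert td["rmssd"] == pytest.approx(sqrt(np.mean(drr**2)), abs=1e-9)
        assert td["nn50"] == np.sum(np.abs(drr) > 50)
        assert td["pnn50"] == pytest.approx(100 * np.mean(np.abs(drr) > 50), abs=1e-9)
        # 5-beat smoothed extremes
        sm = np.convolve(hr, np.ones(5) / 5, mode="valid")
        assert td["min_hr"] == pytest.approx(sm.min(), abs=1e-9)
        assert td["max_hr"] == pytest.approx(sm.max(), abs=1e-9)


class TestFrequencyDomain:
    def _modulated(self, freq, duration=300.0, amp=30.0):
        times, rr = [], []
        t = 0.0
        while t < duration:
            r = 1000.0 + amp * np.sin(2 * np.pi * freq * t)
            t += r / 1000.0
            times.append(t)
            rr.append(r)
        return Tachogram(intervals=np.array(rr), times=np.array(times))

    def test_lf_modulation_lands_in_lf_band(self):
        fd = f.frequency_domain(self._modulated(0.10))
        assert fd["lf_abs"] / (fd["lf_abs"] + fd["hf_abs"]) >= 0.90
        assert fd["lf_nu"] >= 90.0

    def test_hf_modulation_lands_in_hf_band(self):
        fd = f.frequency_domain(self._modulated(0.25))
        assert fd["hf_nu"] >= 90.0

    def test_normalized_units_sum_to_100(self, rng):
        tacho = _rw_tacho(rng, n=400)
        fd = f.frequency_domain(tacho)
        assert fd["lf_nu"] + fd["hf_nu"] == pytest.approx(100.0, abs=1e-6)
        assert fd["total_power"] >= fd["lf_abs"] + fd["hf_abs"]

    def test_short_record_raises(self, rng):
        with pytest.raises(InsufficientDataError):
            f.frequency_domain(_rw_tacho(rng, n=50))


class TestPoincare:
    def test_alternating_series(self):
        rr = np.tile([800.0, 900.0], 30)
        sd1, sd2, _ = f.poincare(_tacho(rr))
        # all successive differences are +-100 ms
        assert sd1 == pytest.approx(100.0 / sqrt(2))

    def test_constant_series_ratio_undefined(self):
        sd1, sd2, ratio = f.poincare(_tacho(np.full(20, 800.0)))
        assert sd1 == 0.0
        assert np.isnan(ratio)

    def test_sd1_rmssd_identity(self, rng):
        for _ in range(5):
            tacho = _rw_tacho(rng, n=int(rng.integers(10, 200)))
            sd1, _, _ = f.poincare(tacho)
            rmssd = f.time_domain(tacho)["rmssd"]
            assert sd1 == pytest.approx(rmssd / sqrt(2), rel=1e-6)


def _entropy_naive(rr, m=2, r_frac=0.2):
    """Direct O(n^2) transcription of the ApEn / SampEn definitions."""
    rr = np.asarray(rr, float)
    n = rr.size
    r = r_frac * np.std(rr, ddof=1)

    def phi(mm):
        vecs = [rr[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for v in vecs:
            c = sum(1 for w in vecs if np.max(np.abs(v - w)) <= r)
            total += log(c / len(vecs))
        return total / len(vecs)

    apen = phi(m) - phi(m + 1)
    vm = [rr[i : i + m] for i in range(n - m)]
    vm1 = [rr[i : i + m + 1] for i in range(n - m)]
    b = sum(
        1 for i in range(len(vm)) for j in range(len(vm)) if i != j
        and np.max(np.abs(vm[i] - vm[j])) <= r
    )
    a = sum(
        1 for i in range(len(vm1)) for j in range(len(vm1)) if i != j
        and np.max(np.abs(vm1[i] - vm1[j])) <= r
    )
    sampen = -log(a / b) if a > 0 else np.nan
    return apen, sampen


class TestEntropy:
    def test_matches_naive_counting(self, rng):
        rr = 900 + 30 * rng.standard_normal(500)
        apen, sampen = f.entropy(_tacho(rr))
        napen, nsampen = _entropy_naive(rr)
        assert apen == pytest.approx(napen, abs=1e-9)
        assert sampen == pytest.approx(nsampen, abs=1e-9)

    def test_periodic_less_complex_than_shuffled(self, rng):
        rr = np.tile([800.0, 900.0], 100).astype(float)
        _, sampen_periodic = f.entropy(_tacho(rr))
        shuffled = rr.copy()
        rng.shuffle(shuffled)
        _, sampen_shuffled = f.entropy(_tacho(shuffled))
        assert sampen_periodic < sampen_shuffled

    def test_constant_series_apen_zero(self):
        apen, _ = f.entropy(_tacho(np.full(100, 800.0)))
        assert apen == 0.0


class TestDfa:
    def test_white_noise_alpha1_near_half(self, rng):
        rr = 900 + 25 * rng.standard_normal(1000)
        a1, a2 = f.dfa(_tacho(rr))
        assert 0.4 <= a1 <= 0.6

    def test_integrated_noise_alpha1_near_three_halves(self, rng):
        steps = rng.standard_normal(1000)
        rr = 900 + 5 * np.cumsum(steps)
        rr = rr - rr.min() + 500  # keep intervals positive
        a1, _ = f.dfa(_tacho(rr))
        assert 1.3 <= a1 <= 1.7

    def test_fluctuation_grows_with_box_size(self, rng):
        from fcgbeats.hrv import dfa as _dfa  # noqa: F401  (module import check)

        rr = 900 + 25 * rng.standard_normal(600)
        y = np.cumsum(rr - rr.mean())

        def fluct(s):
            nb = len(y) // s
            seg = y[: nb * s].reshape(nb, s)
            t = np.arange(s)
            res = []
            for row in seg:
                c = np.polyfit(t, row, 1)
                res.append(row - np.polyval(c, t))
            return np.sqrt(np.mean(np.concatenate(res) ** 2))

        fl = [fluct(s) for s in (4, 8, 16, 32, 64)]
        assert all(b > a for a, b in zip(fl, fl[1:]))

    def test_short_series_gives_nan(self, rng):
        a1, a2 = f.dfa(_rw_tacho(rng, n=80))
        assert np.isnan(a1) and np.isnan(a2)


class TestReport:
    def test_full_panel_on_synthetic_tachogram(self):
        cfg = f.SynthConfig(duration=300.0, seed=2)
        tacho = f.generate_rr_series(cfg)
        rep = f.hrv_report(tacho)
        assert rep.mean_rr == pytest.approx(60000.0 / cfg.hr_mean, rel=0.05)
        assert rep.lf_nu + rep.hf_nu == pytest.approx(100.0, abs=1e-6)
        assert rep.sd1 == pytest.approx(rep.rmssd / sqrt(2), rel=1e-6)
        assert rep.sd1 >= 0 and rep.sd2 >= 0
        assert 0 <= rep.pnn50 <= 100
        assert np.isfinite(rep.apen) and np.isfinite(rep.sampen)
        assert np.isfinite(rep.dfa_a1)

    def test_detected_indices_track_reference(self, clean_results):
        """Time-domain and Poincare indices from detected S1 beats match the
        ground-truth indices within 2% relative."""
        results, truth = clean_results
        det = f.hrv_report(results["S1"].det_tachogram)
        ref = f.hrv_report(
            f.inter_beat_intervals(f.EventSeries(times=truth.s1_times, label="S1"))
        )
        for key in ("mean_rr", "sdnn", "mean_hr", "sd_hr", "min_hr", "max_hr",
                    "rmssd", "pnn50", "sd1", "sd2"):
            a, b = getattr(det, key), getattr(ref, key)
            assert a == pytest.approx(b, rel=0.02), key
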