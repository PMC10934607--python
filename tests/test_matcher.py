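"""NCC matcher: oracle equivalence, bounds, affine invariance, localization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fcgbeats as f
from fcgbeats import matcher
from fcgbeats.core import (
    InvalidArgumentError,
    InvalidTemplateError,
    Template,
    TemplateSelectionError,
    UniformSignal,
)


def _template_from(arr, fs=100.0, label="S1"):
    arr = np.asarray(arr, dtype=float)
    return Template(samples=arr, fs=fs, label=label, peak_offset=int(np.argmax(arr)))


class TestExtractTemplate:
    def test_peak_offset_on_wavelet_peak(self, heart_sounds, clean_results):
        _, truth = clean_results
        s1 = truth.s1_times[5]
        tpl = f.extract_template(heart_sounds, s1 - 0.06, s1 + 0.06, "S1")
        peak_time = tpl.source_span[0] + tpl.peak_offset / tpl.fs
        assert abs(peak_time - s1) <= 1.5 / heart_sounds.fs

    def test_bad_span_raises(self, heart_sounds):
        with pytest.raises(InvalidArgumentError):
            f.extract_template(heart_sounds, 2.0, 1.0, "S1")

    def test_constant_span_raises(self):
        sig = UniformSignal(np.ones(1000), 100.0)
        with pytest.raises(InvalidTemplateError):
            f.extract_template(sig, 1.0, 2.0, "S1")


class TestNcc:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=200)
        sig = UniformSignal(x, 100.0)
        tpl = _template_from(x[50:90])
        trace = f.ncc(sig, tpl)
        assert trace.values[50] == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance_exact(self, rng):
        x = rng.normal(size=300)
        tpl = _template_from(rng.normal(size=30))
        base = f.ncc(UniformSignal(x, 100.0), tpl).values
        scaled = f.ncc(UniformSignal(3.5 * x + 11.0, 100.0), tpl).values
        assert np.allclose(base, scaled, atol=1e-9)

    def test_negative_scaling_flips_sign(self, rng):
        x = rng.normal(size=120)
        sig = UniformSignal(x, 100.0)
        win = 2.0 * x[40:70] + 1.0
        tpl = _template_from(win)
        assert f.ncc(sig, tpl).values[40] == pytest.approx(1.0, abs=1e-9)
        tpl_neg = _template_from(-win)
        assert f.ncc(sig, tpl_neg).values[40] == pytest.approx(-1.0, abs=1e-9)

    @pytest.mark.parametrize("n,m", [(12, 4), (64, 9), (257, 31)])
    def test_matches_naive_double_loop(self, rng, n, m):
        for _ in range(5):
            sig = UniformSignal(rng.normal(size=n), 100.0)
            tpl = _template_from(rng.normal(size=m))
            fast = f.ncc(sig, tpl).values
            slow = matcher.ncc_naive(sig, tpl).values
            assert fast.shape == (n - m + 1,)
            assert np.max(np.abs(fast - slow)) < 1e-9

    def test_zero_variance_windows_map_to_zero(self):
        x = np.concatenate([np.zeros(50), [0.0, 1.0, 2.0, 1.0, 0.0], np.zeros(50)])
        sig = UniformSignal(x, 100.0)
        tpl = _template_from([0.0, 1.0, 2.0, 1.0, 0.0])
        trace = f.ncc(sig, tpl)
        assert trace.values[0] == 0.0
        assert trace.values[50] == pytest.approx(1.0, abs=1e-9)

    def test_template_longer_than_signal_raises(self, rng):
        sig = UniformSignal(rng.normal(size=10), 100.0)
        tpl = _template_from(rng.normal(size=20))
        with pytest.raises(InvalidArgumentError):
            f.ncc(sig, tpl)

    @settings(max_examples=50, deadline=None, derandomize=True, database=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_for_arbitrary_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        m = int(rng.integers(3, min(n, 40) + 1))
        sig = UniformSignal(rng.normal(scale=rng.uniform(0.01, 100), size=n), 100.0)
        tpl = _template_from(rng.normal(scale=rng.uniform(0.01, 100), size=m))
        v = f.ncc(sig, tpl).values
        assert np.all(v >= -1.0) and np.all(v <= 1.0)


class TestFindEvents:
    def _trace(self, values, fs=100.0, peak_offset=0):
        return matcher.NccTrace(values=np.asarray(values, float), fs=fs, peak_offset=peak_offset)

    def test_single_bump(self):
        v = np.concatenate([np.linspace(0, 0.8, 10), np.linspace(0.8, 0, 10)[1:]])
        ev = f.find_events(self._trace(v), min_height=0.5)
        assert len(ev) == 1
        assert ev.times[0] == pytest.approx(9 / 100.0)

    def test_equal_peaks_within_distance_keep_earlier(self):
        v = np.zeros(100)
        v[30] = 0.9
        v[40] = 0.9  # 0.1 s later at fs=100
        ev = f.find_events(self._trace(v), min_height=0.5, min_distance_s=0.3)
        assert len(ev) == 1
        assert ev.times[0] == pytest.approx(0.30)

    def test_realignment_uses_peak_offset(self):
        v = np.zeros(50)
        v[20] = 0.9
        ev = f.find_events(self._trace(v, peak_offset=7), min_height=0.5)
        assert ev.times[0] == pytest.approx(27 / 100.0)

    def test_empty_when_below_threshold(self):
        ev = f.find_events(self._trace(np.zeros(50)), min_height=0.5)
        assert len(ev) == 0


@pytest.fixture(scope="module")
def jitterfree():
    # a clean recording without systolic-interval jitter, so the pair
    # template's internal S1->S2 spacing matches every beat
    cfg = f.SynthConfig(duration=120.0, s2_delay_sd=0.0, seed=11)
    fcg, truth = f.generate_fcg(cfg)
    from fcgbeats.pipeline import heart_sound_component

    return heart_sound_component(fcg), truth


class TestLocalization:
    """Events from each template land within ±5 ms of their true fiducials."""

    @pytest.mark.parametrize("label", ["S1", "S2", "S1S2"])
    def test_within_5ms_of_truth(self, jitterfree, label):
        hs, truth = jitterfree
        tpl = f.auto_select_template(hs, label)
        trace = f.ncc(hs, tpl)
        ev = f.find_events(
            trace,
            matcher.DEFAULT_MIN_HEIGHT[label],
            matcher.DEFAULT_MIN_DISTANCE_S[label],
            label=label,
        )
        # the pair template's absolute maximum lies in S1, so its events are
        # S1 fiducials
        fiducials = truth.s2_times if label == "S2" else truth.s1_times
        assert len(ev) == len(fiducials)
        assert np.max(np.abs(ev.times - fiducials)) < 0.005


class TestAutoSelect:
    def test_s1_span_contains_true_s1(self, heart_sounds, clean_results):
        _, truth = clean_results
        tpl = f.auto_select_template(heart_sounds, "S1")
        lo, hi = tpl.source_span
        assert np.any((truth.s1_times >= lo) & (truth.s1_times <= hi))

    def test_pair_span_contains_s1_and_following_s2(self, heart_sounds, clean_results):
        _, truth = clean_results
        tpl = f.auto_select_template(heart_sounds, "S1S2")
        lo, hi = tpl.source_span
        k = np.nonzero((truth.s1_times >= lo) & (truth.s1_times <= hi))[0]
        assert k.size == 1
        assert lo <= truth.s2_times[k[0]] <= hi

    def test_zero_signal_raises(self):
        sig = UniformSignal(np.zeros(10000), 1000.0)
        with pytest.raises(TemplateSelectionError):
            f.auto_select_template(sig, "S1")
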