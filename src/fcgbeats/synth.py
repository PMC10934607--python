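"""Synthetic forcecardiography (FCG) and ECG generator with exact ground truth.

Real chest-wall force recordings of heart sounds are rarely shared, so the
package ships a generator that emulates the second-order structure the
template-matching method relies on:

* quasi-periodic beats whose RR intervals carry respiratory sinus arrhythmia
  plus white jitter;
* S1 and S2 heart sounds as Gaussian-modulated cosine wavelets (S1 larger
  and lower-pitched, S2 later in the beat and higher-pitched, as aortic and
  pulmonic valve closures are);
* a slow respiratory baseline and respiratory amplitude modulation of S2
  (the mechanical analogue of physiologic S2 splitting);
* broadband measurement noise;
* a concurrent ECG whose R-peaks precede S1 by a fixed electromechanical
  delay.

The emitted :class:`GroundTruth` carries the exact wavelet-peak times, so
recognition statistics and interval agreement can be scored without manual
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import InvalidConfigError, Tachogram, UniformSignal

__all__ = ["SynthConfig", "GroundTruth", "generate_rr_series", "generate_fcg", "generate_ecg"]

# Minimum physiologically plausible RR interval; shorter draws are resampled.
_RR_FLOOR_MS = 300.0
_MAX_RETRIES = 1000


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recording.

    All durations are seconds, rates Hz, intervals ms, amplitudes in the
    (arbitrary) force-signal unit of the S1 wavelet peak, which is 1.
    """

    fs: float = 1000.0           #: sampling rate (Hz)
    duration: float = 300.0      #: recording length (s)
    hr_mean: float = 65.0        #: mean heart rate (bpm)
    rr_jitter_sd: float = 20.0   #: white Gaussian RR perturbation (ms)
    resp_rate: float = 0.25      #: respiratory rate (Hz)
    rsa_amp: float = 30.0        #: respiratory sinus arrhythmia amplitude (ms)
    s1_freq: float = 50.0        #: S1 wavelet carrier (Hz)
    s2_freq: float = 80.0        #: S2 wavelet carrier (Hz)
    s1_dur: float = 0.10         #: S1 wavelet duration (s); envelope SD = dur/6
    s2_dur: float = 0.08         #: S2 wavelet duration (s)
    s2_delay_mean: float = 0.30  #: S1-peak -> S2-peak systolic interval (s)
    s2_delay_sd: float = 0.01    #: beat-to-beat SD of that interval (s)
    s2_amp_ratio: float = 0.6    #: S2/S1 peak amplitude ratio (< 1)
    resp_mod_depth: float = 0.2  #: respiratory modulation depth of S2 amplitude
    resp_baseline_amp: float = 2.0  #: respiratory baseline amplitude (signal units)
    noise_sd: float = 0.02       #: broadband noise SD (signal units)
    r_to_s1_delay: float = 0.05  #: R-peak -> S1-peak electromechanical delay (s)
    seed: int = 0                #: RNG seed; identical config => identical output

    def __post_init__(self) -> None:
        if not (self.fs > 0 and self.duration > 0):
            raise InvalidConfigError("fs and duration must be positive")
        if not (0 < self.s2_amp_ratio < 1):
            raise InvalidConfigError("s2_amp_ratio must lie in (0, 1)")
        if not (self.s2_delay_mean > self.s1_dur):
            raise InvalidConfigError("s2_delay_mean must exceed s1_dur")
        if self.hr_mean <= 0:
            raise InvalidConfigError("hr_mean must be positive")
        if self.rr_jitter_sd < 0 or self.s2_delay_sd < 0 or self.noise_sd < 0:
            raise InvalidConfigError("standard deviations must be non-negative")
        if self.r_to_s1_delay <= 0:
            raise InvalidConfigError("r_to_s1_delay must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Exact beat fiducials of a synthetic recording (all seconds).

    Invariant: ``r[k] < s1[k] < s2[k] < r[k+1]`` for every beat k.
    """

    r_times: np.ndarray
    s1_times: np.ndarray
    s2_times: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_times, dtype=float)
        s1 = np.asarray(self.s1_times, dtype=float)
        s2 = np.asarray(self.s2_times, dtype=float)
        if not (r.size == s1.size == s2.size):
            raise InvalidConfigError("ground-truth series must have equal length")
        interleaved = np.column_stack([r, s1, s2]).ravel()
        if np.any(np.diff(interleaved) <= 0):
            raise InvalidConfigError("ground truth must satisfy r < s1 < s2 < next r")
        object.__setattr__(self, "r_times", r)
        object.__setattr__(self, "s1_times", s1)
        object.__setattr__(self, "s2_times", s2)

    def __len__(self) -> int:
        return self.r_times.size


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per component
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _draw_rr_ms(config: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """RR intervals (ms) and the beat times t_k (s) they accumulate to.

    RR_k = 60000/hr_mean + rsa_amp*sin(2*pi*resp_rate*t_k) + eps_k with
    eps_k ~ N(0, rr_jitter_sd^2); draws below the 300 ms floor are
    resampled a bounded number of times.
    """
    base = 60000.0 / config.hr_mean
    rrs: list[float] = []
    t = 0.0  # beat clock, seconds
    # generate enough beats to cover duration plus one spare beat
    while t < config.duration + base / 1000.0:
        rsa = config.rsa_amp * np.sin(2 * np.pi * config.resp_rate * t)
        rr = base + rsa + (rng.normal(0.0, config.rr_jitter_sd) if config.rr_jitter_sd > 0 else 0.0)
        retries = 0
        while rr <= _RR_FLOOR_MS:
            if config.rr_jitter_sd == 0 or retries >= _MAX_RETRIES:
                raise InvalidConfigError(
                    f"cannot satisfy RR > {_RR_FLOOR_MS:.0f} ms with hr_mean="
                    f"{config.hr_mean}, rsa_amp={config.rsa_amp}"
                )
            rr = base + rsa + rng.normal(0.0, config.rr_jitter_sd)
            retries += 1
        rrs.append(rr)
        t += rr / 1000.0
    rr_arr = np.asarray(rrs)
    beat_times = np.cumsum(rr_arr) / 1000.0
    return rr_arr, beat_times


def generate_rr_series(config: SynthConfig) -> Tachogram:
    """Generate the RR tachogram underlying a synthetic recording.

    Returns intervals in ms; ``times`` holds the end beat of each interval
    (seconds, first beat at t=0).
    """
    rng = _rng(config, 0)
    rr, beat_times = _draw_rr_ms(config, rng)
    return Tachogram(intervals=rr, times=beat_times)


def _beat_fiducials(config: SynthConfig) -> GroundTruth:
    """Exact wavelet-peak times of every complete beat in the recording."""
    rng = _rng(config, 0)
    rr, beat_times = _draw_rr_ms(config, rng)
    # first S1 placed after a short lead-in so the R-peak stays in-record
    start = config.r_to_s1_delay + 0.25
    s1 = start + np.concatenate([[0.0], beat_times[:-1]])
    delay_rng = _rng(config, 1)
    if config.s2_delay_sd > 0:
        delays = delay_rng.normal(config.s2_delay_mean, config.s2_delay_sd, size=s1.size)
    else:
        delays = np.full(s1.size, config.s2_delay_mean)
    delays = np.clip(delays, config.s1_dur + 0.02, None)
    s2 = s1 + delays
    # keep only beats whose S2 wavelet fits inside the record
    margin = config.s2_dur
    keep = s2 + margin < config.duration
    s1, s2 = s1[keep], s2[keep]
    if s1.size < 2:
        raise InvalidConfigError("duration too short for at least 2 beats")
    return GroundTruth(r_times=s1 - config.r_to_s1_delay, s1_times=s1, s2_times=s2)


def _gabor(t: np.ndarray, center: float, freq: float, dur: float) -> np.ndarray:
    """Gaussian-modulated cosine whose signed maximum is exactly at ``center``.

    The envelope SD is dur/6, so ±3 SD spans the nominal duration.
    """
    sigma = dur / 6.0
    u = t - center
    return np.exp(-0.5 * (u / sigma) ** 2) * np.cos(2 * np.pi * freq * u)


def generate_fcg(config: SynthConfig) -> tuple[UniformSignal, GroundTruth]:
    """Synthesize the raw force signal and its exact beat fiducials.

    The signal is the sum of S1 and S2 wavelets at the true times, a slow
    respiratory baseline, and white noise.  The S2 amplitude is modulated
    by respiration with depth ``resp_mod_depth``.
    """
    truth = _beat_fiducials(config)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    sig = np.zeros(n)
    half_s1 = config.s1_dur  # wavelet support: ±dur around the peak is ±6 SD
    half_s2 = config.s2_dur
    for s1_k in truth.s1_times:
        lo = max(0, int((s1_k - half_s1) * config.fs))
        hi = min(n, int((s1_k + half_s1) * config.fs) + 1)
        sig[lo:hi] += _gabor(t[lo:hi], s1_k, config.s1_freq, config.s1_dur)
    for s2_k in truth.s2_times:
        amp = config.s2_amp_ratio * (
            1.0 + config.resp_mod_depth * np.sin(2 * np.pi * config.resp_rate * s2_k)
        )
        lo = max(0, int((s2_k - half_s2) * config.fs))
        hi = min(n, int((s2_k + half_s2) * config.fs) + 1)
        sig[lo:hi] += amp * _gabor(t[lo:hi], s2_k, config.s2_freq, config.s2_dur)
    sig += config.resp_baseline_amp * np.sin(2 * np.pi * config.resp_rate * t)
    if config.noise_sd > 0:
        sig += _rng(config, 2).normal(0.0, config.noise_sd, size=n)
    return UniformSignal(sig, config.fs), truth


def wavelet_sum(config: SynthConfig, truth: GroundTruth) -> UniformSignal:
    """The noise- and baseline-free heart-sound component of :func:`generate_fcg`.

    Useful as a reference when checking that band-pass filtering isolates
    the heart sounds.
    """
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    sig = np.zeros(n)
    for s1_k in truth.s1_times:
        sig += _gabor(t, s1_k, config.s1_freq, config.s1_dur)
    for s2_k in truth.s2_times:
        amp = config.s2_amp_ratio * (
            1.0 + config.resp_mod_depth * np.sin(2 * np.pi * config.resp_rate * s2_k)
        )
        sig += amp * _gabor(t, s2_k, config.s2_freq, config.s2_dur)
    return UniformSignal(sig, config.fs)


def generate_ecg(config: SynthConfig, truth: GroundTruth) -> UniformSignal:
    """Synthesize a concurrent single-lead ECG from the ground-truth R times.

    Each QRS complex is a narrow positive Mexican-hat (Ricker) wavelet whose
    peak falls exactly on ``truth.r_times[k]``; white noise of SD
    ``config.noise_sd`` (scaled to the unit QRS amplitude) is added.
    """
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    sig = np.zeros(n)
    a = 0.0125  # Ricker scale (s): main lobe ~50 ms, support ~80 ms
    for r_k in truth.r_times:
        lo = max(0, int((r_k - 6 * a) * config.fs))
        hi = min(n, int((r_k + 6 * a) * config.fs) + 1)
        u = (t[lo:hi] - r_k) / a
        sig[lo:hi] += (1.0 - u**2) * np.exp(-0.5 * u**2)
    if config.noise_sd > 0:
        sig += _rng(config, 3).normal(0.0, config.noise_sd, size=n)
    return UniformSignal(sig, config.fs)
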