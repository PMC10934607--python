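"""End-to-end orchestration: preprocess → R-peaks → matching → statistics.

``run_pipeline`` ties the stages together for file-based use (the CLI is a
thin wrapper around it); ``analyze_recording`` does the same on in-memory
objects and is the programmatic entry point used by the test-bench and the
reproduction script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import agreement, beats, hrv, io, matcher, preprocess, rpeak
from .core import EventSeries, InvalidArgumentError, Tachogram, UniformSignal
from .synth import GroundTruth

__all__ = ["RunConfig", "LabelResult", "analyze_recording", "run_pipeline"]

log = logging.getLogger("fcgbeats")

LABELS = ("S1", "S2", "S1S2")


@dataclass
class RunConfig:
    """File paths and parameters of a full pipeline run."""

    fcg_path: str
    out_dir: str
    ecg_path: str | None = None
    truth_path: str | None = None       # bypasses R-peak detection when given
    fs: float | None = None             # for single-column CSVs
    template_spec: dict | None = None   # per-label {start_s,end_s} or {"auto": True}
    sg_frame_s: float = 1.5
    sg_polyorder: int = 3
    hs_band: tuple[float, float] = (30.0, 200.0)
    ecg_band: tuple[float, float] = (0.5, 40.0)
    mains_hz: float = 50.0
    # None -> per-label defaults from matcher.DEFAULT_MIN_HEIGHT/_MIN_DISTANCE_S
    min_height: float | dict | None = None
    min_distance_s: float | dict | None = None
    match_tol_s: float = 0.15
    hrv_threshold_ms: float = 250.0
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class LabelResult:
    """Everything derived from one template label."""

    template: matcher.Template
    events: EventSeries
    match: beats.BeatMatch
    sensitivity_pct: float
    ppv_pct: float
    det_tachogram: Tachogram
    paired_ref_ms: np.ndarray
    paired_det_ms: np.ndarray
    regression: agreement.RegressionResult | None
    bland_altman: agreement.BlandAltmanResult | None
    hrv: hrv.HRVReport | None


def heart_sound_component(raw: UniformSignal, cfg: RunConfig | None = None) -> UniformSignal:
    """Respiration removal plus 30–200 Hz band-pass of the raw force signal."""
    cfg = cfg or RunConfig(fcg_path="", out_dir="")
    resp = preprocess.extract_respiratory(raw, cfg.sg_frame_s, cfg.sg_polyorder)
    cardiac = preprocess.remove_baseline(raw, resp)
    return preprocess.bandpass_heart_sounds(cardiac, *cfg.hs_band)


def _analyze_label(
    hs: UniformSignal,
    template: matcher.Template,
    reference: EventSeries,
    cfg: RunConfig,
    bland_altman_seed: int,
) -> LabelResult:
    def _resolve(value, defaults):
        if isinstance(value, dict):
            return value.get(template.label, 0.5)
        return defaults[template.label] if value is None else value

    height = _resolve(cfg.min_height, matcher.DEFAULT_MIN_HEIGHT)
    distance = _resolve(cfg.min_distance_s, matcher.DEFAULT_MIN_DISTANCE_S)
    trace = matcher.ncc(hs, template)
    events = matcher.find_events(trace, height, distance, label=template.label)
    match = beats.match_events(events, reference, tol_s=cfg.match_tol_s)
    sens, ppv = beats.recognition_stats(match)
    regression = ba = None
    hrv_report = None
    det_tacho = None
    xs = ys = np.empty(0)
    if len(events) >= 2:
        det_tacho = beats.inter_beat_intervals(events)
        ref_tacho = beats.inter_beat_intervals(reference)
        xs, ys = beats.paired_valid_intervals(det_tacho, ref_tacho, match)
        if xs.size >= 10 and np.ptp(xs) > 0:
            regression = agreement.compare_methods(xs, ys)
            ba = agreement.bland_altman(xs, ys, seed=bland_altman_seed)
        # HRV uses the unmasked tachogram: FP/FN-affected intervals are kept
        # here and handled by artifact correction instead.
        if len(det_tacho) >= 2:
            hrv_report = hrv.hrv_report(det_tacho, threshold_ms=cfg.hrv_threshold_ms)
    if det_tacho is None:
        det_tacho = Tachogram(intervals=np.empty(0), times=np.empty(0))
    return LabelResult(
        template=template,
        events=events,
        match=match,
        sensitivity_pct=sens,
        ppv_pct=ppv,
        det_tachogram=det_tacho,
        paired_ref_ms=xs,
        paired_det_ms=ys,
        regression=regression,
        bland_altman=ba,
        hrv=hrv_report,
    )


def analyze_recording(
    raw_fcg: UniformSignal,
    reference: EventSeries,
    cfg: RunConfig | None = None,
    templates: dict[str, matcher.Template] | None = None,
) -> dict[str, LabelResult]:
    """Run preprocessing, matching and all statistics on in-memory signals.

    ``reference`` is the beat series (R-peaks or ground-truth S1 times with
    the label ``"R"``).  When ``templates`` is None, one template per label
    is selected automatically from the heart-sound component.
    """
    cfg = cfg or RunConfig(fcg_path="", out_dir="")
    hs = heart_sound_component(raw_fcg, cfg)
    results: dict[str, LabelResult] = {}
    for i, label in enumerate(LABELS):
        tpl = templates.get(label) if templates else None
        if tpl is None:
            tpl = matcher.auto_select_template(hs, label)
        log.info("label %s: template span %s, %d samples", label, tpl.source_span, len(tpl))
        results[label] = _analyze_label(hs, tpl, reference, cfg, bland_altman_seed=cfg.seed + i)
        log.info(
            "label %s: tp=%d fp=%d fn=%d sens=%.1f%% ppv=%.1f%%",
            label,
            results[label].match.tp,
            results[label].match.fp,
            results[label].match.fn,
            results[label].sensitivity_pct,
            results[label].ppv_pct,
        )
    return results


def _round(v: float | None, nd: int) -> float | None:
    return None if v is None or not np.isfinite(v) else round(float(v), nd)


def _results_to_json(results: dict[str, LabelResult], reference: EventSeries) -> dict[str, dict]:
    events = {lbl: [round(float(t), 6) for t in r.events.times] for lbl, r in results.items()}
    stats = {
        lbl: {
            "tp": r.match.tp,
            "fp": r.match.fp,
            "fn": r.match.fn,
            "sensitivity_pct": _round(r.sensitivity_pct, 1),
            "ppv_pct": _round(r.ppv_pct, 1),
            "n_reference": r.match.n_reference,
            "n_intervals_analyzed": int(r.paired_ref_ms.size),
        }
        for lbl, r in results.items()
    }
    agreement_out = {}
    for lbl, r in results.items():
        if r.regression is None or r.bland_altman is None:
            agreement_out[lbl] = None
            continue
        reg, ba = r.regression, r.bland_altman
        agreement_out[lbl] = {
            "n": reg.n,
            "r": _round(reg.r, 4),
            "r_ci": [_round(v, 4) for v in reg.r_ci],
            "slope": _round(reg.slope, 4),
            "slope_ci": [_round(v, 4) for v in reg.slope_ci],
            "intercept_ms": _round(reg.intercept, 3),
            "intercept_ci_ms": [_round(v, 3) for v in reg.intercept_ci],
            "cusum_linear": reg.cusum_linear,
            "bias_ms": _round(ba.bias, 3),
            "bias_ci_ms": [_round(v, 3) for v in ba.bias_ci],
            "loa_low_ms": _round(ba.loa_low, 3),
            "loa_high_ms": _round(ba.loa_high, 3),
            "normal": ba.normal,
        }
    hrv_out: dict[str, dict | None] = {}
    if len(reference) >= 3:
        ref_tacho = beats.inter_beat_intervals(reference)
        hrv_out["reference"] = hrv.hrv_report(ref_tacho).to_dict() if len(ref_tacho) >= 2 else None
    else:
        hrv_out["reference"] = None
    for lbl, r in results.items():
        hrv_out[lbl] = r.hrv.to_dict() if r.hrv is not None else None
    return {"events": events, "stats": stats, "agreement": agreement_out, "hrv": hrv_out}


def run_pipeline(cfg: RunConfig) -> dict[str, dict]:
    """File-based pipeline: read signals, analyze, write the four JSONs.

    Writes ``events.json``, ``stats.json``, ``agreement.json`` and
    ``hrv.json`` into ``cfg.out_dir`` and returns the bundle as a dict.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = io.read_signal_csv(cfg.fcg_path, fs=cfg.fs)
    log.info("loaded FCG: %d samples at %.6g Hz", len(raw), raw.fs)

    if cfg.truth_path:
        truth = io.read_truth_json(cfg.truth_path)
        reference = EventSeries(times=truth.r_times, label="R")
        log.info("reference: %d ground-truth beats", len(reference))
    elif cfg.ecg_path:
        ecg_raw = io.read_signal_csv(cfg.ecg_path, fs=cfg.fs)
        ecg = preprocess.preprocess_ecg(ecg_raw, *cfg.ecg_band, mains=cfg.mains_hz)
        reference = rpeak.detect_r_peaks(ecg)
        log.info("reference: %d detected R-peaks", len(reference))
    else:
        raise InvalidArgumentError("need either an ECG or a truth file for the reference beats")

    templates = None
    if cfg.template_spec:
        hs = heart_sound_component(raw, cfg)
        templates = {}
        for label in LABELS:
            entry = cfg.template_spec.get(label)
            if entry is None:
                raise InvalidArgumentError(f"template spec missing label {label!r}")
            if entry.get("auto"):
                templates[label] = matcher.auto_select_template(hs, label)
            else:
                templates[label] = matcher.extract_template(
                    hs, entry["start_s"], entry["end_s"], label
                )
    results = analyze_recording(raw, reference, cfg, templates)
    bundle = _results_to_json(results, reference)
    for name in ("events", "stats", "agreement", "hrv"):
        io.write_json(bundle[name], out_dir / f"{name}.json")
    log.info("wrote results to %s", out_dir)
    return bundle
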