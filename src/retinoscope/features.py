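"""Feature extraction from processed ERG bundles.

Conventions (all times relative to stimulus onset):

* a-wave: trough of the raw (unfiltered) average within [0, 50] ms;
  amplitude is the baseline-to-trough deflection reported as a positive
  magnitude.  Measuring on the raw average keeps the sharp trough free of
  notch-filter ripple, which would otherwise dominate the smallest
  responses.
* b-wave: peak of the 60 Hz low-passed trace after the a-trough within
  (a-trough, 150] ms; amplitude is trough-to-peak, with the trough value
  taken from the raw a-wave measurement (baseline minus a-amplitude) so the
  sharp trough is not blunted by the notch/low-pass chain.
* OP area: sum of absolute trapezoid areas of the 120 Hz high-passed trace
  over [onset, onset + 120] ms, in uV*ms.

Non-measurable cases (flat or non-negative-going traces) yield amplitude 0
with a QC flag instead of an exception; ratios built on flagged zeros are
excluded rather than propagated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .filters import ProcessedTraceBundle

__all__ = ["ERGFeatures", "measure_a_wave", "measure_b_wave", "op_area", "extract_features", "compute_ratios"]

A_SEARCH_MS = 50.0     # a-trough search window after onset
B_SEARCH_MS = 150.0    # b-peak search window after onset
OP_WINDOW_MS = 120.0   # OP integration span after onset


@dataclass
class ERGFeatures:
    """Per-trace ERG measurements (one eye, one flash intensity)."""

    a_amp_uV: float
    a_latency_ms: float
    b_amp_uV: float
    b_latency_ms: float
    op_area_uVms: float
    intensity_log: float = math.nan
    eye_id: str = ""
    group: str = ""
    qc_flags: tuple = ()

    def __post_init__(self) -> None:
        if self.op_area_uVms < 0:
            raise ValueError("op_area_uVms must be >= 0")
        ok_lat = not (math.isfinite(self.a_latency_ms) and math.isfinite(self.b_latency_ms))
        if not ok_lat and not self.a_latency_ms < self.b_latency_ms:
            raise ValueError("a-wave latency must precede b-wave latency")


def _window_mask(t_ms: np.ndarray, start_ms: float, stop_ms: float) -> np.ndarray:
    mask = (t_ms >= start_ms) & (t_ms <= stop_ms)
    if not np.any(mask):
        raise ValueError("empty measurement window")
    return mask


def measure_a_wave(bundle: ProcessedTraceBundle) -> tuple:
    """Baseline-to-trough a-wave amplitude and onset-to-trough latency.

    Returns ``(amp_uV, latency_ms, flags)``; a trace with no negative-going
    deflection gives amplitude 0 and the ``"a_absent"`` flag.
    """
    tr = bundle.raw_avg
    mask = _window_mask(tr.t_ms, tr.onset_ms, tr.onset_ms + A_SEARCH_MS)
    idx = int(np.argmin(tr.v_uV[mask]))
    t_win, v_win = tr.t_ms[mask], tr.v_uV[mask]
    trough_v, trough_t = float(v_win[idx]), float(t_win[idx])
    amp = bundle.baseline_uV - trough_v
    if amp <= 0:
        return 0.0, math.nan, ("a_absent",)
    return float(amp), trough_t - tr.onset_ms, ()


def measure_b_wave(bundle: ProcessedTraceBundle, a_result: tuple | None = None) -> tuple:
    """Trough-to-peak b-wave amplitude and onset-to-peak latency.

    The peak is sought on the low-passed trace; the trough reference is the
    raw a-wave trough (baseline minus a-amplitude).  When the a-wave is
    absent the trough reference degenerates to the baseline.
    """
    if a_result is None:
        a_result = measure_a_wave(bundle)
    a_amp, a_latency, a_flags = a_result
    tr = bundle.b_isolated
    if "a_absent" in a_flags or not math.isfinite(a_latency):
        search_start = tr.onset_ms
        trough_v = bundle.baseline_uV
    else:
        # Strictly after the trough sample, so the peak cannot coincide with it.
        search_start = tr.onset_ms + a_latency + 0.5 * (1000.0 / tr.fs_hz)
        trough_v = bundle.baseline_uV - a_amp
    peak_mask = _window_mask(tr.t_ms, search_start, tr.onset_ms + B_SEARCH_MS)
    t_win, v_win = tr.t_ms[peak_mask], tr.v_uV[peak_mask]
    idx = int(np.argmax(v_win))
    amp = float(v_win[idx]) - trough_v
    if amp <= 0:
        return 0.0, math.nan, ("b_absent",)
    return amp, float(t_win[idx]) - tr.onset_ms, ()


def op_area(bundle: ProcessedTraceBundle) -> float:
    """Absolute trapezoid area of the isolated OPs over [onset, onset+120] ms."""
    tr = bundle.op_isolated
    stop = tr.onset_ms + OP_WINDOW_MS
    if tr.t_ms[-1] < stop:
        raise ValueError("trace ends before the OP integration window")
    mask = _window_mask(tr.t_ms, tr.onset_ms, stop)
    v = tr.v_uV[mask]
    dt = 1000.0 / tr.fs_hz
    return float(np.sum(np.abs(0.5 * (v[:-1] + v[1:])) * dt))


def extract_features(bundle: ProcessedTraceBundle) -> ERGFeatures:
    """All per-trace measurements in one record."""
    a = measure_a_wave(bundle)
    b = measure_b_wave(bundle, a)
    area = op_area(bundle)
    meta = bundle.raw_notched.meta
    return ERGFeatures(
        a_amp_uV=a[0], a_latency_ms=a[1],
        b_amp_uV=b[0], b_latency_ms=b[1],
        op_area_uVms=area,
        intensity_log=float(meta.get("intensity_log", math.nan)),
        eye_id=str(meta.get("eye_id", "")),
        group=str(meta.get("group", "")),
        qc_flags=tuple(a[2]) + tuple(b[2]),
    )


@dataclass
class RatioSet:
    """Within-trace amplitude ratios; None marks an excluded (flagged) ratio."""

    b_over_a: float | None
    op_over_a: float | None
    op_over_b: float | None
    qc_flags: tuple = field(default_factory=tuple)


def compute_ratios(features: ERGFeatures) -> RatioSet:
    """b/a, OP/a and OP/b ratios from one trace; flagged zeros are excluded."""
    flags = []
    a_ok = features.a_amp_uV > 0 and "a_absent" not in features.qc_flags
    b_ok = features.b_amp_uV > 0 and "b_absent" not in features.qc_flags
    if not a_ok:
        flags.append("ratio_a_denominator_flagged")
    if not b_ok:
        flags.append("ratio_b_denominator_flagged")
    return RatioSet(
        b_over_a=features.b_amp_uV / features.a_amp_uV if a_ok else None,
        op_over_a=features.op_area_uVms / features.a_amp_uV if a_ok else None,
        op_over_b=features.op_area_uVms / features.b_amp_uV if b_ok else None,
        qc_flags=tuple(flags),
    )
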