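"""Synthetic scotopic ERG generator.

Produces single sweeps, eyes (one sweep set per flash intensity) and
two-group cohorts with known ground truth, so the whole measurement chain
(filtering, feature extraction, Hill fitting, statistics) can be exercised
and validated without recorded data.

A sweep is modeled as a sum of interpretable components on a uniform time
base::

    v(t) = -A_a * g_a(t) + A_b * g_b(t) + OP packet + mains + noise

where ``A_a`` and ``A_b`` follow Hill functions of flash intensity (the
generative truth later recovered by the fitter), ``g_a``/``g_b`` are
unit-amplitude gamma-shaped kernels (sharp negative photoreceptor transient,
slower positive bipolar-cell transient), the OP packet is a Gabor wavelet
(Gaussian-windowed cosine) above 120 Hz confined to the first 120 ms after
the flash, mains interference is a 60 Hz sinusoid with random phase, and
noise is white Gaussian.  All deterministic components are exactly zero
before stimulus onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np

from .hill import hill_amplitude_log

__all__ = [
    "StimulusSeries",
    "ComponentParams",
    "TraceConfig",
    "Trace",
    "GroupSpec",
    "CohortSpec",
    "Eye",
    "Cohort",
    "make_default_stimulus",
    "synth_sweep",
    "synth_eye",
    "synth_cohort",
    "default_ctr_group",
    "default_vpa_group",
    "default_cohort_spec",
    "CTR_A_WAVE",
    "VPA_A_WAVE",
]

# Group-level a-wave Hill truth (mean, SD across eyes): (Vmax uV, k log, n).
CTR_A_WAVE = {"Vmax": (377.3, 87.5), "k_log": (2.67, 0.50), "n": (0.79, 0.24)}
VPA_A_WAVE = {"Vmax": (259.7, 121.1), "k_log": (2.52, 0.39), "n": (0.77, 0.26)}


@dataclass(frozen=True)
class StimulusSeries:
    """Ordered ladder of full-field flash intensities (log10 photons um^-2 s^-1)."""

    intensities_log: tuple
    lambda_max_nm: float = 459.0

    def __post_init__(self) -> None:
        arr = tuple(float(v) for v in self.intensities_log)
        object.__setattr__(self, "intensities_log", arr)
        if len(arr) < 1:
            raise ValueError("need at least one intensity")
        if any(b <= a for a, b in zip(arr, arr[1:])):
            raise ValueError("intensities must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.intensities_log)


def make_default_stimulus() -> StimulusSeries:
    """Default 13-step ladder: equal log spacing from -2.01 to 4.09.

    The nominal hardware ladder uses ~0.5 log steps; exact equal spacing
    gives step 8 at 1.548, within 0.02 log units of the nominal 1.56.  An
    explicit intensity list can be passed to :class:`StimulusSeries` when
    the true ladder is known.
    """
    return StimulusSeries(intensities_log=tuple(np.linspace(-2.01, 4.09, 13)))


@dataclass(frozen=True)
class ComponentParams:
    """Generative truth for one eye.

    Amplitude-vs-intensity relations for the a- and b-waves are Hill
    functions; timings are in ms relative to stimulus onset.  Defaults are
    the CTR-group mean a-wave parameters plus representative b-wave and
    OP/interference settings.
    """

    a_Vmax_uV: float = 377.3
    a_k_log: float = 2.67
    a_n: float = 0.79
    b_Vmax_uV: float = 763.9
    b_k_log: float = 1.46
    b_n: float = 0.31
    a_trough_ms: float = 15.0
    b_peak_ms: float = 60.0
    op_center_freq_hz: float = 170.0
    op_amp_uV: float = 35.0
    op_decay_ms: float = 12.0
    op_center_ms: float = 55.0
    mains_amp_uV: float = 5.0
    noise_sd_uV: float = 8.0

    def __post_init__(self) -> None:
        for name in ("a_Vmax_uV", "b_Vmax_uV", "op_amp_uV", "mains_amp_uV", "noise_sd_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.a_n <= 0 or self.b_n <= 0:
            raise ValueError("Hill slopes must be > 0")
        if self.op_center_freq_hz <= 120.0:
            raise ValueError("op_center_freq_hz must exceed 120 Hz to survive the OP high-pass")
        if not self.a_trough_ms < self.b_peak_ms:
            raise ValueError("a_trough_ms must precede b_peak_ms")

    def a_amplitude(self, intensity_log: float) -> float:
        return float(hill_amplitude_log(intensity_log, self.a_Vmax_uV, self.a_k_log, self.a_n)) if self.a_Vmax_uV > 0 else 0.0

    def b_amplitude(self, intensity_log: float) -> float:
        return float(hill_amplitude_log(intensity_log, self.b_Vmax_uV, self.b_k_log, self.b_n)) if self.b_Vmax_uV > 0 else 0.0


@dataclass(frozen=True)
class TraceConfig:
    """Sampling layout of a sweep: 2 kHz, 300 ms, flash at 30 ms by default."""

    fs_hz: float = 2000.0
    duration_ms: float = 300.0
    onset_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.duration_ms <= 0:
            raise ValueError("fs_hz and duration_ms must be > 0")
        if not (0.0 < self.onset_ms < self.duration_ms):
            raise ValueError("onset_ms must fall inside the sweep")

    def time_base(self) -> np.ndarray:
        n = int(round(self.duration_ms * self.fs_hz / 1000.0))
        return np.arange(n) * (1000.0 / self.fs_hz)


@dataclass
class Trace:
    """One uniformly sampled sweep: time (ms), voltage (uV), onset metadata."""

    t_ms: np.ndarray
    v_uV: np.ndarray
    onset_ms: float
    fs_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.v_uV = np.asarray(self.v_uV, dtype=float)
        if self.t_ms.shape != self.v_uV.shape or self.t_ms.ndim != 1:
            raise ValueError("t_ms and v_uV must be 1-D and equal length")
        dt = np.diff(self.t_ms)
        if dt.size and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise ValueError("time base must be uniform (to within 1e-9 ms) and increasing")
        if not (self.t_ms[0] <= self.onset_ms <= self.t_ms[-1]):
            raise ValueError("onset must lie within the sweep")

    def copy_with(self, v_uV: np.ndarray, **meta) -> "Trace":
        m = dict(self.meta)
        m.update(meta)
        return Trace(self.t_ms.copy(), np.asarray(v_uV, float), self.onset_ms, self.fs_hz, m)


# --- waveform kernels ------------------------------------------------------

# Gamma-kernel shape exponents.  Larger = narrower transient.  The a-wave is
# a sharp trough; the b-wave a slower dome whose rise is delayed past the
# a-trough so the sweep minimum equals the a-wave truth exactly.
_A_SHAPE = 4.0
_B_SHAPE = 2.0


def _gamma_kernel(t_rel: np.ndarray, t_peak: float, shape: float) -> np.ndarray:
    """Unit-amplitude gamma transient: 0 for t<=0, peaks at exactly 1 at t_peak."""
    out = np.zeros_like(t_rel)
    pos = t_rel > 0
    x = t_rel[pos] / t_peak
    out[pos] = x**shape * np.exp(shape * (1.0 - x))
    return out


def a_wave_kernel(t_ms: np.ndarray, onset_ms: float, trough_ms: float) -> np.ndarray:
    """Positive unit kernel of the photoreceptor transient (applied with a minus sign)."""
    return _gamma_kernel(t_ms - onset_ms, trough_ms, _A_SHAPE)


def b_wave_kernel(t_ms: np.ndarray, onset_ms: float, trough_ms: float, peak_ms: float) -> np.ndarray:
    """Unit kernel of the bipolar-cell dome; zero until the a-trough time."""
    return _gamma_kernel(t_ms - onset_ms - trough_ms, peak_ms - trough_ms, _B_SHAPE)


def op_packet(t_ms: np.ndarray, onset_ms: float, params: ComponentParams) -> np.ndarray:
    """Gabor wavelet of oscillatory potentials, confined to [onset, onset+120] ms."""
    u = t_ms - onset_ms - params.op_center_ms
    env = np.exp(-0.5 * (u / params.op_decay_ms) ** 2)
    wave = params.op_amp_uV * env * np.cos(2.0 * math.pi * params.op_center_freq_hz * u / 1000.0)
    window = (t_ms >= onset_ms) & (t_ms <= onset_ms + 120.0)
    return np.where(window, wave, 0.0)


def deterministic_sweep(intensity_log: float, params: ComponentParams, config: TraceConfig) -> np.ndarray:
    """Noise- and mains-free component sum at one intensity.

    The b-kernel coefficient is ``max(B - A, 0)`` rather than ``B`` so that
    the *measured* trough-to-peak b-wave amplitude — the quantity fitted
    with the Hill function downstream — equals the generative Hill value
    ``B`` exactly on clean traces (the peak sits at ``B - A`` above baseline
    and the trough at ``-A`` below it).
    """
    t = config.time_base()
    A = params.a_amplitude(intensity_log)
    B = params.b_amplitude(intensity_log)
    v = -A * a_wave_kernel(t, config.onset_ms, params.a_trough_ms)
    v = v + max(B - A, 0.0) * b_wave_kernel(t, config.onset_ms, params.a_trough_ms, params.b_peak_ms)
    if params.op_amp_uV > 0:
        v = v + op_packet(t, config.onset_ms, params)
    return v


def synth_sweep(
    intensity_log: float,
    params: ComponentParams,
    config: TraceConfig | None = None,
    rng: np.random.Generator | int | None = None,
    **meta,
) -> Trace:
    """Generate one sweep at one flash intensity.

    Mains interference has a random phase per sweep (the 60 Hz line is not
    synchronized to the flash), so pre-onset samples carry only stochastic
    signal and the pre-onset deterministic baseline is exactly zero.
    """
    config = config or TraceConfig()
    rng = np.random.default_rng(rng)
    t = config.time_base()
    v = deterministic_sweep(intensity_log, params, config)
    if params.mains_amp_uV > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        v = v + params.mains_amp_uV * np.sin(2.0 * math.pi * 60.0 * t / 1000.0 + phase)
    if params.noise_sd_uV > 0:
        v = v + rng.normal(0.0, params.noise_sd_uV, size=t.size)
    meta.setdefault("intensity_log", float(intensity_log))
    return Trace(t, v, config.onset_ms, config.fs_hz, meta)


def synth_eye(
    params: ComponentParams,
    stimulus: StimulusSeries | None = None,
    config: TraceConfig | None = None,
    sweeps_per_intensity: int = 5,
    rng: np.random.Generator | int | None = None,
    **meta,
) -> list:
    """One sweep set per intensity for a single eye (same truth, fresh noise)."""
    if sweeps_per_intensity < 5:
        raise ValueError("at least 5 sweeps per intensity are required")
    stimulus = stimulus or make_default_stimulus()
    config = config or TraceConfig()
    rng = np.random.default_rng(rng)
    sweep_sets = []
    for idx, intensity in enumerate(stimulus.intensities_log, start=1):
        sweep_sets.append(
            [
                synth_sweep(intensity, params, config, rng, intensity_index=idx, sweep_index=s, **meta)
                for s in range(1, sweeps_per_intensity + 1)
            ]
        )
    return sweep_sets


# --- cohorts ---------------------------------------------------------------

# Fields drawn per eye that must stay strictly positive.
_POSITIVE_FIELDS = {
    "a_Vmax_uV", "b_Vmax_uV", "a_n", "b_n", "op_amp_uV", "mains_amp_uV",
    "noise_sd_uV", "a_trough_ms", "b_peak_ms", "op_decay_ms", "op_center_ms",
}
_PARAM_FIELDS = {f.name for f in fields(ComponentParams)}


@dataclass(frozen=True)
class GroupSpec:
    """Between-eye distribution of one group: mean params and per-field SDs."""

    name: str
    eyes: int
    means: ComponentParams
    sds: Mapping[str, float] = field(default_factory=dict)
    eyes_per_animal: int = 2

    def __post_init__(self) -> None:
        if self.eyes < 1:
            raise ValueError("eyes must be >= 1")
        unknown = set(self.sds) - _PARAM_FIELDS
        if unknown:
            raise ValueError(f"unknown parameter fields in sds: {sorted(unknown)}")
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError("SDs must be >= 0")

    def draw_params(self, rng: np.random.Generator) -> ComponentParams:
        """Per-eye truth: normal draws, truncated at zero for positive fields."""
        values = {}
        for name, sd in self.sds.items():
            mean = getattr(self.means, name)
            if sd == 0:
                continue
            val = rng.normal(mean, sd)
            if name in _POSITIVE_FIELDS:
                while val <= 0:
                    val = rng.normal(mean, sd)
            values[name] = float(val)
        return replace(self.means, **values) if values else self.means


@dataclass(frozen=True)
class CohortSpec:
    """Full generative description of a two-group study."""

    groups: tuple
    stimulus: StimulusSeries = field(default_factory=make_default_stimulus)
    config: TraceConfig = field(default_factory=TraceConfig)
    sweeps_per_intensity: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweeps_per_intensity < 5:
            raise ValueError("sweeps_per_intensity must be >= 5")
        if len(self.groups) < 1:
            raise ValueError("need at least one group")


@dataclass
class Eye:
    """Traces plus ground truth and QC metadata for one eye."""

    eye_id: str
    animal_id: str
    group: str
    params: ComponentParams
    sweep_sets: list
    qc_flags: tuple = ()


@dataclass
class Cohort:
    """Labeled groups of eyes, with the spec that generated them."""

    spec: CohortSpec
    eyes: list

    def group_eyes(self, name: str) -> list:
        return [e for e in self.eyes if e.group == name]

    @property
    def group_names(self) -> list:
        seen = []
        for e in self.eyes:
            if e.group not in seen:
                seen.append(e.group)
        return seen


def synth_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort; reproducible bit-for-bit from ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    group_seqs = root.spawn(len(spec.groups))
    eyes: list = []
    for gspec, gseq in zip(spec.groups, group_seqs):
        eye_seqs = gseq.spawn(gspec.eyes)
        for i, eseq in enumerate(eye_seqs):
            rng = np.random.default_rng(eseq)
            params = gspec.draw_params(rng)
            animal = f"{gspec.name}_animal{i // gspec.eyes_per_animal + 1:02d}"
            eye_id = f"{gspec.name}_eye{i + 1:02d}"
            sweep_sets = synth_eye(
                params, spec.stimulus, spec.config, spec.sweeps_per_intensity, rng,
                eye_id=eye_id, animal_id=animal, group=gspec.name,
            )
            eyes.append(Eye(eye_id, animal, gspec.name, params, sweep_sets))
    return Cohort(spec=spec, eyes=eyes)


def _group(name: str, eyes: int, a_truth: Mapping[str, tuple], b_Vmax: float, b_n: float, **overrides) -> GroupSpec:
    means = ComponentParams(
        a_Vmax_uV=a_truth["Vmax"][0], a_k_log=a_truth["k_log"][0], a_n=a_truth["n"][0],
        b_Vmax_uV=b_Vmax, b_n=b_n, **overrides,
    )
    sds = {"a_Vmax_uV": a_truth["Vmax"][1], "a_k_log": a_truth["k_log"][1], "a_n": a_truth["n"][1],
           "b_Vmax_uV": 180.0, "b_k_log": 1.15 if name.startswith("CTR") else 0.67, "b_n": 0.12}
    return GroupSpec(name=name, eyes=eyes, means=means, sds=sds)


def default_ctr_group(eyes: int = 15) -> GroupSpec:
    """CTR-like group: 15 eyes, a-wave truth at the control group means."""
    return _group("CTR", eyes, CTR_A_WAVE, b_Vmax=763.9, b_n=0.31, b_k_log=1.46)


def default_vpa_group(eyes: int = 12) -> GroupSpec:
    """VPA-like group: 12 eyes, reduced a-wave Vmax, similar k and n."""
    return _group("VPA", eyes, VPA_A_WAVE, b_Vmax=646.8, b_n=0.34, b_k_log=1.47)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Two-group study at the published group sizes (15 vs 12 eyes)."""
    return CohortSpec(groups=(default_ctr_group(), default_vpa_group()), seed=seed)
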