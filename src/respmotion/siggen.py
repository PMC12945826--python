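"""Synthetic respiratory surrogate signals with clinically motivated amplitude structure.

Generates quasi-periodic multi-axis (SI/AP/LR) displacement traces built on the
Lujan-style breathing model ``z(t) = z0 - b * cos^(2n)(pi*t/tau - phi)``, with
per-cycle amplitude modulation, period jitter, slow baseline drift, transient
cough-like artifacts and additive broadband noise.  Every record carries a
noise-free ground-truth component and a motion label derived from it, so the
full prediction pipeline can be exercised and validated without clinical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np

__all__ = [
    "RespiratorySignal",
    "MotionLabel",
    "GeneratorConfig",
    "CLASS_EDGES_MM",
    "REPRESENTATIVE_MM",
    "EXCESSIVE_THRESHOLD_MM",
    "assign_motion_class",
    "generate_signal",
    "generate_dataset",
]

AXES = ("si", "ap", "lr")

#: Left-closed amplitude bin edges in mm: [0,4) -> 1, [4,6) -> 2, [6,8) -> 3, [8,inf) -> 4.
CLASS_EDGES_MM = (4.0, 6.0, 8.0)

#: Representative (reporting) amplitude per motion class, mm.
REPRESENTATIVE_MM = {1: 3.99, 2: 5.99, 3: 7.99, 4: 10.00}

#: Amplitudes at or above this are flagged as clinically excessive motion, mm.
EXCESSIVE_THRESHOLD_MM = 9.0


@dataclass
class RespiratorySignal:
    """Multi-axis respiratory displacement trace.

    ``samples`` is an ``(n_timepoints, 3)`` array in millimetres with fixed
    axis order (SI, AP, LR).  ``clean_samples``, when present, is the
    noise-free generator component of identical shape.
    """

    signal_id: str
    samples: np.ndarray
    sampling_rate_hz: float
    duration_s: float
    clean_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array (SI, AP, LR)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate_hz and duration_s must be positive")
        n_expected = round(self.duration_s * self.sampling_rate_hz)
        if self.samples.shape[0] != n_expected:
            raise ValueError(
                f"n_timepoints {self.samples.shape[0]} != "
                f"round(duration * rate) = {n_expected}"
            )
        if self.clean_samples is not None:
            self.clean_samples = np.asarray(self.clean_samples, dtype=float)
            if self.clean_samples.shape != self.samples.shape:
                raise ValueError("clean_samples shape differs from samples")
            if not np.all(np.isfinite(self.clean_samples)):
                raise ValueError("clean_samples contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_timepoints) / self.sampling_rate_hz


@dataclass
class MotionLabel:
    """Per-record motion amplitude summary and 4-level amplitude class."""

    erom_mm_per_axis: tuple[float, float, float]
    dominant_amplitude_mm: float
    motion_class: int
    representative_value_mm: float
    excessive: bool

    def __post_init__(self) -> None:
        cls, rep, exc = assign_motion_class(self.dominant_amplitude_mm)
        if (cls, rep, exc) != (
            self.motion_class,
            self.representative_value_mm,
            self.excessive,
        ):
            raise ValueError("label fields inconsistent with dominant amplitude")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["erom_mm_per_axis"] = list(self.erom_mm_per_axis)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MotionLabel":
        return cls(
            erom_mm_per_axis=tuple(d["erom_mm_per_axis"]),
            dominant_amplitude_mm=d["dominant_amplitude_mm"],
            motion_class=d["motion_class"],
            representative_value_mm=d["representative_value_mm"],
            excessive=bool(d["excessive"]),
        )

    @classmethod
    def from_amplitudes(cls, erom_mm_per_axis) -> "MotionLabel":
        erom = tuple(float(a) for a in erom_mm_per_axis)
        dom = max(erom)
        mc, rep, exc = assign_motion_class(dom)
        return cls(erom, dom, mc, rep, exc)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic breathing-signal generator.

    Amplitude-related values are millimetres, times are seconds.  The default
    sampling rate of 20 Hz makes the 50-500 ms latency horizons whole numbers
    of samples (1 to 10).
    """

    n_signals: int = 100
    class_mixture: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    sampling_rate_hz: float = 20.0
    duration_s: float = 120.0
    period_mean_s: float = 4.0
    period_sd_s: float = 0.5
    waveform_exponent: int = 2
    axis_ratios: tuple[float, float] = (0.4, 0.3)  # AP, LR as fractions of SI
    am_depth: float = 0.1               # per-cycle amplitude modulation depth
    am_period_s: float = 30.0
    period_jitter_cv: float = 0.05      # per-cycle period jitter (CV)
    drift_amplitude_mm: float = 0.3
    drift_period_s: float = 60.0
    artifact_rate: float = 0.2          # expected transients per 120 s
    artifact_amp_range_mm: tuple[float, float] = (1.0, 3.0)
    artifact_width_range_s: tuple[float, float] = (0.2, 0.5)
    noise_sd_mm: float = 0.05
    segments_per_patient: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_signals <= 0:
            raise ValueError("n_signals must be positive")
        w = np.asarray(self.class_mixture, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("class_mixture must be 4 non-negative weights, not all zero")
        for name in (
            "sampling_rate_hz", "duration_s", "period_mean_s", "waveform_exponent",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "period_sd_s", "am_depth", "period_jitter_cv", "drift_amplitude_mm",
            "drift_period_s", "artifact_rate", "noise_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(r < 0 for r in self.axis_ratios):
            raise ValueError("axis_ratios must be non-negative")
        n_50ms = self.sampling_rate_hz * 0.05
        if abs(n_50ms - round(n_50ms)) > 1e-9 or round(n_50ms) < 1:
            raise ValueError(
                "sampling_rate_hz * 0.05 s must be a whole number of samples >= 1"
            )
        if self.segments_per_patient < 1:
            raise ValueError("segments_per_patient must be >= 1")

    @property
    def normalized_mixture(self) -> np.ndarray:
        w = np.asarray(self.class_mixture, dtype=float)
        return w / w.sum()


def assign_motion_class(amplitude_mm: float) -> tuple[int, float, bool]:
    """Map a peak-to-trough amplitude (mm) to (motion class, representative mm, excessive).

    Bins are left-closed: [0,4) -> 1, [4,6) -> 2, [6,8) -> 3, [8,inf) -> 4.
    Amplitudes >= 9 mm additionally carry the excessive-motion flag.
    """
    amplitude_mm = float(amplitude_mm)
    if not np.isfinite(amplitude_mm) or amplitude_mm < 0:
        raise ValueError("amplitude must be finite and non-negative")
    motion_class = 1 + int(np.searchsorted(CLASS_EDGES_MM, amplitude_mm, side="right"))
    return (
        motion_class,
        REPRESENTATIVE_MM[motion_class],
        amplitude_mm >= EXCESSIVE_THRESHOLD_MM,
    )


def _label_from_clean(signal: RespiratorySignal, nominal_period_s: float) -> MotionLabel:
    """Derive the motion label from the clean trace via per-cycle EROM."""
    from .preprocess import segment_cycles  # deferred: avoids a module cycle

    clean = signal.clean_samples if signal.clean_samples is not None else signal.samples
    clean_sig = RespiratorySignal(
        signal.signal_id, clean, signal.sampling_rate_hz, signal.duration_s
    )
    seg = segment_cycles(clean_sig, nominal_period_s=nominal_period_s)
    if seg.erom_mm.shape[0] == 0:
        # no complete cycle found: fall back to the whole-record range
        erom = clean.max(axis=0) - clean.min(axis=0)
    else:
        erom = seg.erom_mm.mean(axis=0)
    return MotionLabel.from_amplitudes(erom)


def generate_signal(
    target_amplitude_mm: float,
    config: GeneratorConfig,
    seed: int,
    signal_id: str = "S0",
) -> tuple[RespiratorySignal, MotionLabel]:
    """Generate one labelled record with SI peak-to-trough amplitude near the target.

    The SI-axis mean per-cycle EROM tracks ``target_amplitude_mm`` to within the
    configured irregularity; AP and LR are scaled copies per ``axis_ratios``.
    The label is measured on the clean trace, not assumed from the target.
    Identical ``(target, config, seed)`` produce bit-identical output.
    """
    if not np.isfinite(target_amplitude_mm) or target_amplitude_mm <= 0:
        raise ValueError("target_amplitude_mm must be positive and finite")
    config.validate()
    if config.duration_s < config.period_mean_s:
        raise ValueError("duration shorter than one breathing period")

    rng = np.random.default_rng(seed)
    fs = config.sampling_rate_hz
    n = round(config.duration_s * fs)
    t = np.arange(n) / fs
    n_exp = 2 * config.waveform_exponent

    # record-level base period
    tau = config.period_mean_s + config.period_sd_s * rng.standard_normal()
    tau = float(np.clip(tau, 0.5 * config.period_mean_s, config.duration_s))

    # phase as a whole-sample circular offset so that with all irregularity off
    # the waveform extrema stay on the sampling grid
    period_samples = max(1, round(tau * fs))
    t0 = int(rng.integers(0, period_samples)) / fs

    # cycle boundaries with per-cycle period jitter
    boundaries = [0.0]
    horizon = config.duration_s + t0 + tau
    while boundaries[-1] < horizon:
        p = tau * (1.0 + config.period_jitter_cv * rng.standard_normal())
        p = max(p, 0.3 * tau)
        boundaries.append(boundaries[-1] + p)
    boundaries = np.asarray(boundaries)
    periods = np.diff(boundaries)

    # per-cycle amplitude modulation (amplitude held constant within a cycle,
    # so the per-cycle EROM of the core waveform is exactly the cycle amplitude)
    psi_am = rng.uniform(0.0, 2.0 * np.pi)
    cycle_amp = target_amplitude_mm * (
        1.0 + config.am_depth
        * np.sin(2.0 * np.pi * boundaries[:-1] / config.am_period_s + psi_am)
    )
    cycle_amp = np.maximum(cycle_amp, 0.05 * target_amplitude_mm)

    a = t + t0
    c_idx = np.clip(np.searchsorted(boundaries, a, side="right") - 1, 0, len(periods) - 1)
    u = np.pi * (a - boundaries[c_idx]) / periods[c_idx]
    core = -cycle_amp[c_idx] * np.cos(u) ** n_exp

    psi_d = rng.uniform(0.0, 2.0 * np.pi)
    drift = config.drift_amplitude_mm * np.sin(
        2.0 * np.pi * t / config.drift_period_s + psi_d
    )

    ratios = np.array([1.0, config.axis_ratios[0], config.axis_ratios[1]])
    clean = (core + drift)[:, None] * ratios[None, :]

    # transient (cough-like) artifacts enter the observed trace only
    n_art = rng.poisson(config.artifact_rate * config.duration_s / 120.0)
    artifact = np.zeros(n)
    for _ in range(n_art):
        center = rng.uniform(0.0, config.duration_s)
        amp = rng.uniform(*config.artifact_amp_range_mm)
        width = rng.uniform(*config.artifact_width_range_s)
        artifact += amp * np.exp(-0.5 * ((t - center) / width) ** 2)

    noise = rng.normal(0.0, config.noise_sd_mm, size=(n, 3))
    samples = clean + artifact[:, None] * ratios[None, :] + noise

    signal = RespiratorySignal(
        signal_id=signal_id,
        samples=samples,
        sampling_rate_hz=fs,
        duration_s=config.duration_s,
        clean_samples=clean,
    )
    label = _label_from_clean(signal, nominal_period_s=config.period_mean_s)
    return signal, label


# Target amplitudes per class are drawn uniformly inside the class's bin;
# class 4 spans 8-15 mm (free-breathing lung motion commonly reaches 10-15 mm)
# and class 1 starts at 0.5 mm, below which breathing would vanish into the
# generator's drift/noise floor.
_CLASS_AMPLITUDE_RANGES = {1: (0.5, 4.0), 2: (4.0, 6.0), 3: (6.0, 8.0), 4: (8.0, 15.0)}


def _record_seed(master_seed: int, *counters: int) -> int:
    """Counter-scheme substream: stable derived seed below 2**31."""
    key = [int(master_seed) & 0x7FFFFFFF, *[int(c) for c in counters]]
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[tuple[RespiratorySignal, MotionLabel]], list[dict]]:
    """Generate ``config.n_signals`` labelled records plus a manifest.

    Classes are drawn from ``class_mixture``; target amplitudes uniformly
    within each class's bin.  Records are grouped into synthetic patients of
    ``segments_per_patient`` consecutive segments (segments of one patient
    share the drawn motion class).  Deterministic under a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(_record_seed(config.seed, 0))
    mixture = config.normalized_mixture

    records: list[tuple[RespiratorySignal, MotionLabel]] = []
    manifest: list[dict] = []
    spp = config.segments_per_patient
    n_patients = int(np.ceil(config.n_signals / spp))
    patient_classes = rng.choice(4, size=n_patients, p=mixture) + 1

    for i in range(config.n_signals):
        patient = i // spp
        segment = i % spp
        target_class = int(patient_classes[patient])
        lo, hi = _CLASS_AMPLITUDE_RANGES[target_class]
        # independent substreams for the amplitude draw and the waveform
        amp_rng = np.random.default_rng(_record_seed(config.seed, i + 1, 0))
        rec_seed = _record_seed(config.seed, i + 1, 1)
        target_amp = float(amp_rng.uniform(lo, hi))
        signal_id = f"P{patient:05d}S{segment:02d}"
        sig, label = generate_signal(
            target_amp, config, seed=rec_seed, signal_id=signal_id
        )
        records.append((sig, label))
        manifest.append(
            {
                "signal_id": signal_id,
                "patient_id": f"P{patient:05d}",
                "seed": rec_seed,
                "target_class": target_class,
                "target_amplitude_mm": target_amp,
                "motion_class": label.motion_class,
                "excessive": bool(label.excessive),
            }
        )
    return records, manifest


def manifest_json(manifest: list[dict]) -> str:
    """Canonical JSON rendering of a dataset manifest (stable across runs)."""
    return json.dumps(manifest, indent=2, sort_keys=True)
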