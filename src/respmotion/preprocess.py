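"""Signal conditioning: wavelet denoising, cycle segmentation, normalization, windowing.

Denoising uses a per-axis multilevel discrete wavelet transform with
soft universal thresholding of the detail coefficients (threshold
``sigma * sqrt(2 ln N)``, with ``sigma`` estimated from the finest detail level
by the median absolute deviation).  Breathing cycles are delimited by
successive end-exhale troughs.  Records are min-max normalized to [0,1] per
axis, and converted into sliding-window supervised examples carrying a
motion-class target, future positions at each latency horizon, the clean
window as reconstruction target and the excessive-motion flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pywt
from scipy.signal import find_peaks

from .siggen import RespiratorySignal, MotionLabel

__all__ = [
    "WaveletConfig",
    "WindowSpec",
    "CycleSegmentation",
    "NormalizationTransform",
    "WindowedDataset",
    "dwt_denoise",
    "segment_cycles",
    "normalize",
    "make_windows",
    "build_windowed_dataset",
]


@dataclass
class WaveletConfig:
    """Discrete wavelet transform settings for denoising."""

    wavelet_name: str = "db4"
    level: int = 4
    threshold_rule: str = "soft-universal"  # or "none"
    boundary_mode: str = "symmetric"

    def validate(self, n_samples: int | None = None) -> None:
        if self.wavelet_name not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet name: {self.wavelet_name!r}")
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.threshold_rule not in ("soft-universal", "none"):
            raise ValueError(f"unknown threshold rule: {self.threshold_rule!r}")
        if n_samples is not None and 2**self.level > n_samples:
            raise ValueError(
                f"level {self.level} infeasible for signal length {n_samples}"
            )


def dwt_denoise(signal: RespiratorySignal, config: WaveletConfig | None = None) -> RespiratorySignal:
    """Wavelet-denoise each axis; approximation coefficients are left untouched.

    With ``threshold_rule == "none"`` this is the identity up to the DWT's
    perfect-reconstruction round-off.  ``clean_samples`` pass through unchanged.
    """
    config = config or WaveletConfig()
    n = signal.n_timepoints
    config.validate(n)
    out = np.empty_like(signal.samples)
    for axis in range(3):
        x = signal.samples[:, axis]
        coeffs = pywt.wavedec(
            x, config.wavelet_name, level=config.level, mode=config.boundary_mode
        )
        if config.threshold_rule == "soft-universal":
            finest = coeffs[-1]
            sigma = np.median(np.abs(finest)) / 0.6745
            thr = sigma * np.sqrt(2.0 * np.log(n))
            coeffs = [coeffs[0]] + [
                pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]
            ]
        rec = pywt.waverec(coeffs, config.wavelet_name, mode=config.boundary_mode)
        out[:, axis] = rec[:n]
    return RespiratorySignal(
        signal_id=signal.signal_id,
        samples=out,
        sampling_rate_hz=signal.sampling_rate_hz,
        duration_s=signal.duration_s,
        clean_samples=None if signal.clean_samples is None else signal.clean_samples.copy(),
    )


@dataclass
class CycleSegmentation:
    """Trough-to-trough breathing cycles and their per-axis ranges of motion."""

    intervals: list[tuple[int, int]]          # [start, end] sample indices, inclusive
    erom_mm: np.ndarray                       # (n_cycles, 3) max - min per axis
    trough_indices: np.ndarray                # detected end-exhale troughs
    dominant_axis: int

    @property
    def n_cycles(self) -> int:
        return len(self.intervals)

    @property
    def mean_erom_mm(self) -> np.ndarray:
        if self.n_cycles == 0:
            return np.zeros(3)
        return self.erom_mm.mean(axis=0)

    @property
    def median_erom_mm(self) -> np.ndarray:
        if self.n_cycles == 0:
            return np.zeros(3)
        return np.median(self.erom_mm, axis=0)


def segment_cycles(
    signal: RespiratorySignal,
    nominal_period_s: float = 4.0,
    min_separation_fraction: float = 0.5,
    prominence_fraction: float = 0.1,
) -> CycleSegmentation:
    """Delimit breathing cycles by successive end-exhale troughs.

    Troughs are local minima of the dominant axis (largest peak-to-peak range)
    with a minimum separation of ``min_separation_fraction * nominal_period_s``
    and a prominence of at least ``prominence_fraction`` of the record's
    amplitude range.  Fewer than two troughs yield an empty segmentation.
    """
    x = signal.samples
    ranges = x.max(axis=0) - x.min(axis=0)
    dominant = int(np.argmax(ranges))
    trace = x[:, dominant]
    amp_range = ranges[dominant]
    distance = max(
        1, round(min_separation_fraction * nominal_period_s * signal.sampling_rate_hz)
    )
    prominence = prominence_fraction * amp_range if amp_range > 0 else None
    troughs, _ = find_peaks(-trace, distance=distance, prominence=prominence)

    intervals: list[tuple[int, int]] = []
    eroms: list[np.ndarray] = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        seg = x[a : b + 1]
        intervals.append((int(a), int(b)))
        eroms.append(seg.max(axis=0) - seg.min(axis=0))
    erom = np.asarray(eroms) if eroms else np.zeros((0, 3))
    return CycleSegmentation(intervals, erom, troughs, dominant)


@dataclass
class NormalizationTransform:
    """Invertible per-axis min-max map of a record onto [0,1].

    The range is the union of the observed and (if present) clean traces, so
    both share one transform.  A constant axis is flagged degenerate and maps
    to 0.5 everywhere.
    """

    lo: np.ndarray                 # (3,)
    hi: np.ndarray                 # (3,)
    degenerate: np.ndarray         # (3,) bool

    EPS = 1e-12

    def apply(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.degenerate, 1.0, self.hi - self.lo)
        out = (x - self.lo) / span
        return np.where(self.degenerate, 0.5, out)

    def invert(self, y: np.ndarray) -> np.ndarray:
        span = np.where(self.degenerate, 1.0, self.hi - self.lo)
        out = y * span + self.lo
        return np.where(self.degenerate, self.lo, out)

    @property
    def span_mm(self) -> np.ndarray:
        return np.where(self.degenerate, 0.0, self.hi - self.lo)

    def to_dict(self) -> dict:
        return {
            "lo": self.lo.tolist(),
            "hi": self.hi.tolist(),
            "degenerate": self.degenerate.astype(bool).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationTransform":
        return cls(
            np.asarray(d["lo"], dtype=float),
            np.asarray(d["hi"], dtype=float),
            np.asarray(d["degenerate"], dtype=bool),
        )


def normalize(
    signal: RespiratorySignal,
) -> tuple[RespiratorySignal, NormalizationTransform]:
    """Min-max map each axis of a record (noisy and clean jointly) onto [0,1]."""
    stack = signal.samples
    if signal.clean_samples is not None:
        stack = np.vstack([signal.samples, signal.clean_samples])
    lo = stack.min(axis=0)
    hi = stack.max(axis=0)
    degenerate = (hi - lo) < NormalizationTransform.EPS
    transform = NormalizationTransform(lo=lo, hi=hi, degenerate=degenerate)
    normed = RespiratorySignal(
        signal_id=signal.signal_id,
        samples=transform.apply(signal.samples),
        sampling_rate_hz=signal.sampling_rate_hz,
        duration_s=signal.duration_s,
        clean_samples=None
        if signal.clean_samples is None
        else transform.apply(signal.clean_samples),
    )
    return normed, transform


#: Fixed full scale (mm) used to embed the record's measured amplitude as a
#: bounded context feature.  20 mm comfortably exceeds free-breathing motion.
AMPLITUDE_FULL_SCALE_MM = 20.0

LATENCY_BIN_LABELS = ("40-50", "100-150", "200-300", "400-500")


@dataclass
class WindowSpec:
    """Sliding-window layout and prediction horizons (in samples)."""

    window_len_samples: int = 120          # 6 s at 20 Hz
    horizons_samples: tuple[int, ...] = (1, 3, 6, 10)
    horizon_latency_ms_bins: tuple[str, ...] = LATENCY_BIN_LABELS
    stride: int = 1
    amplitude_context: bool = True         # append per-record amplitude channel
    nominal_period_s: float = 4.0

    def validate(self, n_samples: int | None = None) -> None:
        if self.window_len_samples < 1 or self.stride < 1:
            raise ValueError("window length and stride must be positive")
        h = self.horizons_samples
        if len(h) == 0 or any(b <= a for a, b in zip(h, h[1:])) or h[0] < 1:
            raise ValueError("horizons must be strictly increasing positive integers")
        if len(self.horizon_latency_ms_bins) != len(h):
            raise ValueError("one latency-bin label per horizon is required")
        if n_samples is not None and self.window_len_samples + max(h) > n_samples:
            raise ValueError(
                f"window ({self.window_len_samples}) + max horizon ({max(h)}) "
                f"exceeds signal length {n_samples}"
            )

    def n_windows(self, n_samples: int) -> int:
        usable = n_samples - self.window_len_samples - max(self.horizons_samples)
        if usable < 0:
            return 0
        return usable // self.stride + 1


@dataclass
class WindowedDataset:
    """Supervised examples: input windows with class / future-position /
    reconstruction / excessive targets, all in normalized units.

    ``inputs`` is ``(n, window_len, n_channels)`` with channels
    (SI, AP, LR[, amplitude context]).  ``future`` is ``(n, 3, n_horizons)``
    clean-trace positions at each horizon past the window end; ``recon`` is the
    clean window ``(n, window_len, 3)``.
    """

    inputs: np.ndarray
    class_index: np.ndarray        # (n,) int in 0..3  (motion class - 1)
    future: np.ndarray             # (n, 3, n_horizons)
    recon: np.ndarray              # (n, window_len, 3)
    excessive: np.ndarray          # (n,) float 0/1
    record_ids: np.ndarray         # (n,) str
    window_starts: np.ndarray      # (n,) int
    spec: WindowSpec
    transforms: dict = field(default_factory=dict)     # record_id -> NormalizationTransform
    amplitudes_mm: dict = field(default_factory=dict)  # record_id -> measured EROM (mm)

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.inputs.shape[2]

    @property
    def window_len(self) -> int:
        return self.inputs.shape[1]

    @property
    def horizons(self) -> tuple[int, ...]:
        return tuple(self.spec.horizons_samples)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        ids = set(np.asarray(self.record_ids)[idx].tolist())
        return WindowedDataset(
            inputs=self.inputs[idx],
            class_index=self.class_index[idx],
            future=self.future[idx],
            recon=self.recon[idx],
            excessive=self.excessive[idx],
            record_ids=self.record_ids[idx],
            window_starts=self.window_starts[idx],
            spec=self.spec,
            transforms={k: v for k, v in self.transforms.items() if k in ids},
            amplitudes_mm={k: v for k, v in self.amplitudes_mm.items() if k in ids},
        )

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        spec = parts[0].spec
        transforms: dict = {}
        amplitudes: dict = {}
        for p in parts:
            transforms.update(p.transforms)
            amplitudes.update(p.amplitudes_mm)
        return WindowedDataset(
            inputs=np.concatenate([p.inputs for p in parts]),
            class_index=np.concatenate([p.class_index for p in parts]),
            future=np.concatenate([p.future for p in parts]),
            recon=np.concatenate([p.recon for p in parts]),
            excessive=np.concatenate([p.excessive for p in parts]),
            record_ids=np.concatenate([p.record_ids for p in parts]),
            window_starts=np.concatenate([p.window_starts for p in parts]),
            spec=spec,
            transforms=transforms,
            amplitudes_mm=amplitudes,
        )

    def save(self, path) -> None:
        """Write a single-file archive plus an embedded JSON schema descriptor."""
        descriptor = {
            "format": "respmotion.windowed_dataset",
            "version": 1,
            "spec": asdict(self.spec),
            "transforms": {k: v.to_dict() for k, v in self.transforms.items()},
            "amplitudes_mm": {k: float(v) for k, v in self.amplitudes_mm.items()},
        }
        np.savez_compressed(
            path,
            inputs=self.inputs,
            class_index=self.class_index,
            future=self.future,
            recon=self.recon,
            excessive=self.excessive,
            record_ids=self.record_ids.astype(str),
            window_starts=self.window_starts,
            descriptor=np.frombuffer(
                json.dumps(descriptor).encode("utf-8"), dtype=np.uint8
            ),
        )

    @classmethod
    def load(cls, path) -> "WindowedDataset":
        with np.load(path, allow_pickle=False) as z:
            descriptor = json.loads(bytes(z["descriptor"].tobytes()).decode("utf-8"))
            if descriptor.get("format") != "respmotion.windowed_dataset":
                raise ValueError("not a respmotion windowed-dataset archive")
            spec_d = descriptor["spec"]
            spec = WindowSpec(
                window_len_samples=spec_d["window_len_samples"],
                horizons_samples=tuple(spec_d["horizons_samples"]),
                horizon_latency_ms_bins=tuple(spec_d["horizon_latency_ms_bins"]),
                stride=spec_d["stride"],
                amplitude_context=spec_d["amplitude_context"],
                nominal_period_s=spec_d["nominal_period_s"],
            )
            return cls(
                inputs=z["inputs"],
                class_index=z["class_index"],
                future=z["future"],
                recon=z["recon"],
                excessive=z["excessive"],
                record_ids=z["record_ids"].astype(str),
                window_starts=z["window_starts"],
                spec=spec,
                transforms={
                    k: NormalizationTransform.from_dict(v)
                    for k, v in descriptor["transforms"].items()
                },
                amplitudes_mm=descriptor["amplitudes_mm"],
            )


def make_windows(
    signal: RespiratorySignal, label: MotionLabel, spec: WindowSpec
) -> WindowedDataset:
    """Convert one (typically denoised) record into supervised window examples.

    The record is min-max normalized (one transform shared by inputs and all
    targets).  Each window of length ``W`` starting at ``t0`` yields the clean
    future positions at ``t0 + W - 1 + h`` for every horizon ``h``, and the
    aligned clean window as reconstruction target.  When
    ``spec.amplitude_context`` is set, a constant fourth channel carries the
    record's amplitude measured from the observed (denoised) trace — median
    per-cycle dominant-axis EROM scaled by a fixed 20 mm full scale — restoring
    the absolute-scale information that per-record normalization removes.
    """
    n = signal.n_timepoints
    spec.validate(n)
    hmax = max(spec.horizons_samples)
    W = spec.window_len_samples

    # record-level amplitude measured from the observed trace (no clean access);
    # the median over cycles resists transient-artifact inflation
    seg = segment_cycles(signal, nominal_period_s=spec.nominal_period_s)
    if seg.n_cycles > 0:
        amp_mm = float(seg.median_erom_mm.max())
    else:
        amp_mm = float((signal.samples.max(axis=0) - signal.samples.min(axis=0)).max())

    normed, transform = normalize(signal)
    x = normed.samples
    clean = normed.clean_samples if normed.clean_samples is not None else x

    starts = np.arange(0, n - W - hmax + 1, spec.stride)
    n_win = len(starts)
    offs = np.arange(W)
    idx = starts[:, None] + offs[None, :]          # (n_win, W)
    inputs = x[idx].astype(np.float32)             # (n_win, W, 3)
    recon = clean[idx].astype(np.float32)

    if spec.amplitude_context:
        ctx = min(amp_mm / AMPLITUDE_FULL_SCALE_MM, 1.0)
        ctx_channel = np.full((n_win, W, 1), ctx, dtype=np.float32)
        inputs = np.concatenate([inputs, ctx_channel], axis=2)

    last = starts + W - 1
    future = np.empty((n_win, 3, len(spec.horizons_samples)), dtype=np.float32)
    for j, h in enumerate(spec.horizons_samples):
        future[:, :, j] = clean[last + h]

    return WindowedDataset(
        inputs=inputs,
        class_index=np.full(n_win, label.motion_class - 1, dtype=np.int64),
        future=future,
        recon=recon,
        excessive=np.full(n_win, float(label.excessive), dtype=np.float32),
        record_ids=np.full(n_win, signal.signal_id, dtype=object).astype(str),
        window_starts=starts.astype(np.int64),
        spec=spec,
        transforms={signal.signal_id: transform},
        amplitudes_mm={signal.signal_id: amp_mm},
    )


def build_windowed_dataset(
    records: list[tuple[RespiratorySignal, MotionLabel]],
    spec: WindowSpec,
    wavelet: WaveletConfig | None = None,
) -> WindowedDataset:
    """Denoise (optional) and window a list of labelled records into one dataset."""
    parts = []
    for sig, label in records:
        if wavelet is not None:
            sig = dwt_denoise(sig, wavelet)
        parts.append(make_windows(sig, label, spec))
    return WindowedDataset.concatenate(parts)
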