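"""File formats and run configuration.

Signals travel as delimited text with header
``time_s,si_mm,ap_mm,lr_mm[,clean_si_mm,clean_ap_mm,clean_lr_mm]`` and a JSON
label sidecar; datasets are tied together by a JSON manifest.  Numeric I/O
round-trips at 12+ significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .siggen import GeneratorConfig, MotionLabel, RespiratorySignal
from .preprocess import WaveletConfig, WindowSpec
from .nn.model import NetConfig

__all__ = [
    "write_signal_csv",
    "read_signal_csv",
    "write_label_json",
    "read_label_json",
    "save_dataset",
    "load_dataset",
    "patient_split",
    "RunConfig",
    "setup_logging",
]

REQUIRED_COLUMNS = ("time_s", "si_mm", "ap_mm", "lr_mm")
CLEAN_COLUMNS = ("clean_si_mm", "clean_ap_mm", "clean_lr_mm")


def write_signal_csv(signal: RespiratorySignal, path) -> None:
    """Write a signal as CSV; clean columns are included when present."""
    data = {
        "time_s": signal.time_s,
        "si_mm": signal.samples[:, 0],
        "ap_mm": signal.samples[:, 1],
        "lr_mm": signal.samples[:, 2],
    }
    if signal.clean_samples is not None:
        for j, col in enumerate(CLEAN_COLUMNS):
            data[col] = signal.clean_samples[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.14g")


def read_signal_csv(path, signal_id: str | None = None) -> RespiratorySignal:
    """Read a signal CSV, validating schema, numeric cells and time monotonicity.

    Unknown columns are tolerated and ignored.  Errors name the offending
    column or (1-based data) row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path.name}: file is empty") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path.name}: no data rows")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    use_clean = all(c in df.columns for c in CLEAN_COLUMNS)
    cols = list(REQUIRED_COLUMNS) + (list(CLEAN_COLUMNS) if use_clean else [])
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path.name}: non-numeric value in {col!r} at row {row}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0]) + 1
            raise ValueError(f"{path.name}: missing value in {col!r} at row {row}")
        df[col] = numeric

    t = df["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0]) + 2
            raise ValueError(f"{path.name}: non-monotone time_s at row {row}")
        fs = 1.0 / float(np.median(dt))
    else:
        fs = 1.0
    samples = df[["si_mm", "ap_mm", "lr_mm"]].to_numpy(dtype=float)
    clean = df[list(CLEAN_COLUMNS)].to_numpy(dtype=float) if use_clean else None
    n = len(df)
    return RespiratorySignal(
        signal_id=signal_id or path.stem,
        samples=samples,
        sampling_rate_hz=fs,
        duration_s=n / fs,
        clean_samples=clean,
    )


def write_label_json(label: MotionLabel, path) -> None:
    with open(path, "w") as fh:
        json.dump(label.to_dict(), fh, indent=2, sort_keys=True)


def read_label_json(path) -> MotionLabel:
    with open(path) as fh:
        return MotionLabel.from_dict(json.load(fh))


def save_dataset(records, manifest, outdir) -> Path:
    """Write signal CSVs, label sidecars and the manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for (signal, label), meta in zip(records, manifest):
        sig_path = outdir / f"{signal.signal_id}.csv"
        lab_path = outdir / f"{signal.signal_id}.label.json"
        write_signal_csv(signal, sig_path)
        write_label_json(label, lab_path)
        entries.append(
            {**meta, "signal_path": sig_path.name, "label_path": lab_path.name}
        )
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
    return manifest_path


def load_dataset(manifest_path):
    """Load all (signal, label) records referenced by a manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        entries = json.load(fh)
    base = manifest_path.parent
    records = []
    for e in entries:
        sig = read_signal_csv(base / e["signal_path"], signal_id=e["signal_id"])
        lab = read_label_json(base / e["label_path"])
        records.append((sig, lab))
    return records, entries


def patient_split(patient_ids, test_fraction: float, seed: int):
    """Deterministic patient-wise split; no patient straddles the boundary."""
    unique = sorted(set(patient_ids))
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    n_test = max(1, int(round(test_fraction * len(unique))))
    n_test = min(n_test, len(unique) - 1) if len(unique) > 1 else n_test
    test = {unique[i] for i in perm[:n_test]}
    train = {u for u in unique if u not in test}
    return train, test


@dataclass
class RunConfig:
    """Nested configuration of a full pipeline run (simulate to evaluate)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    windows: WindowSpec = field(default_factory=WindowSpec)
    net: NetConfig = field(default_factory=NetConfig)
    output_dir: str = "runs/run"
    master_seed: int = 1
    train_fraction: float = 0.8

    def validate(self) -> None:
        self.generator.validate()
        self.wavelet.validate()
        self.windows.validate()
        self.net.validate()
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(dc_type, payload):
            if payload is None:
                return dc_type()
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - names
            if unknown:
                raise ValueError(f"unknown {dc_type.__name__} fields: {sorted(unknown)}")
            kwargs = {}
            for f in dataclasses.fields(dc_type):
                if f.name in payload:
                    v = payload[f.name]
                    if isinstance(v, list):
                        v = tuple(v)
                    kwargs[f.name] = v
            return dc_type(**kwargs)

        return cls(
            generator=build(GeneratorConfig, d.get("generator")),
            wavelet=build(WaveletConfig, d.get("wavelet")),
            windows=build(WindowSpec, d.get("windows")),
            net=build(NetConfig, d.get("net")),
            output_dir=d.get("output_dir", "runs/run"),
            master_seed=d.get("master_seed", 1),
            train_fraction=d.get("train_fraction", 0.8),
        )

    @classmethod
    def from_json_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


class _JsonLinesHandler(logging.Handler):
    def __init__(self, path):
        super().__init__()
        self._fh = open(path, "a")

    def emit(self, record):
        entry = {
            "ts": time.strftime("%Y-%m-%dT%H:%M:%S", time.localtime(record.created)),
            "level": record.levelname,
            "message": record.getMessage(),
        }
        self._fh.write(json.dumps(entry) + "\n")
        self._fh.flush()

    def close(self):
        self._fh.close()
        super().close()


def setup_logging(run_dir, name: str = "respmotion") -> logging.Logger:
    """Timestamped, level-tagged text log plus machine-readable JSON-lines log."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger(f"{name}.{run_dir.name}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s [%(levelname)s] %(message)s")
    fh = logging.FileHandler(run_dir / "run.log")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    logger.addHandler(_JsonLinesHandler(run_dir / "run.jsonl"))
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    logger.propagate = False
    return logger
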