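"""Recording data model, epoching, and CSV/EDF input-output.

The study design records 20 scalp EEG channels (10-20 system, 250 Hz,
microvolts) and a single wrist EDA channel (4 Hz, microsiemens) for each
(subject, round, condition) presentation plus one resting baseline per
subject.  Seventeen of the EEG channels enter feature extraction; the
occipital pair (O1, O2) and FC1 are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("baseline", "low", "medium", "high")
#: The three presence classes, in fixed label order.
CLASSES = ("low", "medium", "high")

#: 20-channel montage (FCz reference, FPz ground).
MONTAGE_20 = (
    "FP1", "FP2", "F3", "F4", "F7", "F8", "FT9", "FT10",
    "FC1", "FC2", "FC5", "FC6", "P3", "P4", "P7", "P8",
    "O1", "O2", "Fz", "Pz",
)

#: The 17 channels used for feature extraction, in registry order.
FEATURE_CHANNELS = (
    "F3", "F4", "F7", "F8", "FP1", "FP2", "FT9", "FT10", "Fz",
    "FC2", "FC5", "FC6", "P3", "P4", "P7", "P8", "Pz",
)

#: Scalp region of every montage channel.
REGION_MAP = {
    "FP1": "prefrontal", "FP2": "prefrontal",
    "F3": "frontal", "F4": "frontal", "F7": "frontal", "F8": "frontal",
    "FT9": "fronto-temporal", "FT10": "fronto-temporal",
    "FC1": "central-frontal", "FC2": "central-frontal",
    "FC5": "central-frontal", "FC6": "central-frontal",
    "Fz": "mid-frontal",
    "P3": "parietal", "P4": "parietal", "P7": "parietal", "P8": "parietal",
    "Pz": "mid-parietal",
    "O1": "occipital", "O2": "occipital",
}

_CANONICAL = {name.upper(): name for name in MONTAGE_20}


def canonical_channel(label: str) -> str:
    """Normalise a channel label to its canonical 10-20 case (``FZ`` -> ``Fz``)."""
    return _CANONICAL.get(label.strip().upper(), label.strip())


def _check_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise ValueError(
            f"condition must be one of {CONDITIONS}, got {condition!r}"
        )
    return condition


@dataclass
class EegRecording:
    """Multichannel EEG time series in microvolts.

    ``samples`` is a (channels, time) array; rows follow ``channel_labels``.
    """

    subject_id: str
    condition: str
    round_index: int
    channel_labels: list[str]
    samples: np.ndarray
    sampling_rate: float = 250.0
    provenance: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_labels = [canonical_channel(c) for c in self.channel_labels]
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but "
                f"{self.samples.shape[0]} sample rows"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        label = canonical_channel(label)
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None
        return self.samples[idx]

    def copy_with(self, samples: np.ndarray, stage: str | None = None,
                  **params) -> "EegRecording":
        """Return a copy carrying new samples and an extended provenance log."""
        log = list(self.provenance)
        if stage is not None:
            log.append({"stage": stage, **params})
        return EegRecording(
            subject_id=self.subject_id,
            condition=self.condition,
            round_index=self.round_index,
            channel_labels=list(self.channel_labels),
            samples=samples,
            sampling_rate=self.sampling_rate,
            provenance=log,
        )


@dataclass
class EdaRecording:
    """Single-channel skin conductance time series in microsiemens."""

    subject_id: str
    condition: str
    round_index: int
    conductance: np.ndarray
    sampling_rate: float = 4.0

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.conductance = np.asarray(self.conductance, dtype=float).ravel()
        if self.conductance.size == 0:
            raise ValueError("conductance series is empty")

    @property
    def n_samples(self) -> int:
        return self.conductance.size

    def copy_with(self, conductance: np.ndarray) -> "EdaRecording":
        return EdaRecording(
            subject_id=self.subject_id,
            condition=self.condition,
            round_index=self.round_index,
            conductance=conductance,
            sampling_rate=self.sampling_rate,
        )


@dataclass
class EpochGrid:
    """5-s, 30 %-overlap analysis windows as 0-based half-open sample pairs."""

    window_seconds: float
    overlap_fraction: float
    sampling_rate: float
    windows: list[tuple[int, int]]

    @property
    def hop_seconds(self) -> float:
        return self.window_seconds * (1.0 - self.overlap_fraction)

    @property
    def n_epochs(self) -> int:
        return len(self.windows)

    def slices(self):
        return [slice(s, e) for s, e in self.windows]


def make_epochs(n_samples: int, sampling_rate: float,
                window_seconds: float = 5.0,
                overlap_fraction: float = 0.3) -> EpochGrid:
    """Partition a signal into overlapping fixed-length windows.

    Windows are ``[start, start + w)`` in samples with hop
    ``round(window * (1 - overlap) * fs)``; a trailing window that would
    overrun the signal is dropped, so the count is
    ``floor((T - w) / h) + 1``.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    w = int(round(window_seconds * sampling_rate))
    if w < 2:
        raise ValueError("window shorter than 2 samples")
    if n_samples < w:
        raise ValueError(
            f"signal of {n_samples} samples is shorter than one "
            f"{window_seconds}-s window ({w} samples)"
        )
    h = int(round(window_seconds * (1.0 - overlap_fraction) * sampling_rate))
    h = max(h, 1)
    n_win = (n_samples - w) // h + 1
    windows = [(i * h, i * h + w) for i in range(n_win)]
    return EpochGrid(window_seconds, overlap_fraction, sampling_rate, windows)


# ---------------------------------------------------------------------------
# CSV I/O (time_s + one column per channel, JSON metadata sidecar)
# ---------------------------------------------------------------------------

_SIDEKEYS = ("subject_id", "condition", "round", "sampling_rate_hz", "units")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec, path, format: str = "csv") -> Path:
    """Write a recording to CSV (+ JSON sidecar) or EDF."""
    path = Path(path)
    if format == "csv":
        return _write_csv(rec, path)
    if format == "edf":
        return _write_edf(rec, path)
    raise ValueError(f"unknown format {format!r}")


def read_recording(path, kind: str):
    """Read a CSV or EDF recording; ``kind`` selects the returned type."""
    path = Path(path)
    if kind not in ("eeg", "eda"):
        raise ValueError("kind must be 'eeg' or 'eda'")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, kind)
    return _read_csv(path, kind)


def _write_csv(rec, path: Path) -> Path:
    n = rec.n_samples
    time_s = np.arange(n) / rec.sampling_rate
    if isinstance(rec, EegRecording):
        cols = {"time_s": time_s}
        for i, ch in enumerate(rec.channel_labels):
            cols[ch] = rec.samples[i]
        units = "uV"
    else:
        cols = {"time_s": time_s, "EDA": rec.conductance}
        units = "uS"
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False)
    meta = {
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "round": rec.round_index,
        "sampling_rate_hz": rec.sampling_rate,
        "units": units,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def _read_csv(path: Path, kind: str):
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {side}")
    meta = json.loads(side.read_text())
    for key in ("subject_id", "condition", "round", "sampling_rate_hz"):
        if key not in meta:
            raise ValueError(f"{key} missing from sidecar {side}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("CSV lacks a time_s column")
    data_cols = [c for c in df.columns if c != "time_s"]
    if len(set(canonical_channel(c) for c in data_cols)) != len(data_cols):
        raise ValueError("duplicate channel labels in CSV header")
    if kind == "eeg":
        return EegRecording(
            subject_id=str(meta["subject_id"]),
            condition=meta["condition"],
            round_index=int(meta["round"]),
            channel_labels=data_cols,
            samples=df[data_cols].to_numpy().T,
            sampling_rate=float(meta["sampling_rate_hz"]),
        )
    if "EDA" not in df.columns:
        raise ValueError("EDA CSV must contain an 'EDA' column")
    return EdaRecording(
        subject_id=str(meta["subject_id"]),
        condition=meta["condition"],
        round_index=int(meta["round"]),
        conductance=df["EDA"].to_numpy(),
        sampling_rate=float(meta["sampling_rate_hz"]),
    )


# ---------------------------------------------------------------------------
# EDF I/O.  Minimal writer/reader for the standard European Data Format:
# 16-bit samples, 1-s data records.  Subject/condition/round ride in the
# patient and recording identification fields.
# ---------------------------------------------------------------------------


def _write_edf(rec, path: Path) -> Path:
    if isinstance(rec, EegRecording):
        labels = list(rec.channel_labels)
        data = rec.samples
        unit = "uV"
    else:
        labels = ["EDA"]
        data = rec.conductance[None, :]
        unit = "uS"
    fs = rec.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9 or spr < 1:
        raise ValueError("EDF export requires an integer sampling rate")
    n_sig = len(labels)
    n = data.shape[1]
    n_rec = -(-n // spr)  # records of 1 s; last padded with the edge value
    pad = n_rec * spr - n
    if pad:
        data = np.concatenate([data, np.repeat(data[:, -1:], pad, axis=1)], axis=1)

    def fit8(v: float, up: bool) -> str:
        # EDF physical limits live in 8-character ASCII fields; round
        # outward to the widest value whose decimal form fits.
        for prec in range(7, 0, -1):
            s = f"{v:.{prec}g}"
            if len(s) <= 8 and ((float(s) >= v) if up else (float(s) <= v)):
                return s
            nudged = v + (abs(v) + 1.0) * 10.0 ** (-prec) * (1 if up else -1)
            s = f"{nudged:.{prec}g}"
            if len(s) <= 8:
                return s
        raise ValueError(f"cannot encode physical limit {v}")

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    pmin_s = [fit8(v, up=False) for v in pmin]
    pmax_s = [fit8(v, up=True) for v in pmax]
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.array([float(s) for s in pmax_s])
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8),
        f(rec.subject_id, 80),
        f(f"cond={rec.condition} round={rec.round_index}", 80),
        f("01.01.20", 8),
        f("00.00.00", 8),
        f(256 * (1 + n_sig), 8),
        f("", 44),
        f(n_rec, 8),
        f("1", 8),
        f(n_sig, 4),
    ])
    sig_fields = [
        (labels, 16), (["" for _ in labels], 80), ([unit] * n_sig, 8),
        (pmin_s, 8), (pmax_s, 8),
        ([dmin] * n_sig, 8), ([dmax] * n_sig, 8),
        (["" for _ in labels], 80), ([spr] * n_sig, 8),
        (["" for _ in labels], 32),
    ]
    header += b"".join(
        b"".join(f(v, width) for v in values) for values, width in sig_fields
    )
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.astype("<i2").tobytes())
    return path


def _read_edf(path: Path, kind: str):
    with open(path, "rb") as fh:
        head = fh.read(256)
        subject_id = head[8:88].decode("ascii").strip()
        recording_id = head[88:168].decode("ascii").strip()
        n_rec = int(head[236:244])
        rec_dur = float(head[244:252])
        n_sig = int(head[252:256])
        sig = fh.read(256 * n_sig)

        def col(offset, width):
            base = offset * n_sig
            return [
                sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_sig)
            ]

        labels = col(0, 16)
        pmin = np.array([float(v) for v in col(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in col(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in col(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in col(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in col(16 + 80 + 8 + 32 + 80, 8)]
        raw = fh.read()

    total = sum(spr)
    records = np.frombuffer(raw, dtype="<i2", count=total * n_rec)
    records = records.reshape(n_rec, total)
    data = np.empty((n_sig, n_rec * max(spr)))
    offset = 0
    for i, s in enumerate(spr):
        chan = records[:, offset:offset + s].reshape(-1).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        data[i, :chan.size] = (chan - dmin[i]) * gain + pmin[i]
        offset += s

    meta = dict(
        item.split("=", 1) for item in recording_id.split() if "=" in item
    )
    if "cond" not in meta or "round" not in meta:
        raise ValueError("condition missing from EDF recording field")
    fs = spr[0] / rec_dur
    if kind == "eeg":
        return EegRecording(
            subject_id=subject_id,
            condition=meta["cond"],
            round_index=int(meta["round"]),
            channel_labels=labels,
            samples=data,
            sampling_rate=fs,
        )
    return EdaRecording(
        subject_id=subject_id,
        condition=meta["cond"],
        round_index=int(meta["round"]),
        conductance=data[0],
        sampling_rate=fs,
    )
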