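"""The 181-column feature registry and its extractors.

Per epoch (5 s, 30 % overlap) the registry holds:

* 153 per-channel EEG features: 17 channels x 3 bands (theta 4-8 Hz,
  alpha 9-12 Hz, beta 13-25 Hz) x {relative band power, differential
  entropy, Higuchi fractal dimension};
* 18 ratio indices: 5 homologous frontal-theta / parietal-alpha pairs,
  7 per-channel theta/beta, 6 per-channel beta/(theta+alpha);
* 10 electrodermal statistics: {mean, median, sd, kurtosis, Shannon
  entropy} of the tonic and phasic components.

Band limitation uses a complex-Morlet (6-cycle) wavelet filter bank with
centre frequencies every 1 Hz across the band, realised in the frequency
domain and normalised to unit peak response inside the band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .recordings import (
    CLASSES,
    FEATURE_CHANNELS,
    EegRecording,
    EpochGrid,
    make_epochs,
)

#: Analysis bands in Hz, as (low, high) inclusive edges.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (9.0, 12.0),
    "beta": (13.0, 25.0),
}
BAND_NAMES = tuple(BANDS)

#: Channels of the three ratio-index families.
THETA_ALPHA_PAIRS = (("Fz", "Pz"), ("F3", "P3"), ("F7", "P7"),
                     ("F4", "P4"), ("F8", "P8"))
THETA_BETA_CHANNELS = ("FP1", "Fz", "F3", "F7", "F4", "F8", "FP2")
BETA_THETA_ALPHA_CHANNELS = ("Fz", "F7", "F8", "P7", "P8", "Pz")

EDA_COMPONENTS = ("tonic", "phasic")
EDA_STATS = ("mean", "median", "sd", "kurtosis", "entropy")

PER_CHANNEL_KINDS = ("relpow", "de", "hfd")

DEFAULT_KMAX = 10
DEFAULT_ENTROPY_BINS = 16
_VARIANCE_FLOOR = 1e-12


def build_registry() -> list[str]:
    """Deterministic ordered list of the 181 feature names."""
    names: list[str] = []
    for ch in FEATURE_CHANNELS:
        for band in BAND_NAMES:
            for kind in PER_CHANNEL_KINDS:
                names.append(f"{ch}_{band}_{kind}")
    for f, p in THETA_ALPHA_PAIRS:
        names.append(f"ratio_{f}theta_{p}alpha")
    for ch in THETA_BETA_CHANNELS:
        names.append(f"ratio_{ch}_theta_beta")
    for ch in BETA_THETA_ALPHA_CHANNELS:
        names.append(f"ratio_{ch}_beta_thetaalpha")
    for comp in EDA_COMPONENTS:
        for stat in EDA_STATS:
            names.append(f"eda_{comp}_{stat}")
    assert len(names) == 181 and len(set(names)) == 181
    return names


def registry_blocks(registry: list[str] | None = None) -> dict[str, list[str]]:
    """Partition the registry into its per-channel, ratio and EDA blocks."""
    registry = registry or build_registry()
    per_channel = registry[:153]
    ratios = registry[153:171]
    eda = registry[171:]
    return {"per_channel": per_channel, "ratios": ratios, "eda": eda,
            "eeg": registry[:171]}


# ---------------------------------------------------------------------------
# Morlet filter bank
# ---------------------------------------------------------------------------

def _morlet_comb(freqs: np.ndarray, band: tuple[float, float],
                 n_cycles: float) -> np.ndarray:
    low, high = band
    centers = np.arange(low, high + 0.5, 1.0)
    sigma_f = centers / n_cycles
    resp = np.zeros_like(freqs)
    for fc, sf in zip(centers, sigma_f):
        resp += np.exp(-((freqs - fc) ** 2) / (2.0 * sf ** 2))
    peak = resp[(freqs >= low) & (freqs <= high)].max()
    return resp / peak


def morlet_band_decompose(x: np.ndarray, sampling_rate: float,
                          band: tuple[float, float] | str,
                          n_cycles: float = 6.0) -> np.ndarray:
    """Band-limit a signal with the 6-cycle Morlet wavelet filter bank.

    Equivalent to summing the real parts of the complex-Morlet wavelet
    transform at 1 Hz-spaced centre frequencies spanning the band, with
    the summed response renormalised to unit gain at its in-band peak.
    """
    if isinstance(band, str):
        band = BANDS[band]
    if band[1] >= sampling_rate / 2:
        raise ValueError(
            f"band upper edge {band[1]} Hz is at or above Nyquist "
            f"({sampling_rate / 2} Hz)"
        )
    x = np.asarray(x, dtype=float)
    n = x.size
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return np.fft.irfft(spectrum * _morlet_comb(freqs, band, n_cycles), n=n)


# ---------------------------------------------------------------------------
# Scalar features
# ---------------------------------------------------------------------------

def rms_power(x: np.ndarray) -> float:
    """Root mean square of a (band-limited) signal segment."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(x ** 2)))


def relative_band_power(epoch_power: float, baseline_power: float,
                        label: str = "") -> float:
    """Epoch RMS band power divided by the channel/band baseline power."""
    if baseline_power <= 0:
        raise ValueError(f"baseline power is zero or absent ({label})")
    return float(epoch_power) / float(baseline_power)


def differential_entropy(variance: float) -> float:
    """DE of a band-limited epoch: ``0.5 * ln(2 * pi * variance)`` (nats)."""
    if variance <= _VARIANCE_FLOOR:
        raise ValueError(
            f"variance {variance:.3g} at or below floor {_VARIANCE_FLOOR:g}"
        )
    return 0.5 * float(np.log(2.0 * np.pi * variance))


def higuchi_fd(x: np.ndarray, kmax: int = DEFAULT_KMAX) -> float:
    """Higuchi fractal dimension: slope of log mean curve length vs log 1/k.

    Returns a value in [1, 2] for bounded signals; estimates outside that
    range are clamped with a warning.  A constant signal is defined to have
    dimension 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 * kmax:
        raise ValueError(f"epoch of {n} samples too short for kmax={kmax}")
    if np.ptp(x) == 0:
        return 1.0
    lengths = np.empty(kmax)
    for k in range(1, kmax + 1):
        lk = 0.0
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lk += dist * norm / k
        lengths[k - 1] = lk / k
    ks = np.arange(1, kmax + 1)
    valid = lengths > 0
    if valid.sum() < 2:
        return 1.0
    slope, _ = np.polyfit(np.log(1.0 / ks[valid]), np.log(lengths[valid]), 1)
    fd = float(slope)
    if fd < 1.0 or fd > 2.0:
        warnings.warn(
            f"Higuchi estimate {fd:.3f} outside [1, 2]; clamped", stacklevel=2
        )
        fd = min(max(fd, 1.0), 2.0)
    return fd


def ratio_indices(band_powers: dict[tuple[str, str], float]) -> dict[str, float]:
    """The 18 ratio-index features from per-channel RMS band powers.

    ``band_powers`` maps ``(channel, band)`` to the epoch's RMS power.
    """
    def power(ch: str, band: str) -> float:
        key = (ch, band)
        if key not in band_powers:
            raise KeyError(f"missing channel/band {key} for ratio index")
        return band_powers[key]

    out: dict[str, float] = {}
    for f, p in THETA_ALPHA_PAIRS:
        denom = power(p, "alpha")
        if denom <= 0:
            raise ValueError(f"zero parietal alpha power in pair {f}/{p}")
        out[f"ratio_{f}theta_{p}alpha"] = power(f, "theta") / denom
    for ch in THETA_BETA_CHANNELS:
        denom = power(ch, "beta")
        if denom <= 0:
            raise ValueError(f"zero beta power at {ch}")
        out[f"ratio_{ch}_theta_beta"] = power(ch, "theta") / denom
    for ch in BETA_THETA_ALPHA_CHANNELS:
        denom = power(ch, "theta") + power(ch, "alpha")
        if denom <= 0:
            raise ValueError(f"zero theta+alpha power at {ch}")
        out[f"ratio_{ch}_beta_thetaalpha"] = power(ch, "beta") / denom
    return out


def shannon_entropy(x: np.ndarray, bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Shannon entropy (nats) of the amplitude histogram."""
    x = np.asarray(x, dtype=float)
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def eda_window_stats(tonic: np.ndarray, phasic: np.ndarray,
                     bins: int = DEFAULT_ENTROPY_BINS) -> dict[str, float]:
    """Ten statistics of a tonic/phasic window pair.

    Kurtosis uses the Pearson (non-excess) convention; the sd uses the
    n-1 denominator.  A constant window takes sd 0, kurtosis 0, entropy 0.
    """
    out: dict[str, float] = {}
    for comp, x in (("tonic", tonic), ("phasic", phasic)):
        x = np.asarray(x, dtype=float)
        if x.size < 4:
            raise ValueError(f"{comp} window of {x.size} samples (< 4)")
        constant = np.ptp(x) == 0
        out[f"eda_{comp}_mean"] = float(np.mean(x))
        out[f"eda_{comp}_median"] = float(np.median(x))
        out[f"eda_{comp}_sd"] = 0.0 if constant else float(np.std(x, ddof=1))
        out[f"eda_{comp}_kurtosis"] = (
            0.0 if constant else float(sps.kurtosis(x, fisher=False))
        )
        out[f"eda_{comp}_entropy"] = 0.0 if constant else shannon_entropy(x, bins)
    return out


# ---------------------------------------------------------------------------
# Feature table assembly
# ---------------------------------------------------------------------------

META_COLUMNS = ("subject", "round", "condition", "epoch")


@dataclass
class FeatureTable:
    """Epochs x 181 feature matrix with class labels and subject groups."""

    frame: pd.DataFrame
    feature_names: list[str] = field(default_factory=build_registry)

    def __post_init__(self) -> None:
        missing = [c for c in (*META_COLUMNS, *self.feature_names)
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing[:5]} ...")
        if self.frame[self.feature_names].isna().any().any():
            raise ValueError("NaN in assembled feature table")

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.frame["condition"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.frame["subject"].to_numpy()

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique())

    def subset(self, row_mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.frame.loc[row_mask].reset_index(drop=True),
                            list(self.feature_names))

    def to_csv(self, path) -> None:
        import json
        from pathlib import Path
        path = Path(path)
        self.frame.to_csv(path, index=False)
        schema = {
            "feature_names": self.feature_names,
            "meta_columns": list(META_COLUMNS),
            "classes": list(CLASSES),
        }
        path.with_suffix(".json").write_text(json.dumps(schema) + "\n")

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        import json
        from pathlib import Path
        path = Path(path)
        schema = json.loads(path.with_suffix(".json").read_text())
        return cls(pd.read_csv(path), schema["feature_names"])


def band_signals(rec: EegRecording,
                 channels=FEATURE_CHANNELS) -> dict[tuple[str, str], np.ndarray]:
    """Morlet band-limited copies of every (channel, band) pair."""
    out = {}
    for ch in channels:
        x = rec.channel(ch)
        for band in BAND_NAMES:
            out[(ch, band)] = morlet_band_decompose(x, rec.sampling_rate, band)
    return out


def baseline_band_powers(baseline: EegRecording,
                         channels=FEATURE_CHANNELS) -> dict[tuple[str, str], float]:
    """RMS band power over the entire baseline recording per channel/band."""
    return {key: rms_power(sig)
            for key, sig in band_signals(baseline, channels).items()}


def eeg_epoch_features(rec: EegRecording,
                       baseline_powers: dict[tuple[str, str], float],
                       grid: EpochGrid | None = None,
                       kmax: int = DEFAULT_KMAX) -> pd.DataFrame:
    """All 171 EEG features for every epoch of one preprocessed recording."""
    if grid is None:
        grid = make_epochs(rec.n_samples, rec.sampling_rate)
    sigs = band_signals(rec)
    rows = []
    for ei, sl in enumerate(grid.slices()):
        row: dict[str, float] = {}
        powers: dict[tuple[str, str], float] = {}
        for ch in FEATURE_CHANNELS:
            for band in BAND_NAMES:
                seg = sigs[(ch, band)][sl]
                p = rms_power(seg)
                powers[(ch, band)] = p
                row[f"{ch}_{band}_relpow"] = relative_band_power(
                    p, baseline_powers[(ch, band)], f"{ch}/{band}"
                )
                row[f"{ch}_{band}_de"] = differential_entropy(
                    float(np.var(seg))
                )
                row[f"{ch}_{band}_hfd"] = higuchi_fd(seg, kmax)
        row.update(ratio_indices(powers))
        row["epoch"] = ei
        rows.append(row)
    df = pd.DataFrame(rows)
    df["subject"] = rec.subject_id
    df["round"] = rec.round_index
    df["condition"] = rec.condition
    return df


def eda_epoch_features(tonic: np.ndarray, phasic: np.ndarray,
                       sampling_rate: float,
                       grid: EpochGrid | None = None) -> pd.DataFrame:
    """The 10 EDA statistics for every epoch of one decomposed recording."""
    if grid is None:
        grid = make_epochs(tonic.size, sampling_rate)
    rows = []
    for ei, sl in enumerate(grid.slices()):
        row = eda_window_stats(tonic[sl], phasic[sl])
        row["epoch"] = ei
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_feature_table(eeg_records, eda_decompositions,
                           registry: list[str] | None = None,
                           kmax: int = DEFAULT_KMAX) -> FeatureTable:
    """Assemble the epochs x 181 table from preprocessed recordings.

    ``eeg_records`` is an iterable of preprocessed :class:`EegRecording`
    in which every subject's baseline precedes that subject's condition
    recordings.  ``eda_decompositions`` maps
    ``(subject, condition, round)`` to ``(tonic, phasic, sampling_rate)``.
    """
    registry = registry or build_registry()
    baselines: dict[str, dict] = {}
    parts = []
    for rec in eeg_records:
        if rec.condition == "baseline":
            baselines[rec.subject_id] = baseline_band_powers(rec)
            continue
        if rec.subject_id not in baselines:
            raise ValueError(f"no baseline recording for {rec.subject_id}")
        eeg_df = eeg_epoch_features(rec, baselines[rec.subject_id], kmax=kmax)
        key = (rec.subject_id, rec.condition, rec.round_index)
        if key not in eda_decompositions:
            raise ValueError(f"no EDA decomposition for {key}")
        tonic, phasic, fs = eda_decompositions[key]
        eda_df = eda_epoch_features(np.asarray(tonic), np.asarray(phasic), fs)
        if len(eda_df) != len(eeg_df):
            raise ValueError(
                f"EEG ({len(eeg_df)}) and EDA ({len(eda_df)}) epoch counts "
                f"differ for {key}"
            )
        parts.append(eeg_df.merge(eda_df, on="epoch"))
    if not parts:
        raise ValueError("no condition recordings supplied")
    frame = pd.concat(parts, ignore_index=True)
    frame = frame[[*META_COLUMNS, *registry]]
    return FeatureTable(frame, registry)
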