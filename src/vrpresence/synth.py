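"""Synthetic studies with known ground truth.

Generates complete studies — counterbalanced condition orders over three
rounds, per-condition EEG and EDA recordings, and questionnaire scores —
with a known generative class structure, so the full pipeline can be
exercised and validated without any recorded data.

The EEG model is phenomenological, not biophysical: each channel is an
independent sum of band-limited Gaussian noise (theta/alpha/beta, with
per-condition, per-region power multipliers relative to baseline), a 1/f
background, 50 Hz line interference, and Poisson trains of stereotyped
eye-blink transients on frontal channels.  The EDA model is a smooth
tonic drift plus a Poisson train of Bateman-kernel skin-conductance
responses whose rate depends on condition, plus white noise.
Questionnaire totals are truncated-normal draws on the 0-78 summed scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as _feat
from .recordings import (
    CLASSES,
    MONTAGE_20,
    REGION_MAP,
    EdaRecording,
    EegRecording,
)

_COND_CODE = {"H": "high", "M": "medium", "L": "low"}
_SEQUENCES = tuple("".join(p) for p in itertools.permutations("HML"))
# ('HML', 'HLM', 'MHL', 'MLH', 'LHM', 'LMH')


def default_band_effects() -> dict[tuple[str, str, str], float]:
    """Per-(condition, region, band) power multipliers relative to baseline.

    The directions follow the pattern the classifier is meant to recover:
    high presence raises prefrontal theta/beta and mid-parietal beta;
    medium presence raises frontal beta while suppressing mid-frontal
    alpha; low presence shows elevated parietal theta and mid-frontal
    alpha.  Magnitudes are free calibration parameters of the generator.
    """
    return {
        ("high", "prefrontal", "theta"): 2.2,
        ("high", "prefrontal", "beta"): 1.9,
        ("high", "mid-parietal", "beta"): 1.8,
        ("high", "frontal", "theta"): 1.5,
        ("medium", "frontal", "beta"): 1.8,
        ("medium", "mid-frontal", "alpha"): 0.6,
        ("medium", "parietal", "beta"): 1.4,
        ("low", "parietal", "theta"): 1.4,
        ("low", "mid-frontal", "alpha"): 1.4,
    }


def null_band_effects() -> dict[tuple[str, str, str], float]:
    """All multipliers 1: conditions are exchangeable."""
    return {}


@dataclass
class SimulationConfig:
    """Study-level generative parameters.

    Defaults mirror the study design: 22 subjects, 3 rounds, 105 s per
    presence level (the smallest whole-second duration yielding the
    29-epoch grid), a 60 s baseline, EEG at 250 Hz and EDA at 4 Hz.
    """

    n_subjects: int = 22
    rounds: int = 3
    level_duration_s: float = 105.0
    baseline_duration_s: float = 60.0
    eeg_fs: float = 250.0
    eda_fs: float = 4.0
    # EEG composition
    band_effects: dict = field(default_factory=default_band_effects)
    base_band_rms_uv: dict = field(
        default_factory=lambda: {"theta": 4.0, "alpha": 5.0, "beta": 3.0}
    )
    background_exponent: float = 1.0
    background_rms_uv: float = 3.0
    blink_rate_per_min: float = 15.0
    blink_amp_uv: float = 100.0
    blink_duration_s: float = 0.4
    blink_channel_weights: dict = field(
        default_factory=lambda: {"FP1": 1.0, "FP2": 1.0, "F7": 0.5, "F8": 0.5}
    )
    line_noise_amp_uv: float = 5.0
    line_freq_hz: float = 50.0
    # EDA composition
    scr_rate_per_min: dict = field(
        default_factory=lambda: {"baseline": 2.0, "low": 3.0,
                                 "medium": 5.0, "high": 8.0}
    )
    scr_amp_mean_us: float = 0.4
    bateman_rise_s: float = 0.7
    bateman_decay_s: float = 2.0
    tonic_level_us: float = 2.0
    tonic_drift_scale_us: float = 0.15
    eda_noise_sd_us: float = 0.01
    # Questionnaire (summed 13-item 0-6 scale -> 0-78)
    ipq_means: dict = field(
        default_factory=lambda: {"low": 49.68, "medium": 52.11, "high": 61.27}
    )
    ipq_sds: dict = field(
        default_factory=lambda: {"low": 12.37, "medium": 10.27, "high": 11.48}
    )
    #: Within-subject consistency of questionnaire totals: the fraction of
    #: each condition's variance carried by a shared per-subject offset.
    #: Presence questionnaires are strongly trait-like, and the paired
    #: (Friedman) analysis assumes exactly this structure; marginal
    #: means/sds are preserved for any value in [0, 1).
    ipq_icc: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.bateman_rise_s >= self.bateman_decay_s:
            raise ValueError("Bateman rise time must be below the decay time")
        if any(m <= 0 for m in self.band_effects.values()):
            raise ValueError("band-effect multipliers must be positive")
        if any(r < 0 for r in self.scr_rate_per_min.values()):
            raise ValueError("SCR rates must be nonnegative")

    def multiplier(self, condition: str, channel: str, band: str) -> float:
        return self.band_effects.get(
            (condition, REGION_MAP[channel], band), 1.0
        )

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.rng_seed, spawn_key=tuple(key))
    )


_STREAM_ORDERS, _STREAM_EEG, _STREAM_EDA, _STREAM_IPQ = 1, 2, 3, 4


# ---------------------------------------------------------------------------
# Counterbalancing
# ---------------------------------------------------------------------------

def counterbalanced_orders(n_subjects: int, seed: int = 0) -> list[list[str]]:
    """Per-subject condition orders: 3 rounds forming a 3x3 Latin square.

    The first-round sequence is drawn uniformly from the six permutations
    of {H, M, L}; the remaining two rounds are its cyclic rotations (the
    Latin-square completion), their direction also randomised.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM_ORDERS,))
    )
    orders = []
    for _ in range(n_subjects):
        first = _SEQUENCES[rng.integers(len(_SEQUENCES))]
        step = 1 if rng.integers(2) == 0 else 2
        rounds = []
        for r in range(3):
            shift = (r * step) % 3
            rounds.append(first[shift:] + first[:shift])
        orders.append(rounds)
    return orders


# ---------------------------------------------------------------------------
# EEG generator
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng, n, fs, exponent, rms):
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f >= 0.5
    shape[nz] = (f[nz] / 0.5) ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _blink_template(fs: float, duration_s: float) -> np.ndarray:
    n = max(int(round(duration_s * fs)), 2)
    t = np.arange(n) / (n - 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))  # raised cosine, peak 1


def _condition_index(condition: str) -> int:
    return ("baseline", *CLASSES).index(condition)


def simulate_eeg_recording(subject_idx: int, condition: str, round_index: int,
                           config: SimulationConfig) -> EegRecording:
    """One EEG recording; deterministic under (seed, subject, condition, round)."""
    rng = _rng(config, _STREAM_EEG, subject_idx, round_index,
               _condition_index(condition))
    fs = config.eeg_fs
    duration = (config.baseline_duration_s if condition == "baseline"
                else config.level_duration_s)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    samples = np.empty((len(MONTAGE_20), n))
    for ci, ch in enumerate(MONTAGE_20):
        x = np.zeros(n)
        for band in _feat.BAND_NAMES:
            noise = _feat.morlet_band_decompose(
                rng.standard_normal(n), fs, band
            )
            sd = noise.std()
            if sd > 0:
                noise /= sd
            target_sd = (config.base_band_rms_uv[band]
                         * np.sqrt(config.multiplier(condition, ch, band)))
            x += noise * target_sd
        x += _one_over_f_noise(rng, n, fs, config.background_exponent,
                               config.background_rms_uv)
        if config.line_noise_amp_uv > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += config.line_noise_amp_uv * np.sin(
                2 * np.pi * config.line_freq_hz * t + phase
            )
        samples[ci] = x

    if config.blink_rate_per_min > 0 and config.blink_amp_uv != 0:
        template = _blink_template(fs, config.blink_duration_s) * config.blink_amp_uv
        n_blinks = rng.poisson(config.blink_rate_per_min * duration / 60.0)
        starts = np.sort(
            rng.integers(0, max(n - template.size, 1), size=n_blinks)
        )
        blink = np.zeros(n)
        for s in starts:
            blink[s:s + template.size] += template[: n - s]
        for ch, w in config.blink_channel_weights.items():
            samples[MONTAGE_20.index(ch)] += w * blink

    return EegRecording(
        subject_id=config.subject_ids()[subject_idx],
        condition=condition,
        round_index=round_index,
        channel_labels=list(MONTAGE_20),
        samples=samples,
        sampling_rate=fs,
    )


def blink_onsets(subject_idx: int, condition: str, round_index: int,
                 config: SimulationConfig) -> np.ndarray:
    """Ground-truth blink start samples for a given recording.

    Replays the generator's random stream, so it is exact for the
    recording produced by :func:`simulate_eeg_recording` under the same
    configuration.
    """
    rng = _rng(config, _STREAM_EEG, subject_idx, round_index,
               _condition_index(condition))
    fs = config.eeg_fs
    duration = (config.baseline_duration_s if condition == "baseline"
                else config.level_duration_s)
    n = int(round(duration * fs))
    for _ in MONTAGE_20:
        for _band in _feat.BAND_NAMES:
            rng.standard_normal(n)
        rng.standard_normal(n)
        if config.line_noise_amp_uv > 0:
            rng.uniform(0, 2 * np.pi)
    if config.blink_rate_per_min <= 0 or config.blink_amp_uv == 0:
        return np.array([], dtype=int)
    template_n = max(int(round(config.blink_duration_s * fs)), 2)
    n_blinks = rng.poisson(config.blink_rate_per_min * duration / 60.0)
    return np.sort(rng.integers(0, max(n - template_n, 1), size=n_blinks))


# ---------------------------------------------------------------------------
# EDA generator
# ---------------------------------------------------------------------------

def bateman_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """``exp(-t/decay) - exp(-t/rise)`` for t >= 0, normalised to unit peak."""
    if rise >= decay:
        raise ValueError("rise must be below decay")
    h = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay)
                 - np.exp(-np.maximum(t, 0) / rise), 0.0)
    t_peak = (np.log(decay / rise) * rise * decay) / (decay - rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return h / peak


def simulate_eda_recording(subject_idx: int, condition: str, round_index: int,
                           config: SimulationConfig,
                           return_truth: bool = False):
    """One EDA recording (tonic drift + Bateman SCR train + noise)."""
    rng = _rng(config, _STREAM_EDA, subject_idx, round_index,
               _condition_index(condition))
    fs = config.eda_fs
    duration = (config.baseline_duration_s if condition == "baseline"
                else config.level_duration_s)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # Tonic: level + integrated low-pass Gaussian drift.
    if config.tonic_drift_scale_us > 0:
        walk = np.cumsum(rng.standard_normal(n))
        width = max(int(30 * fs), 3)
        kernel = np.hanning(width)
        kernel /= kernel.sum()
        slow = np.convolve(walk, kernel, mode="same")
        slow -= slow.mean()
        sd = slow.std()
        if sd > 0:
            slow *= config.tonic_drift_scale_us / sd
    else:
        slow = np.zeros(n)
    tonic = config.tonic_level_us + slow

    # Phasic: Poisson event train convolved with the Bateman kernel.
    rate = config.scr_rate_per_min.get(condition, 0.0)
    n_events = rng.poisson(rate * duration / 60.0)
    event_times = np.sort(rng.uniform(0, duration, size=n_events))
    amps = rng.gamma(4.0, config.scr_amp_mean_us / 4.0, size=n_events)
    phasic = np.zeros(n)
    for t0, a in zip(event_times, amps):
        phasic += a * bateman_kernel(t - t0, config.bateman_rise_s,
                                     config.bateman_decay_s)

    noise = (rng.standard_normal(n) * config.eda_noise_sd_us
             if config.eda_noise_sd_us > 0 else np.zeros(n))
    y = tonic + phasic + noise
    if y.min() < 0:
        y = y - y.min()

    rec = EdaRecording(
        subject_id=config.subject_ids()[subject_idx],
        condition=condition,
        round_index=round_index,
        conductance=y,
        sampling_rate=fs,
    )
    if return_truth:
        return rec, {"event_times": event_times, "amplitudes": amps,
                     "tonic": tonic, "phasic": phasic}
    return rec


# ---------------------------------------------------------------------------
# Whole-study assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """All recordings, condition orders, questionnaire scores and truth."""

    eeg: list[EegRecording]
    eda: list[EdaRecording]
    manifest: pd.DataFrame
    orders: list[list[str]]
    ipq_scores: pd.DataFrame  # rows subjects, columns low/medium/high
    config: SimulationConfig

    def recording_pairs(self):
        """(eeg, eda) pairs aligned by (subject, condition, round)."""
        eda_by_key = {(r.subject_id, r.condition, r.round_index): r
                      for r in self.eda}
        return [(e, eda_by_key[(e.subject_id, e.condition, e.round_index)])
                for e in self.eeg]


def simulate_ipq_scores(config: SimulationConfig) -> pd.DataFrame:
    """Truncated-normal questionnaire totals per subject and condition."""
    rng = _rng(config, _STREAM_IPQ)
    icc = config.ipq_icc
    if not 0 <= icc < 1:
        raise ValueError("ipq_icc must lie in [0, 1)")
    subject_effect = rng.standard_normal(config.n_subjects)
    data = {}
    for cond in CLASSES:
        m, s = config.ipq_means[cond], config.ipq_sds[cond]
        draws = (m + subject_effect * s * np.sqrt(icc)
                 + rng.normal(0.0, s * np.sqrt(1 - icc),
                              size=config.n_subjects))
        data[cond] = np.clip(draws, 0.0, 78.0)
    return pd.DataFrame(data, index=config.subject_ids())


def simulate_design(config: SimulationConfig):
    """Condition orders and the study manifest, without signal synthesis."""
    orders = counterbalanced_orders(config.n_subjects, config.rng_seed)
    rows = []
    for si, subject in enumerate(config.subject_ids()):
        rows.append({"subject": subject, "round": 0,
                     "condition": "baseline"})
        for r in range(1, config.rounds + 1):
            sequence = orders[si][(r - 1) % 3]
            for code in sequence:
                rows.append({"subject": subject, "round": r,
                             "condition": _COND_CODE[code]})
    manifest = pd.DataFrame(rows)
    return orders, manifest


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study under one seed."""
    config = config or SimulationConfig()
    orders, manifest = simulate_design(config)
    subject_index = {s: i for i, s in enumerate(config.subject_ids())}
    eeg, eda = [], []
    for row in manifest.itertuples(index=False):
        si = subject_index[row.subject]
        eeg.append(simulate_eeg_recording(si, row.condition, row.round, config))
        eda.append(simulate_eda_recording(si, row.condition, row.round, config))
    ipq = simulate_ipq_scores(config)
    manifest = manifest.assign(
        label=lambda d: d["condition"].where(d["condition"] != "baseline")
    )
    return SyntheticStudy(eeg=eeg, eda=eda, manifest=manifest,
                          orders=orders, ipq_scores=ipq, config=config)


def iter_study_recordings(config: SimulationConfig):
    """Yield (eeg, eda) recording pairs one at a time (memory-light).

    Order matches the manifest of :func:`simulate_design`: each subject's
    baseline pair precedes that subject's condition pairs.
    """
    _, manifest = simulate_design(config)
    subject_index = {s: i for i, s in enumerate(config.subject_ids())}
    for row in manifest.itertuples(index=False):
        si = subject_index[row.subject]
        yield (simulate_eeg_recording(si, row.condition, row.round, config),
               simulate_eda_recording(si, row.condition, row.round, config))


def modulated_features(config: SimulationConfig,
                       registry: list[str] | None = None) -> set[str]:
    """Registry features whose generative law differs across conditions.

    A per-channel EEG feature is modulated when its (region, band) carries
    a multiplier that is not identical across the three conditions; ratio
    features are modulated when any constituent is; EDA features when the
    SCR event rate differs across conditions.
    """
    registry = registry or _feat.build_registry()

    def band_modulated(ch: str, band: str) -> bool:
        ms = {config.multiplier(c, ch, band) for c in CLASSES}
        return len(ms) > 1

    def channel_modulated(ch: str) -> bool:
        return any(band_modulated(ch, b) for b in _feat.BAND_NAMES)

    eda_mod = len({config.scr_rate_per_min.get(c, 0.0) for c in CLASSES}) > 1

    out = set()
    for name in registry:
        if name.startswith("eda_"):
            if eda_mod:
                out.add(name)
        elif name.startswith("ratio_"):
            for pair in _feat.THETA_ALPHA_PAIRS:
                if name == f"ratio_{pair[0]}theta_{pair[1]}alpha" and (
                        channel_modulated(pair[0]) or channel_modulated(pair[1])):
                    out.add(name)
            for ch in _feat.THETA_BETA_CHANNELS:
                if name == f"ratio_{ch}_theta_beta" and channel_modulated(ch):
                    out.add(name)
            for ch in _feat.BETA_THETA_ALPHA_CHANNELS:
                if name == f"ratio_{ch}_beta_thetaalpha" and channel_modulated(ch):
                    out.add(name)
        else:
            ch, band, _kind = name.split("_")
            # z-scoring couples the bands of one channel: any band effect on
            # a channel perturbs every band share of that channel.
            if channel_modulated(ch):
                out.add(name)
    return out
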