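"""Shared fixtures: small deterministic studies and the two reference
8-subject pipelines (null-effect and strong-effect) used by the
calibration and recovery suites."""

import numpy as np
import pandas as pd
import pytest

from vrpresence import synth
from vrpresence.features import FeatureTable, build_registry
from vrpresence.pipeline import run_study_pipeline
from vrpresence.recordings import CLASSES


def null_config(n_subjects: int = 8, seed: int = 13) -> synth.SimulationConfig:
    """Exchangeable conditions: no band effects, equal SCR rates, no
    artifacts (there is nothing for wICA to remove in this regime)."""
    return synth.SimulationConfig(
        n_subjects=n_subjects,
        rng_seed=seed,
        band_effects=synth.null_band_effects(),
        scr_rate_per_min={c: 4.0 for c in ("baseline", "low", "medium", "high")},
        blink_rate_per_min=0.0,
        line_noise_amp_uv=0.0,
    )


@pytest.fixture(scope="session")
def null_table() -> FeatureTable:
    return run_study_pipeline(null_config(), run_wica=False)


@pytest.fixture(scope="session")
def strong_config() -> synth.SimulationConfig:
    return synth.SimulationConfig(n_subjects=8, rng_seed=11)


@pytest.fixture(scope="session")
def strong_table(strong_config) -> FeatureTable:
    return run_study_pipeline(strong_config, run_wica=True)


def random_feature_table(n_subjects: int = 6, epochs_per: int = 10,
                         seed: int = 0, informative: int | None = None,
                         separation: float = 3.0) -> FeatureTable:
    """Registry-shaped table with noise features (optionally one
    informative column) for structural and selection tests."""
    rng = np.random.default_rng(seed)
    names = build_registry()
    rows_y, rows_g, rows_r = [], [], []
    for si in range(n_subjects):
        for r in (1, 2, 3):
            for c in CLASSES:
                for _ in range(epochs_per):
                    rows_y.append(c)
                    rows_g.append(f"S{si + 1:02d}")
                    rows_r.append(r)
    n = len(rows_y)
    X = rng.standard_normal((n, len(names)))
    if informative is not None:
        codes = pd.Categorical(rows_y, categories=list(CLASSES)).codes
        X[:, informative] = codes * separation + rng.standard_normal(n) * 0.3
    frame = pd.DataFrame(X, columns=names)
    frame["subject"] = rows_g
    frame["round"] = rows_r
    frame["condition"] = rows_y
    frame["epoch"] = np.tile(np.arange(epochs_per),
                             n // epochs_per)
    return FeatureTable(frame, names)
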