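"""Synthetic-study generator: design, determinism, and signal content."""

import numpy as np
import pytest
from scipy import signal as sps

from vrpresence import synth
from vrpresence.features import morlet_band_decompose
from vrpresence.recordings import CLASSES

SEQUENCES = {"HML", "HLM", "MHL", "MLH", "LHM", "LMH"}


class TestCounterbalancing:
    def test_first_round_space_is_the_six_permutations(self):
        orders = synth.counterbalanced_orders(600, seed=0)
        firsts = {o[0] for o in orders}
        assert firsts == SEQUENCES

    def test_rounds_form_latin_square(self):
        for o in synth.counterbalanced_orders(50, seed=1):
            for pos in range(3):
                assert {o[r][pos] for r in range(3)} == {"H", "M", "L"}

    def test_lhm_continuation_is_the_latin_completion(self):
        # a subject starting LHM must see HML and MLH in some order
        for seed in range(200):
            orders = synth.counterbalanced_orders(1, seed=seed)[0]
            if orders[0] == "LHM":
                assert set(orders[1:]) == {"HML", "MLH"}
                break
        else:
            pytest.fail("no LHM first round in 200 seeds")


class TestEegGenerator:
    def test_seed_determinism(self):
        cfg = synth.SimulationConfig(n_subjects=2, rng_seed=9)
        a = synth.simulate_eeg_recording(0, "high", 2, cfg)
        b = synth.simulate_eeg_recording(0, "high", 2, cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_null_config_matches_baseline_band_power(self):
        cfg = synth.SimulationConfig(
            n_subjects=2, rng_seed=3,
            band_effects={}, blink_rate_per_min=0.0, line_noise_amp_uv=0.0,
        )
        low = synth.simulate_eeg_recording(0, "low", 1, cfg)
        base = synth.simulate_eeg_recording(0, "baseline", 0, cfg)
        for ch in ("FP1", "Pz"):
            f_l, p_l = sps.welch(low.channel(ch), fs=250, nperseg=2048)
            f_b, p_b = sps.welch(base.channel(ch), fs=250, nperseg=2048)
            band = (f_l >= 4) & (f_l <= 8)
            ratio = p_l[band].sum() / p_b[band].sum()
            assert 0.75 < ratio < 1.3

    def test_band_multiplier_reflected_in_welch_power(self):
        cfg = synth.SimulationConfig(
            n_subjects=2, rng_seed=7,
            band_effects={("high", "prefrontal", "theta"): 4.0},
            blink_rate_per_min=0.0, line_noise_amp_uv=0.0,
            background_rms_uv=0.0,
        )
        high = synth.simulate_eeg_recording(0, "high", 1, cfg)
        base = synth.simulate_eeg_recording(0, "baseline", 0, cfg)
        f, p_h = sps.welch(high.channel("FP1"), fs=250, nperseg=2048)
        _, p_b = sps.welch(base.channel("FP1"), fs=250, nperseg=2048)
        band = (f >= 4) & (f <= 8)
        ratio = p_h[band].sum() / p_b[band].sum()
        assert abs(ratio - 4.0) <= 1.0  # within 25 %

    def test_blink_onsets_replay_matches_recording(self):
        cfg = synth.SimulationConfig(n_subjects=2, rng_seed=5)
        rec = synth.simulate_eeg_recording(0, "low", 1, cfg)
        onsets = synth.blink_onsets(0, "low", 1, cfg)
        assert len(onsets) > 0
        fp1 = rec.channel("FP1")
        for s in onsets[:5]:
            assert fp1[s:s + 100].max() > 0.6 * cfg.blink_amp_uv

    def test_relative_theta_power_ordering_over_seeds(self):
        # raising prefrontal theta for "high" must lift the FP1 theta
        # share over both other conditions, which stay equal
        highs, meds, lows = [], [], []
        for seed in range(5):
            cfg = synth.SimulationConfig(
                n_subjects=2, rng_seed=seed,
                band_effects={("high", "prefrontal", "theta"): 2.5},
                blink_rate_per_min=0.0, line_noise_amp_uv=0.0,
            )
            out = {}
            base = synth.simulate_eeg_recording(0, "baseline", 0, cfg)
            for cond in CLASSES:
                rec = synth.simulate_eeg_recording(0, cond, 1, cfg)
                x = rec.channel("FP1")
                z = (x - x.mean()) / x.std()
                bz = base.channel("FP1")
                bz = (bz - bz.mean()) / bz.std()
                num = np.sqrt(np.mean(
                    morlet_band_decompose(z, 250.0, "theta") ** 2))
                den = np.sqrt(np.mean(
                    morlet_band_decompose(bz, 250.0, "theta") ** 2))
                out[cond] = num / den
            highs.append(out["high"])
            meds.append(out["medium"])
            lows.append(out["low"])
        assert np.mean(highs) > np.mean(meds) + 0.05
        assert np.mean(highs) > np.mean(lows) + 0.05
        assert abs(np.mean(meds) - np.mean(lows)) < 0.05


class TestEdaGenerator:
    def test_constant_trace_without_generative_terms(self):
        cfg = synth.SimulationConfig(
            n_subjects=2, scr_rate_per_min={c: 0.0 for c in
                                            ("baseline", "low", "medium", "high")},
            tonic_drift_scale_us=0.0, eda_noise_sd_us=0.0,
        )
        rec = synth.simulate_eda_recording(0, "low", 1, cfg)
        assert np.ptp(rec.conductance) < 1e-12

    def test_single_event_peak_location(self):
        t = np.arange(0, 30, 0.25)
        kern = synth.bateman_kernel(t - 10.0, 0.7, 2.0)
        peak_t = t[np.argmax(kern)]
        assert 10.0 <= peak_t <= 10.0 + 3 * 2.0

    def test_event_counts_poisson_scale(self):
        counts = []
        for seed in range(30):
            cfg = synth.SimulationConfig(
                n_subjects=2, rng_seed=seed,
                scr_rate_per_min={"high": 6.0, "baseline": 0, "low": 0,
                                  "medium": 0},
            )
            _, truth = synth.simulate_eda_recording(0, "high", 1, cfg,
                                                    return_truth=True)
            counts.append(len(truth["event_times"]))
        mean = np.mean(counts)
        # expectation 6/min * 1.75 min = 10.5
        assert abs(mean - 10.5) < 2.0
        assert np.var(counts) > 2.0  # genuinely dispersed

    def test_rise_must_precede_decay(self):
        with pytest.raises(ValueError, match="rise"):
            synth.SimulationConfig(bateman_rise_s=2.0, bateman_decay_s=0.7)


class TestStudyAssembly:
    def test_manifest_arithmetic_defaults(self):
        _, manifest = synth.simulate_design(synth.SimulationConfig())
        assert len(manifest) == 22 * (3 * 3 + 1) == 220

    def test_single_round_arithmetic(self):
        cfg = synth.SimulationConfig(n_subjects=3, rounds=1)
        study = synth.simulate_study(cfg)
        assert len(study.eeg) == len(study.eda) == 3 * 4
        counts = study.manifest.groupby("subject").size()
        assert (counts == 4).all()

    def test_study_determinism_and_invariants(self):
        cfg = synth.SimulationConfig(n_subjects=2, rounds=3, rng_seed=21)
        a = synth.simulate_study(cfg)
        b = synth.simulate_study(cfg)
        for ra, rb in zip(a.eeg, b.eeg):
            assert np.array_equal(ra.samples, rb.samples)
        assert a.ipq_scores.equals(b.ipq_scores)
        per_subject = a.manifest.groupby("subject")["condition"]
        for _, conds in per_subject:
            vals = conds.value_counts()
            assert vals["baseline"] == 1
            for c in CLASSES:
                assert vals[c] == 3

    def test_ipq_means_ordered_and_bounded(self):
        ok = 0
        for seed in range(20):
            cfg = synth.SimulationConfig(n_subjects=22, rng_seed=seed)
            ipq = synth.simulate_ipq_scores(cfg)
            assert (ipq.to_numpy() >= 0).all() and (ipq.to_numpy() <= 78).all()
            m = ipq.mean()
            ok += bool(m["high"] > m["medium"] > m["low"])
        assert ok >= 18  # >= 90 % of seeds at this sample size


class TestModulatedFeatures:
    def test_null_config_modulates_nothing(self):
        cfg = synth.SimulationConfig(
            band_effects={}, scr_rate_per_min={c: 4.0 for c in
                                               ("baseline", "low", "medium", "high")},
        )
        assert synth.modulated_features(cfg) == set()

    def test_default_config_marks_prefrontal_theta(self):
        mod = synth.modulated_features(synth.SimulationConfig())
        assert "FP1_theta_relpow" in mod
        assert "eda_phasic_entropy" in mod
        assert "FT9_theta_relpow" not in mod
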