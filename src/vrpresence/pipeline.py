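"""End-to-end runner: synthetic study -> preprocessed signals -> features.

Processes one recording pair at a time so a full study never has to be
held in memory.
"""

from __future__ import annotations

from . import eda as _eda
from . import eeg as _eeg
from .features import FeatureTable, assemble_feature_table, build_registry
from .synth import SimulationConfig, SyntheticStudy, iter_study_recordings


def preprocess_pair(eeg_rec, eda_rec, run_wica: bool = True,
                    wica_cfg=None, normalize_eda: bool = True):
    """Preprocess one (EEG, EDA) recording pair.

    Returns ``(clean_eeg, (tonic, phasic, fs))``.
    """
    clean = _eeg.preprocess_eeg(eeg_rec, wica_cfg=wica_cfg, run_wica=run_wica)
    _, decomp = _eda.preprocess_eda(eda_rec, normalize=normalize_eda)
    return clean, (decomp.tonic, decomp.phasic, decomp.sampling_rate)


def run_study_pipeline(study_or_config, run_wica: bool = True,
                       wica_cfg=None) -> FeatureTable:
    """Preprocess every recording of a study and assemble the feature table.

    Accepts either a materialised :class:`SyntheticStudy` or a
    :class:`SimulationConfig` (recordings are then generated on the fly,
    which keeps peak memory to a single recording).
    """
    if isinstance(study_or_config, SyntheticStudy):
        pairs = study_or_config.recording_pairs()
    elif isinstance(study_or_config, SimulationConfig):
        pairs = iter_study_recordings(study_or_config)
    else:
        raise TypeError("expected a SyntheticStudy or SimulationConfig")

    registry = build_registry()

    def eeg_stream():
        for eeg_rec, eda_rec in pairs:
            clean = _eeg.preprocess_eeg(eeg_rec, wica_cfg=wica_cfg,
                                        run_wica=run_wica)
            if eeg_rec.condition != "baseline":
                _, decomp = _eda.preprocess_eda(eda_rec)
                key = (eeg_rec.subject_id, eeg_rec.condition,
                       eeg_rec.round_index)
                eda_store[key] = (decomp.tonic, decomp.phasic,
                                  decomp.sampling_rate)
            yield clean

    eda_store: dict = {}
    return assemble_feature_table(eeg_stream(), eda_store, registry)
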