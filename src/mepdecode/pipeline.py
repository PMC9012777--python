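"""End-to-end convenience layer: trials -> labels -> features -> decoder.

These functions glue the stage modules together exactly the way the
analysis scripts, the tests and the acceptance script run them, so every
entry point exercises the same code path.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from . import defaults, eeg, emg
from .containers import FeatureMatrix, TrialSet
from .decoder import (GridSearchResult, LdaModel, confusion, grid_search,
                      make_folds, mep_modulation)


@dataclass
class ParticipantResult:
    """Everything the personalized analysis produces for one participant."""

    records: list
    kept_index: np.ndarray
    labels: np.ndarray
    amplitudes: np.ndarray
    features_final: FeatureMatrix
    grid: GridSearchResult
    confusion: np.ndarray
    modulation: dict


def prepare_labels(trials: TrialSet):
    """EMG pipeline -> (records, kept trial positions, 0/1 labels, amplitudes)."""
    records = emg.process_participant(trials)
    kept, y = emg.labels_vector(records)
    amps = np.array([records[i].amplitude for i in kept])
    return records, kept, y, amps


def run_personalized(
    trials: TrialSet,
    seed: int = 0,
    windows: str = "last",
    n_feature_grid: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    k: int = defaults.K_FOLDS,
) -> ParticipantResult:
    """The personalized decoding pipeline for one participant.

    EMG preprocessing and median-split labels, band-power features from the
    final pre-TMS window (or all six when ``windows="all"``; the final
    window still feeds the classifier), stratified cross-validated grid
    search, confusion matrix and MEP-amplitude modulation.
    """
    records, kept, y, amps = prepare_labels(trials)
    fms = eeg.extract_features(trials, windows=windows)
    fm_final = fms[-1].select_trials(kept)
    plan = make_folds(y, k=k, seed=seed)
    grid = grid_search(fm_final.values, y, fold_plan=plan,
                       n_feature_grid=n_feature_grid, lambda_grid=lambda_grid)
    conf = confusion(grid.per_trial_prediction, y)
    mod = mep_modulation(grid.per_trial_prediction, amps, true_labels=y)
    return ParticipantResult(
        records=records, kept_index=kept, labels=y, amplitudes=amps,
        features_final=fm_final, grid=grid, confusion=conf, modulation=mod,
    )


def measure_latency(trials: TrialSet, model: LdaModel,
                    max_trials: int | None = None) -> np.ndarray:
    """Wall-clock milliseconds to featurize one 500-ms segment and predict.

    Mirrors the real-time loop: per trial, cut the final pre-TMS window from
    the referenced EEG, compute the 168 band-power features and apply the
    trained discriminant. Hardware-dependent; reported for information only.
    """
    n = trials.n_trials if max_trials is None else min(max_trials, trials.n_trials)
    if n == 0:
        return np.empty(0)
    referenced = eeg.common_average_reference(trials.eeg[:n])
    out = np.empty(n)
    final = (defaults.WINDOWS[defaults.FINAL_WINDOW],)
    for i in range(n):
        t0 = time.perf_counter()
        seg = eeg.segment_windows(referenced[i], trials.eeg_rate,
                                  trials.eeg_tms_onset, windows=final)[0]
        freqs, psd = eeg.welch_power(seg)
        values, _ = eeg.band_average(psd, freqs, channels=trials.channel_names)
        model.decision_values(values[None, :])
        out[i] = (time.perf_counter() - t0) * 1000
    return out
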