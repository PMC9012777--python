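"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrialSet:
    """Aligned EEG epochs, EMG traces and metadata for one participant.

    EEG is stored as trials x channels x samples with the TMS pulse at sample
    index ``eeg_tms_onset`` (pre-stimulus samples precede it). EMG is a single
    bipolar channel per trial, trials x samples, pulse at ``emg_tms_onset``.
    """

    eeg: np.ndarray
    channel_names: tuple[str, ...]
    eeg_rate: float
    eeg_tms_onset: int
    emg: np.ndarray
    emg_rate: float
    emg_tms_onset: int
    trial_ids: np.ndarray
    participant_id: str = "P00"

    def __post_init__(self) -> None:
        if self.eeg.ndim != 3:
            raise ValueError("eeg must be trials x channels x samples")
        if self.emg.ndim != 2:
            raise ValueError("emg must be trials x samples")
        if self.eeg.shape[0] != self.emg.shape[0]:
            raise ValueError("EEG and EMG trial counts differ")
        if self.eeg.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length does not match EEG channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_trials(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[1]

    def select_trials(self, index: np.ndarray) -> "TrialSet":
        """A new TrialSet restricted to the given trial indices."""
        return TrialSet(
            eeg=self.eeg[index],
            channel_names=self.channel_names,
            eeg_rate=self.eeg_rate,
            eeg_tms_onset=self.eeg_tms_onset,
            emg=self.emg[index],
            emg_rate=self.emg_rate,
            emg_tms_onset=self.emg_tms_onset,
            trial_ids=self.trial_ids[index],
            participant_id=self.participant_id,
        )


@dataclass
class GroundTruth:
    """Generative ground truth attached to a synthetic TrialSet."""

    latent_state: np.ndarray
    coupled_features: tuple[tuple[str, str], ...]
    true_mep_amplitude: np.ndarray
    contaminated_rms: np.ndarray = field(default_factory=lambda: np.array([], int))
    contaminated_shape: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        if len(self.latent_state) != len(self.true_mep_amplitude):
            raise ValueError("latent_state and true_mep_amplitude lengths differ")
        if np.any(self.true_mep_amplitude <= 0):
            raise ValueError("true MEP amplitudes must be positive")


@dataclass
class FeatureMatrix:
    """Trials x (channel, band) power features for one pre-TMS window."""

    values: np.ndarray
    descriptors: tuple[tuple[str, str], ...]
    window_id: int
    window: tuple[float, float] | None = None
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be trials x features")
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count does not match feature count")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError("descriptors must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features contain non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_trials(self, index: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[index],
            descriptors=self.descriptors,
            window_id=self.window_id,
            window=self.window,
            trial_ids=None if self.trial_ids is None else self.trial_ids[index],
        )
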