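"""On-disk layout for trial sets, MEP tables, feature matrices and results.

A TrialSet is stored as one HDF5 file (EEG epochs and EMG traces as numeric
arrays with rate/onset attributes) next to a tab-separated trial-metadata
table; synthetic ground truth (latent states, true amplitudes, contamination
flags) goes to a separate sidecar so downstream stages cannot peek at it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import FeatureMatrix, GroundTruth, TrialSet
from .decoder import GridSearchResult
from .emg import MepRecord


def save_trialset(trials: TrialSet, directory: str | Path,
                  truth: GroundTruth | None = None) -> Path:
    """Write a TrialSet (and optional ground truth) under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pid = trials.participant_id
    h5path = d / f"{pid}_trials.h5"
    with h5py.File(h5path, "w") as f:
        f.create_dataset("eeg", data=trials.eeg, compression="gzip")
        f.create_dataset("emg", data=trials.emg, compression="gzip")
        f.attrs["eeg_rate"] = trials.eeg_rate
        f.attrs["emg_rate"] = trials.emg_rate
        f.attrs["eeg_tms_onset"] = trials.eeg_tms_onset
        f.attrs["emg_tms_onset"] = trials.emg_tms_onset
        f.attrs["channel_names"] = list(trials.channel_names)
        f.attrs["participant_id"] = pid
    meta = pd.DataFrame({
        "trial_id": trials.trial_ids,
        "tms_onset_sample": trials.eeg_tms_onset,
    })
    meta.to_csv(d / f"{pid}_trials.tsv", sep="\t", index=False)
    if truth is not None:
        gt = pd.DataFrame({
            "trial_id": trials.trial_ids,
            "latent_state": truth.latent_state,
            "true_mep_amplitude": truth.true_mep_amplitude,
            "contaminated_rms": np.isin(trials.trial_ids, truth.contaminated_rms),
            "contaminated_shape": np.isin(trials.trial_ids, truth.contaminated_shape),
        })
        gt.to_csv(d / f"{pid}_ground_truth.tsv", sep="\t", index=False)
        (d / f"{pid}_coupled_features.json").write_text(
            json.dumps([list(cf) for cf in truth.coupled_features]))
    return h5path


def load_trialset(path: str | Path) -> TrialSet:
    """Load a TrialSet.

    Accepts the HDF5 container written by :func:`save_trialset` (or a
    directory holding one), a delimited-text export
    (:func:`load_trialset_delimited`), or — via MNE, when installed — a
    continuous BrainVision/EDF/FIF recording with TMS event markers
    (:func:`load_trialset_mne`).
    """
    path = Path(path)
    if path.is_dir():
        candidates = sorted(path.glob("*_trials.h5"))
        if not candidates:
            raise FileNotFoundError(f"no *_trials.h5 under {path}")
        path = candidates[0]
    if path.suffix in {".tsv", ".csv", ".txt"}:
        return load_trialset_delimited(path)
    if path.suffix in {".vhdr", ".edf", ".fif"}:
        return load_trialset_mne(path)
    with h5py.File(path, "r") as f:
        n = f["eeg"].shape[0]
        return TrialSet(
            eeg=f["eeg"][()],
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            eeg_rate=float(f.attrs["eeg_rate"]),
            eeg_tms_onset=int(f.attrs["eeg_tms_onset"]),
            emg=f["emg"][()],
            emg_rate=float(f.attrs["emg_rate"]),
            emg_tms_onset=int(f.attrs["emg_tms_onset"]),
            trial_ids=np.arange(n),
            participant_id=str(f.attrs["participant_id"]),
        )


def save_trialset_delimited(trials: TrialSet, path: str | Path) -> Path:
    """Plain-text export: one wide TSV of samples plus a JSON sidecar.

    Rows are trials; EEG columns are ``<channel>_s<i>``, EMG columns
    ``EMG_s<i>``. Bulky but dependency-free and diff-able; intended for
    small trial sets and fixtures.
    """
    path = Path(path)
    n, n_ch, n_s = trials.eeg.shape
    cols = {}
    for ci, ch in enumerate(trials.channel_names):
        block = np.asarray(trials.eeg[:, ci, :])
        for si in range(n_s):
            cols[f"{ch}_s{si}"] = block[:, si]
    for si in range(trials.emg.shape[1]):
        cols[f"EMG_s{si}"] = trials.emg[:, si]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    sidecar = {
        "channel_names": list(trials.channel_names),
        "eeg_rate": trials.eeg_rate, "emg_rate": trials.emg_rate,
        "eeg_tms_onset": trials.eeg_tms_onset,
        "emg_tms_onset": trials.emg_tms_onset,
        "eeg_n_samples": n_s, "participant_id": trials.participant_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def load_trialset_delimited(path: str | Path) -> TrialSet:
    """Read the delimited export written by :func:`save_trialset_delimited`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t")
    n = len(df)
    chans = meta["channel_names"]
    n_s = meta["eeg_n_samples"]
    eeg = np.empty((n, len(chans), n_s))
    for ci, ch in enumerate(chans):
        want = [f"{ch}_s{si}" for si in range(n_s)]
        missing = [c for c in want if c not in df.columns]
        if missing:
            raise ValueError(f"channel {ch} incomplete: missing {missing[0]}...")
        eeg[:, ci, :] = df[want].to_numpy()
    emg_cols = [c for c in df.columns if c.startswith("EMG_s")]
    emg = df[emg_cols].to_numpy()
    return TrialSet(
        eeg=eeg, channel_names=tuple(chans), eeg_rate=meta["eeg_rate"],
        eeg_tms_onset=meta["eeg_tms_onset"], emg=emg,
        emg_rate=meta["emg_rate"], emg_tms_onset=meta["emg_tms_onset"],
        trial_ids=np.arange(n), participant_id=meta.get("participant_id", "P00"),
    )


def load_trialset_mne(
    path: str | Path,
    montage: tuple[str, ...] | None = None,
    emg_channel: str = "EMG",
    event_id: int = 1,
    pre_s: float = 3.005,
    post_s: float = 0.120,
) -> TrialSet:
    """Epoch a continuous BrainVision/EDF/FIF recording around TMS markers.

    Requires MNE. Channels are reordered to ``montage`` (errors name any
    missing channel); TMS onsets come from the annotations/stim events with
    ``event_id``. EEG units are converted from MNE's volts to µV.
    """
    import mne

    path = Path(path)
    readers = {".vhdr": mne.io.read_raw_brainvision,
               ".edf": mne.io.read_raw_edf,
               ".fif": mne.io.read_raw_fif}
    if path.suffix not in readers:
        raise ValueError(f"unrecognized recording format: {path.suffix}")
    raw = readers[path.suffix](path, preload=True, verbose="error")
    if montage is None:
        from . import defaults
        montage = tuple(c for c in defaults.CHANNELS if c in raw.ch_names)
    missing = [c for c in montage if c not in raw.ch_names]
    if missing:
        raise ValueError(f"montage channel missing from recording: {missing[0]}")
    if emg_channel not in raw.ch_names:
        raise ValueError(f"EMG channel {emg_channel!r} missing from recording")
    rate = float(raw.info["sfreq"])
    try:
        events = mne.find_events(raw, verbose="error")
    except ValueError:
        events, _ = mne.events_from_annotations(raw, verbose="error")
    onsets = events[events[:, 2] == event_id, 0] if len(events) else np.array([], int)
    if len(onsets) == 0:
        raise ValueError(f"no TMS markers with event id {event_id}")
    n_pre = int(round(pre_s * rate))
    n_post = int(round(post_s * rate))
    data = raw.get_data(picks=list(montage)) * 1e6  # V -> µV
    emg_data = raw.get_data(picks=[emg_channel])[0] * 1e6
    eeg_trials, emg_trials = [], []
    for s in onsets:
        if s - n_pre < 0 or s + n_post > data.shape[1]:
            raise ValueError(f"marker at sample {s} lacks pre/post coverage")
        eeg_trials.append(data[:, s - n_pre:s])
        emg_trials.append(emg_data[s - n_pre:s + n_post])
    return TrialSet(
        eeg=np.stack(eeg_trials), channel_names=tuple(montage),
        eeg_rate=rate, eeg_tms_onset=n_pre,
        emg=np.stack(emg_trials), emg_rate=rate, emg_tms_onset=n_pre,
        trial_ids=np.arange(len(onsets)), participant_id=path.stem,
    )


def mep_records_to_frame(records: list[MepRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": r.trial_id,
        "amplitude_uV": r.amplitude,
        "prestim_rms_uV": r.prestim_rms,
        "template_corr": r.template_corr,
        "excluded": r.excluded,
        "exclusion_reason": r.exclusion_reason or "",
        "label": r.label or "",
    } for r in records])


def save_mep_records(records: list[MepRecord], path: str | Path) -> None:
    mep_records_to_frame(records).to_csv(path, sep="\t", index=False)


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Feature matrix as TSV, header encoding channel_band, plus sidecar."""
    path = Path(path)
    cols = [f"{ch}_{band}" for ch, band in fm.descriptors]
    df = pd.DataFrame(fm.values, columns=cols)
    if fm.trial_ids is not None:
        df.insert(0, "trial_id", fm.trial_ids)
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "window_id": fm.window_id,
        "window_seconds_before_tms": fm.window,
        "descriptors": [list(d) for d in fm.descriptors],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    trial_ids = None
    if "trial_id" in df.columns:
        trial_ids = df.pop("trial_id").to_numpy()
    return FeatureMatrix(
        values=df.to_numpy(float),
        descriptors=tuple(tuple(d) for d in sidecar["descriptors"]),
        window_id=sidecar["window_id"],
        window=tuple(sidecar["window_seconds_before_tms"])
        if sidecar["window_seconds_before_tms"] else None,
        trial_ids=trial_ids,
    )


def save_grid_result(res: GridSearchResult, directory: str | Path,
                     prefix: str = "decode") -> None:
    """Persist the AUC surface, best configuration and held-out predictions."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / f"{prefix}_auc_surface.tsv", res.auc_surface, delimiter="\t")
    pd.DataFrame({
        "prediction": res.per_trial_prediction,
        "score": res.per_trial_score,
        "fold": res.fold_plan.assignments,
    }).to_csv(d / f"{prefix}_predictions.tsv", sep="\t", index=False)
    summary = {
        "best_auc": res.best_auc,
        "best_n_features": res.best_n_features,
        "best_lambda": res.best_lambda,
        "n_configurations": res.n_configurations,
        "k": res.fold_plan.k,
        "fold_seed": res.fold_plan.seed,
    }
    (d / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=1))


def config_hash(obj) -> str:
    """Stable short hash of a configuration-like object, for output stamps."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
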