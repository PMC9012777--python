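"""Pre-TMS EEG band-power features.

The pipeline mirrors a minimal real-time-compatible preprocessing chain:
common average reference, six 500-ms windows leading up to the pulse,
per-window demeaning/detrending, downsampling to 500 Hz with an
anti-aliasing low-pass, a Hann-tapered periodogram zero-padded to a 0.25 Hz
grid over 4-100 Hz (line-noise bins between 58 and 62 Hz dropped), and the
mean power per (channel, band) — 168 features per window for the default
28-channel montage and six bands.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from . import defaults
from .containers import FeatureMatrix, TrialSet
from .defaults import BandSpec


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean from every sample.

    ``data`` is (..., channels, samples); at least two channels required.
    """
    if data.shape[-2] < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return data - data.mean(axis=-2, keepdims=True)


def _window_slice(tms_onset: int, rate: float,
                  window: tuple[float, float]) -> slice:
    """Sample slice for a (start, end) window in seconds before TMS.

    Half-open toward the pulse: [onset - start*rate, onset - end*rate).
    """
    start_s, end_s = window
    a = tms_onset - int(round(start_s * rate))
    b = tms_onset - int(round(end_s * rate))
    return slice(a, b)


def segment_windows(
    data: np.ndarray,
    rate: float,
    tms_onset: int,
    windows: tuple[tuple[float, float], ...] = defaults.WINDOWS,
    out_rate: float = defaults.DOWNSAMPLED_RATE,
) -> list[np.ndarray]:
    """Cut the pre-TMS windows, demean, detrend and downsample each.

    ``data`` is (..., channels, samples). Each returned slice is
    (..., channels, round(0.5 s * out_rate)) at ``out_rate``. Downsampling is
    a zero-phase Butterworth low-pass at 0.4*out_rate followed by decimation.
    """
    earliest = max(w[0] for w in windows)
    need = int(round(earliest * rate))
    if tms_onset < need:
        raise ValueError(
            f"need {need} pre-TMS samples ({earliest:g} s at {rate:g} Hz), "
            f"have {tms_onset}"
        )
    q = rate / out_rate
    if abs(q - round(q)) > 1e-9:
        raise ValueError("rate must be an integer multiple of out_rate")
    q = int(round(q))
    sos = None
    if q > 1:
        sos = signal.butter(8, 0.4 * out_rate, btype="low", fs=rate, output="sos")
    slices = []
    for w in windows:
        seg = data[..., _window_slice(tms_onset, rate, w)].astype(float)
        seg = signal.detrend(seg, axis=-1, type="linear")  # removes mean too
        if q > 1:
            seg = signal.sosfiltfilt(sos, seg, axis=-1)[..., ::q]
        slices.append(seg)
    return slices


def welch_power(window_slice: np.ndarray,
                rate: float = defaults.DOWNSAMPLED_RATE,
                nfft: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Power spectral density of a 500-ms slice on the 0.25 Hz analysis grid.

    A single Hann-tapered segment zero-padded to ``nfft`` samples (default
    the length giving 0.25 Hz resolution, 2000 at 500 Hz); with one segment
    Welch's method reduces to a padded periodogram. Returns (freqs, psd)
    restricted to 4-100 Hz; psd has units µV²/Hz and shape
    (..., n_bins). Line-noise bins strictly inside 58-62 Hz are retained in
    the grid but masked out downstream via :func:`retained_mask`.
    """
    n = window_slice.shape[-1]
    expected = int(round(0.5 * rate))
    if n != expected:
        raise ValueError(f"slice must hold 0.5 s ({expected} samples), got {n}")
    if nfft is None:
        nfft = int(round(rate / defaults.SPECTRUM_DF))
    freqs, psd = signal.welch(
        window_slice, fs=rate, window="hann", nperseg=n, noverlap=0,
        nfft=nfft, detrend=False, scaling="density", axis=-1,
    )
    keep = (freqs >= defaults.SPECTRUM_FMIN) & (freqs <= defaults.SPECTRUM_FMAX)
    return freqs[keep], psd[..., keep]


def retained_mask(freqs: np.ndarray) -> np.ndarray:
    """Bins kept after excluding line-noise frequencies (58, 62) Hz, open."""
    lo, hi = defaults.LINE_NOISE_RANGE
    return ~((freqs > lo) & (freqs < hi))


def band_average(
    psd: np.ndarray,
    freqs: np.ndarray,
    bands: tuple[BandSpec, ...] = defaults.BANDS,
    channels: tuple[str, ...] = defaults.CHANNELS,
) -> tuple[np.ndarray, tuple[tuple[str, str], ...]]:
    """Mean retained PSD per (channel, band).

    ``psd`` is (..., n_channels, n_bins). Returns values of shape
    (..., n_channels*n_bands) and matching (channel, band) descriptors,
    channel-major.
    """
    if psd.shape[-2] != len(channels):
        raise ValueError("psd channel axis does not match channel list")
    keep = retained_mask(freqs)
    cols, descriptors = [], []
    for ci, ch in enumerate(channels):
        for band in bands:
            m = band.mask(freqs) & keep
            if not m.any():
                raise ValueError(f"band {band.name} retains no spectral bins")
            cols.append(psd[..., ci, m].mean(axis=-1))
            descriptors.append((ch, band.name))
    return np.stack(cols, axis=-1), tuple(descriptors)


def extract_features(
    trials: TrialSet,
    windows: str | tuple[tuple[float, float], ...] = "all",
    bands: tuple[BandSpec, ...] = defaults.BANDS,
) -> list[FeatureMatrix]:
    """Full feature extraction: CAR -> windows -> PSD -> band power.

    ``windows`` is ``"all"`` (six windows), ``"last"`` (final 0.505-0.005 s
    window only) or an explicit tuple. Returns one FeatureMatrix per window
    in temporal order (earliest first); window_id indexes the default list.
    """
    if windows == "all":
        wins = defaults.WINDOWS
        ids = list(range(len(wins)))
    elif windows == "last":
        wins = (defaults.WINDOWS[defaults.FINAL_WINDOW],)
        ids = [defaults.FINAL_WINDOW]
    else:
        wins = tuple(windows)
        ids = [defaults.WINDOWS.index(w) if w in defaults.WINDOWS else i
               for i, w in enumerate(wins)]

    referenced = common_average_reference(trials.eeg)
    slices = segment_windows(referenced, trials.eeg_rate, trials.eeg_tms_onset,
                             windows=wins)
    out = []
    for wid, w, seg in zip(ids, wins, slices):
        freqs, psd = welch_power(seg)
        values, descriptors = band_average(
            psd, freqs, bands=bands, channels=trials.channel_names)
        out.append(FeatureMatrix(values=values, descriptors=descriptors,
                                 window_id=wid, window=w,
                                 trial_ids=trials.trial_ids.copy()))
    return out
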