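"""Study constants: montage, frequency bands, analysis windows, grids.

These defaults reproduce the fixed parameters of the decoding protocol:
28 scalp channels (TP9/TP10 removed), six 500-ms pre-stimulus windows,
six band-power bands over a 4-100 Hz spectrum with the 58-62 Hz line-noise
notch, a 5-fold stratified cross-validation, a 100-point shrinkage grid and
feature-count grid 1..168 (16,800 cross-validated configurations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 28 retained EEG channels (TP9 and TP10 excluded for poor contact).
CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz", "Iz",
    "FC1", "FC2", "CP1", "CP2", "FC5", "FC6", "CP5", "CP6",
)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band over which spectral power is averaged.

    ``excluded_range`` marks an open interval of line-noise frequencies whose
    bins are dropped before averaging (only the broadband band carries one;
    low gamma ends at 58 Hz and high gamma starts at 62 Hz, so the notch
    only bites into broadband).
    """

    name: str
    f_lo: float
    f_hi: float
    excluded_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: need 0 < f_lo < f_hi")
        if self.excluded_range is not None:
            lo, hi = self.excluded_range
            if not (self.f_lo <= lo < hi <= self.f_hi):
                raise ValueError(
                    f"band {self.name}: excluded_range must lie inside the band"
                )

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of retained bins for this band on a frequency grid."""
        m = (freqs >= self.f_lo) & (freqs <= self.f_hi)
        if self.excluded_range is not None:
            lo, hi = self.excluded_range
            m &= ~((freqs > lo) & (freqs < hi))
        return m


#: The six power bands; bins strictly inside (58, 62) Hz are excluded.
BANDS: tuple[BandSpec, ...] = (
    BandSpec("broadband", 4.0, 100.0, excluded_range=(58.0, 62.0)),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 13.0, 35.0),
    BandSpec("low_gamma", 36.0, 58.0),
    BandSpec("high_gamma", 62.0, 100.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)

#: Six 500-ms windows as (start, end) in seconds BEFORE the TMS pulse,
#: ordered earliest first; the last one (0.505-0.005 s) feeds the
#: personalized classifier.
WINDOWS: tuple[tuple[float, float], ...] = (
    (3.005, 2.505),
    (2.505, 2.005),
    (2.005, 1.505),
    (1.505, 1.005),
    (1.005, 0.505),
    (0.505, 0.005),
)

FINAL_WINDOW: int = len(WINDOWS) - 1

#: Spectral analysis grid: 4-100 Hz at 0.25 Hz after downsampling to 500 Hz.
DOWNSAMPLED_RATE: float = 500.0
SPECTRUM_FMIN: float = 4.0
SPECTRUM_FMAX: float = 100.0
SPECTRUM_DF: float = 0.25
LINE_NOISE_RANGE: tuple[float, float] = (58.0, 62.0)

#: Grid-search defaults: feature counts 1..168 and 100 shrinkage values
#: linearly spaced in [1e-10, 1].
N_LAMBDA: int = 100
LAMBDA_MIN: float = 1e-10
LAMBDA_MAX: float = 1.0
K_FOLDS: int = 5
PERMUTATION_REPS: int = 500

#: EMG processing constants.
MEP_WINDOW: tuple[float, float] = (0.020, 0.040)   # peak-to-peak window, s post-TMS
MEP_SEGMENT: tuple[float, float] = (0.020, 0.100)  # analysis segment, s post-TMS
OFFSET_WINDOW: tuple[float, float] = (0.020, 0.001)  # s before TMS, for DC removal
PRESTIM_RMS_WINDOW: tuple[float, float] = (0.105, 0.005)  # s before TMS
RMS_QUANTILE: float = 0.75
RMS_IQR_MULTIPLIER: float = 3.0
CORR_THRESHOLD: float = 0.4


def lambda_grid(n: int = N_LAMBDA) -> np.ndarray:
    """The shrinkage grid: ``n`` values linearly spaced in [1e-10, 1]."""
    return np.linspace(LAMBDA_MIN, LAMBDA_MAX, n)


def feature_count_grid(n_features: int = len(CHANNELS) * len(BANDS),
                       stride: int = 1) -> np.ndarray:
    """Feature-count grid 1..n_features (optionally strided for quick runs)."""
    grid = np.arange(1, n_features + 1, stride)
    if grid[-1] != n_features:
        grid = np.append(grid, n_features)
    return grid
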