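"""Run configuration: package defaults plus optional YAML overrides.

The checked-in ``configs/defaults.yaml`` mirrors every fixed analysis
constant (montage, bands, windows, grids, exclusion thresholds) so a run
can be audited from one file; any override is echoed into the run log and
stamped into output metadata via a configuration hash.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

from . import defaults
from .io import config_hash

log = logging.getLogger("mepdecode")


def default_run_config() -> dict:
    return {
        "montage": list(defaults.CHANNELS),
        "bands": {b.name: [b.f_lo, b.f_hi] for b in defaults.BANDS},
        "line_noise_excluded_hz": list(defaults.LINE_NOISE_RANGE),
        "windows_s_before_tms": [list(w) for w in defaults.WINDOWS],
        "downsampled_rate_hz": defaults.DOWNSAMPLED_RATE,
        "spectrum": {"fmin_hz": defaults.SPECTRUM_FMIN,
                     "fmax_hz": defaults.SPECTRUM_FMAX,
                     "resolution_hz": defaults.SPECTRUM_DF},
        "grid": {"n_lambda": defaults.N_LAMBDA,
                 "lambda_min": defaults.LAMBDA_MIN,
                 "lambda_max": defaults.LAMBDA_MAX,
                 "feature_counts": "1..168"},
        "cv": {"k": defaults.K_FOLDS, "stratified": True},
        "permutation_reps": defaults.PERMUTATION_REPS,
        "emg": {"segment_s_post_tms": list(defaults.MEP_SEGMENT),
                "mep_window_s_post_tms": list(defaults.MEP_WINDOW),
                "offset_window_s_pre_tms": list(defaults.OFFSET_WINDOW),
                "prestim_rms_window_s_pre_tms": list(defaults.PRESTIM_RMS_WINDOW),
                "rms_quantile": defaults.RMS_QUANTILE,
                "rms_iqr_multiplier": defaults.RMS_IQR_MULTIPLIER,
                "corr_threshold": defaults.CORR_THRESHOLD},
    }


def load_run_config(path: str | Path | None = None) -> dict:
    """Defaults merged with YAML overrides; overrides are logged."""
    cfg = default_run_config()
    if path is not None:
        overrides = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in overrides.items():
            if key in cfg and cfg[key] != value:
                log.info("config override: %s = %r (default %r)",
                         key, value, cfg[key])
            cfg[key] = value
    cfg["config_hash"] = config_hash({k: v for k, v in cfg.items()
                                      if k != "config_hash"})
    return cfg
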