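"""Synthetic TMS-EEG-EMG trial sets with known ground truth.

A latent excitability state drives both (i) the log band power of a chosen
set of (channel, band) EEG features and (ii) the log peak-to-peak amplitude
of the motor-evoked potential (MEP) in the EMG, so that every stage of the
decoding pipeline can be validated against a known coupling without any
recordings.

Generative model, per participant:

* Latent state. One standard-normal AR(1) chain across trials
  (lag-1 correlation ``rho_state``); within each trial the state is chained
  backwards across the six 500-ms pre-TMS windows with the same per-step
  correlation, so the final window carries the state ``e_t`` that the MEP
  couples to, and earlier windows are progressively noisier copies of it.
* EEG. Per window, each channel is a sum over the six analysis bands of a
  band-limited Gaussian component whose realized log power is
  ``mu_cb + gamma_cb * e + N(0, sigma_feature)`` (``gamma_cb`` equals
  ``gamma_coupling`` for configured coupled features, else 0), superposed on
  1/f-shaped background noise. Per-participant baseline offsets ``mu_cb``
  make cross-participant generalization non-trivial.
* EMG. Pre-stimulus Gaussian noise plus a biphasic damped-sinusoid MEP
  template (6 ms period, 5 ms decay) with onset ``mep_latency`` after the
  pulse, scaled so its peak-to-peak deflection in the 20-40 ms window equals
  ``exp(alpha_mep + beta_mep * e_t + N(0, sigma_mep))`` microvolts.
* Contamination. A configured fraction of trials gets >= 10x inflated
  pre-stimulus RMS (voluntary drive), another fraction an uncorrelated
  waveform of comparable amplitude in place of the MEP template (aberrant
  shape).

Seeding: all signal draws derive from ``default_rng([seed, stream, trial])``
so extending ``n_trials`` never perturbs earlier trials. Contamination
assignment draws a subset of exact size round(frac * n_trials) from a
dedicated stream and therefore depends on n_trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .containers import GroundTruth, TrialSet

# rng stream tags
_S_LATENT, _S_EEG, _S_EMG, _S_PARTICIPANT, _S_CONTAM = 3, 1, 2, 4, 5

#: Default coupled features: predominantly gamma-range, sensorimotor sites.
DEFAULT_COUPLED: tuple[tuple[str, str], ...] = (
    ("C3", "high_gamma"),
    ("C4", "high_gamma"),
    ("FC1", "low_gamma"),
    ("C3", "alpha"),
    ("Cz", "beta"),
)


@dataclass
class SimConfig:
    """Parameters of one synthetic participant.

    Effect sizes (``gamma_coupling`` in log-power units and ``beta_mep`` in
    log-amplitude units, both per unit latent state) are calibrated so the
    personalized decoding AUC on defaults lands in the 0.55-0.7 range and
    the true-split MEP modulation is a few hundred percent; see
    docs/methods.md for the calibration rationale.
    """

    n_trials: int = 600
    n_channels: int = 28
    channel_names: tuple[str, ...] = defaults.CHANNELS
    eeg_rate: float = 5000.0
    emg_rate: float = 5000.0
    pre_tms_duration: float = 3.005
    coupled_features: tuple[tuple[str, str], ...] = DEFAULT_COUPLED
    coupled_windows: tuple[int, ...] = tuple(range(len(defaults.WINDOWS)))
    gamma_coupling: float = 0.4
    beta_mep: float = 0.6
    alpha_mep: float = 6.2      # log µV; exp(6.2) ~ 490 µV typical MEP
    sigma_feature: float = 0.35
    sigma_mep: float = 0.5
    rho_state: float = 0.5
    # defaults emulate a realistic contaminated-trial share (~7% excluded)
    contamination_rms_frac: float = 0.04
    contamination_shape_frac: float = 0.03
    mep_latency: float = 0.022
    emg_noise_rms: float = 8.0  # µV baseline RMS
    background_power: float = 30.0  # total 1/f background variance, µV²
    participant_spread: float = 0.3  # SD of per-participant mu_cb offsets
    seed: int = 0
    participant_id: str = "P00"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_channels != len(self.channel_names):
            raise ValueError("n_channels must match channel_names length")
        for name, v in (("eeg_rate", self.eeg_rate),
                        ("emg_rate", self.emg_rate),
                        ("pre_tms_duration", self.pre_tms_duration),
                        ("mep_latency", self.mep_latency)):
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name, v in (("contamination_rms_frac", self.contamination_rms_frac),
                        ("contamination_shape_frac", self.contamination_shape_frac),
                        ("rho_state", self.rho_state)):
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        band_names = set(defaults.BAND_NAMES)
        for ch, band in self.coupled_features:
            if ch not in self.channel_names:
                raise ValueError(f"coupled_features: unknown channel {ch!r}")
            if band not in band_names:
                raise ValueError(f"coupled_features: unknown band {band!r}")
        earliest = max(w[0] for w in defaults.WINDOWS)
        if self.pre_tms_duration < earliest:
            raise ValueError(
                f"pre_tms_duration must cover the analysis windows (>= {earliest})")


def _rng(seed: int, stream: int, index: int | None = None) -> np.random.Generator:
    key = [seed, stream] if index is None else [seed, stream, index]
    return np.random.default_rng(key)


def _latent_states(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(per-trial state e_t, per-trial-per-window states), marginally N(0,1).

    The across-trial chain is AR(1) with lag-1 correlation rho_state; within
    each trial the six window states are chained backwards from the final
    window (which equals e_t) with the same per-step correlation.
    """
    n, rho = cfg.n_trials, cfg.rho_state
    e = np.empty(n)
    n_win = len(defaults.WINDOWS)
    e_win = np.empty((n, n_win))
    for t in range(n):
        g = _rng(cfg.seed, _S_LATENT, t)
        z = g.standard_normal()
        e[t] = z if t == 0 else rho * e[t - 1] + np.sqrt(1 - rho**2) * z
        e_win[t, n_win - 1] = e[t]
        back = g.standard_normal(n_win - 1)
        for w in range(n_win - 2, -1, -1):
            e_win[t, w] = rho * e_win[t, w + 1] + np.sqrt(1 - rho**2) * back[w]
    return e, e_win


def _band_bin_masks(n_samples: int, rate: float) -> list[np.ndarray]:
    freqs = np.fft.rfftfreq(n_samples, 1 / rate)
    return [(freqs >= b.f_lo) & (freqs <= b.f_hi) for b in defaults.BANDS]


def _background_1f(g: np.random.Generator, n_channels: int, n_samples: int,
                   rate: float, total_power: float) -> np.ndarray:
    """1/f-power-shaped Gaussian noise, variance ~ total_power per channel."""
    from scipy.fft import next_fast_len
    n_fft = next_fast_len(n_samples, real=True)  # avoid large-prime lengths
    freqs = np.fft.rfftfreq(n_fft, 1 / rate)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 1.0))
    spec = g.standard_normal((n_channels, len(freqs))) \
        + 1j * g.standard_normal((n_channels, len(freqs)))
    x = np.fft.irfft(spec * shape, n=n_fft, axis=-1)[:, :n_samples]
    x *= np.sqrt(total_power) / x.std(axis=-1, keepdims=True)
    return x


def _mep_template(cfg: SimConfig, n_post: int) -> tuple[np.ndarray, float]:
    """(unit template over the post-TMS samples, its 20-40 ms peak-to-peak)."""
    r = cfg.emg_rate
    t = np.arange(n_post) / r  # time after TMS
    rel = t - cfg.mep_latency
    tpl = np.where(
        rel >= 0,
        np.exp(-np.maximum(rel, 0) / 0.005) * np.sin(2 * np.pi * np.maximum(rel, 0) / 0.006),
        0.0,
    )
    w0, w1 = defaults.MEP_WINDOW
    m = (t >= w0) & (t <= w1)
    ptp = float(tpl[m].max() - tpl[m].min())
    return tpl, ptp


def _contamination_indices(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    n_rms = int(round(cfg.contamination_rms_frac * cfg.n_trials))
    n_shape = int(round(cfg.contamination_shape_frac * cfg.n_trials))
    g = _rng(cfg.seed, _S_CONTAM)
    perm = g.permutation(cfg.n_trials)
    return np.sort(perm[:n_rms]), np.sort(perm[n_rms:n_rms + n_shape])


def generate_participant(cfg: SimConfig,
                         include_eeg: bool = True) -> tuple[TrialSet, GroundTruth]:
    """Generate one participant's trials plus the generative ground truth.

    ``include_eeg=False`` skips EEG synthesis (the trial set then carries an
    empty channel axis) for EMG-only studies; all random draws for the
    trials that are generated are unchanged.
    """
    n = cfg.n_trials
    n_ch = cfg.n_channels
    n_pre = int(round(cfg.pre_tms_duration * cfg.eeg_rate))
    win_len = int(round(0.5 * cfg.eeg_rate))
    n_win = len(defaults.WINDOWS)

    e, e_win = _latent_states(cfg)

    # per-participant feature baselines: log band power mu_cb with a random
    # participant offset; baseline equals the 1/f background power in-band so
    # oscillatory components and background contribute comparably
    gp = _rng(cfg.seed, _S_PARTICIPANT)
    band_base = np.empty(len(defaults.BANDS))
    for bi, b in enumerate(defaults.BANDS):
        band_base[bi] = np.log(cfg.background_power * np.log(b.f_hi / b.f_lo)
                               / np.log(defaults.SPECTRUM_FMAX / 1.0))
    mu = band_base[None, :] + cfg.participant_spread * gp.standard_normal((n_ch, len(defaults.BANDS)))

    gamma = np.zeros((n_ch, len(defaults.BANDS)))
    ch_index = {c: i for i, c in enumerate(cfg.channel_names)}
    band_index = {b: i for i, b in enumerate(defaults.BAND_NAMES)}
    for ch, band in cfg.coupled_features:
        gamma[ch_index[ch], band_index[band]] = cfg.gamma_coupling

    masks = _band_bin_masks(win_len, cfg.eeg_rate)

    eeg = np.empty((n, n_ch, n_pre if include_eeg else 0), dtype=np.float32)
    for t in range(n if include_eeg else 0):
        g = _rng(cfg.seed, _S_EEG, t)
        trace = _background_1f(g, n_ch, n_pre, cfg.eeg_rate, cfg.background_power)
        for w in range(n_win):
            # accumulate all bands in the frequency domain (one irfft per
            # window); each band's spectrum is Parseval-normalized to unit
            # time-domain variance before scaling to its target power
            spec = np.zeros((n_ch, len(masks[0])), complex)
            coupled_w = w in cfg.coupled_windows
            for bi in range(len(defaults.BANDS)):
                nbin = int(masks[bi].sum())
                band_spec = (g.standard_normal((n_ch, nbin))
                             + 1j * g.standard_normal((n_ch, nbin)))
                # var(irfft) = 2*sum|X_k|^2 / n^2 for interior bins
                var = 2 * np.sum(np.abs(band_spec) ** 2, axis=1) / win_len**2
                logp = mu[:, bi] + cfg.sigma_feature * g.standard_normal(n_ch)
                if coupled_w:
                    logp = logp + gamma[:, bi] * e_win[t, w]
                scale = np.sqrt(np.exp(logp) / var)
                spec[:, masks[bi]] += band_spec * scale[:, None]
            seg = np.fft.irfft(spec, n=win_len, axis=-1)
            trace[:, w * win_len:(w + 1) * win_len] += seg
        eeg[t] = trace

    # EMG: 150 ms pre + 120 ms post
    n_pre_emg = int(round(0.150 * cfg.emg_rate))
    n_post_emg = int(round(0.120 * cfg.emg_rate))
    tpl, tpl_ptp = _mep_template(cfg, n_post_emg)
    rms_idx, shape_idx = _contamination_indices(cfg)
    rms_set, shape_set = set(rms_idx.tolist()), set(shape_idx.tolist())

    emg = np.empty((n, n_pre_emg + n_post_emg))
    true_amp = np.empty(n)
    for t in range(n):
        g = _rng(cfg.seed, _S_EMG, t)
        noise = g.standard_normal(n_pre_emg + n_post_emg) * cfg.emg_noise_rms
        if t in rms_set:
            noise[:n_pre_emg] *= 12.0  # >= 10x RMS inflation
        amp = float(np.exp(cfg.alpha_mep + cfg.beta_mep * e[t]
                           + cfg.sigma_mep * g.standard_normal()))
        true_amp[t] = amp
        if t in shape_set:
            wave = _aberrant_waveform(g, cfg, n_post_emg)
            noise[n_pre_emg:] += wave * amp
        else:
            noise[n_pre_emg:] += tpl * (amp / tpl_ptp)
        emg[t] = noise

    trials = TrialSet(
        eeg=eeg, channel_names=tuple(cfg.channel_names),
        eeg_rate=cfg.eeg_rate, eeg_tms_onset=n_pre,
        emg=emg, emg_rate=cfg.emg_rate, emg_tms_onset=n_pre_emg,
        trial_ids=np.arange(n), participant_id=cfg.participant_id,
    )
    truth = GroundTruth(
        latent_state=e, coupled_features=tuple(cfg.coupled_features),
        true_mep_amplitude=true_amp,
        contaminated_rms=rms_idx, contaminated_shape=shape_idx,
    )
    return trials, truth


def _aberrant_waveform(g: np.random.Generator, cfg: SimConfig,
                       n_post: int) -> np.ndarray:
    """A waveform uncorrelated with the MEP template, unit 20-40 ms ptp.

    Band-limited (80-400 Hz) noise under the same decaying envelope as the
    template, orthogonalized against the template so the exclusion rule's
    correlation statistic is centred at zero for these trials.
    """
    r = cfg.emg_rate
    t = np.arange(n_post) / r
    freqs = np.fft.rfftfreq(n_post, 1 / r)
    m = (freqs >= 80) & (freqs <= 400)
    spec = np.zeros(len(freqs), complex)
    spec[m] = g.standard_normal(m.sum()) + 1j * g.standard_normal(m.sum())
    x = np.fft.irfft(spec, n=n_post)
    rel = t - cfg.mep_latency
    x *= np.where(rel >= 0, np.exp(-np.maximum(rel, 0) / 0.005), 0.0)
    tpl, _ = _mep_template(cfg, n_post)
    x -= (x @ tpl) / (tpl @ tpl) * tpl
    w0, w1 = defaults.MEP_WINDOW
    win = (t >= w0) & (t <= w1)
    ptp = x[win].max() - x[win].min()
    if ptp == 0:
        raise RuntimeError("degenerate aberrant waveform")
    return x / ptp


def generate_cohort(configs: list[SimConfig]) -> list[tuple[TrialSet, GroundTruth]]:
    """Generate independent participants, one per config."""
    if not configs:
        raise ValueError("need at least one SimConfig")
    return [generate_participant(c) for c in configs]


def default_cohort_configs(
    n_participants: int = 20,
    base_seed: int = 0,
    **overrides,
) -> list[SimConfig]:
    """Convenience: distinct-seed configs sharing every other parameter."""
    return [
        SimConfig(seed=base_seed + 1000 * i, participant_id=f"P{i:02d}",
                  **overrides)
        for i in range(n_participants)
    ]
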