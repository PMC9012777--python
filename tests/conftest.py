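import numpy as np
import pytest

from mepdecode import defaults, eeg, emg, synthetic


@pytest.fixture(scope="session")
def small_participant():
    """One 60-trial default-coupling participant, shared across tests."""
    cfg = synthetic.SimConfig(n_trials=60, seed=7)
    trials, truth = synthetic.generate_participant(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def small_features(small_participant):
    """Final-window features + labels for the shared small participant."""
    _, trials, _ = small_participant
    records = emg.process_participant(trials)
    kept, y = emg.labels_vector(records)
    fm = eeg.extract_features(trials, windows="last")[0].select_trials(kept)
    return fm, y, records, kept


@pytest.fixture(scope="session")
def reduced_grids():
    """Desk-scale grid: strided feature counts, 10 lambdas."""
    n_grid = defaults.feature_count_grid(168, stride=8)
    lam_grid = defaults.lambda_grid(10)
    return n_grid, lam_grid


def gaussian_features(n_trials, n_features, coupled, effect, seed,
                      label_noise_sd=0.0):
    """Direct feature-level simulation for decoder tests: feature j in
    ``coupled`` carries ``effect`` * latent; labels = median split of the
    latent plus optional noise. Returns (X, y, latent)."""
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n_trials)
    X = rng.standard_normal((n_trials, n_features))
    for j in coupled:
        X[:, j] += effect * e
    obs = e + label_noise_sd * rng.standard_normal(n_trials)
    y = (obs > np.median(obs)).astype(int)
    return X, y, e
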