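# mepdecode

Personalized decoding of motor-cortex (M1) excitability states from
pre-stimulus EEG band power.

## The problem

Brain-state-dependent transcranial magnetic stimulation (TMS) needs a
real-time decision: is the cortex currently in a high- or low-excitability
state? The objective readout of M1 excitability is the motor-evoked
potential (MEP) — the EMG deflection a single TMS pulse evokes in a hand
muscle, whose peak-to-peak amplitude indexes corticospinal excitability.
`mepdecode` implements an analysis pipeline that learns, per participant, a
pattern of pre-stimulus EEG band power that predicts whether the upcoming
pulse will evoke a large or a small MEP:

1. **EMG / labels.** Per trial, the EMG is offset-corrected (mean of the
   1–20 ms pre-stimulus interval), segmented after the pulse, demeaned and
   detrended; MEP amplitude = max − min voltage between 20 and 40 ms
   post-TMS. Trials with pre-stimulus RMS above Q₇₅ + 3·IQR or with
   waveform correlation r < 0.4 against the participant-average MEP are
   excluded; the rest are median-split into *low*/*high* excitability
   labels.
2. **EEG / features.** Common average reference; six 500-ms windows from
   3.005 s up to 0.005 s before the pulse; per window: demean, detrend,
   downsample to 500 Hz, Hann-tapered periodogram on a 0.25 Hz grid over
   4–100 Hz (58–62 Hz line-noise bins dropped); mean power per channel ×
   band (θ 4–7, α 8–12, β 13–35, low-γ 36–58, high-γ 62–100, broadband
   4–100 Hz) → **168 features** for the 28-channel montage.
3. **Classifier.** Shrinkage LDA with pooled covariance regularized as
   S(λ) = (1−λ)S + λνI, ν = tr(S)/p. A stratified 5-fold cross-validated
   grid search optimizes the number of top-ranked features (chi-square
   importance, ranked on training folds only) and λ over 100 values in
   [10⁻¹⁰, 1] — **16,800 cross-validated configurations**. Performance is
   the fold-averaged AUC.
4. **Inference.** Significance by permutation: the full grid search re-run
   on shuffled labels (500 reps in the full protocol), true AUC compared
   to the null 95th percentile; the null mean is the empirical chance
   level. Plus cross-participant generalization, backwards temporal
   generalization over the six windows, trial-count curves, and
   nonparametric group statistics (Wilcoxon signed rank, Mann–Whitney U,
   Benjamini–Hochberg FDR, Spearman).

Because the original recordings are an external download
(OpenNeuro ds002094), the package ships a **synthetic TMS-EEG-EMG
generator** with known ground truth: a latent AR(1) excitability state
drives both the log band power of chosen (channel, band) features and the
log MEP amplitude, with configurable noise, autocorrelation and
contaminated-trial fractions. Every pipeline stage is tested against this
ground truth.

## Worked example

```python
import mepdecode as m

cfg = m.SimConfig(n_trials=300, seed=1)        # default study conditions
trials, truth = m.generate_participant(cfg)
res = m.run_personalized(trials, seed=1)       # EMG -> features -> grid search

print(f"configurations {res.grid.n_configurations}, "
      f"AUC {res.grid.best_auc:.3f} at n={res.grid.best_n_features}, "
      f"lambda={res.grid.best_lambda:.3f}")
print(f"predicted MEP modulation {res.modulation['percent']:.1f}%  "
      f"(true-split ceiling {res.modulation['true_percent']:.1f}%)")
```

prints (seed 1):

```
configurations 16800, AUC 0.644 at n=24, lambda=0.980
predicted MEP modulation 36.4%  (true-split ceiling 235.8%)
```

i.e. the search evaluated all 168 × 100 configurations, the personalized
classifier separates held-out high- from low-excitability trials with
AUC 0.64 using 24 features, and MEPs in classifier-predicted high states
are ~36% larger than in predicted low states — against a ~236% ceiling if
every trial were labelled perfectly.

The same stages are exposed as a CLI
(`mepdecode simulate | preprocess-emg | extract-features | decode |
permute | generalize | trial-curve | latency | report`) and as numbered
drivers under `analysis/` that write tables to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_and_decode.py
python analysis/03_permutation_significance.py
python analysis/04_generalization.py
python analysis/05_trial_count_curve.py
```

## Layout

- `src/mepdecode/` — library: `synthetic`, `emg`, `eeg`, `decoder`,
  `evaluation`, `pipeline`, `io`, `config`, `cli`.
- `configs/defaults.yaml` — every fixed analysis constant in one file.
- `analysis/` — numbered narrative drivers writing to `results/`.
- `scripts/acceptance.py` — end-to-end recomputation (above).
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
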