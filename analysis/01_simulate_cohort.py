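"""Simulate a small synthetic TMS-EEG-EMG cohort under default conditions.

Writes per-participant trial sets (HDF5 + TSV metadata + ground-truth
sidecars) under results/cohort/. Downstream scripts consume this directory.

Run:  python analysis/01_simulate_cohort.py [--participants 4] [--trials 150]
"""

import argparse
from pathlib import Path

from mepdecode import io, synthetic

def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--participants", type=int, default=4)
    ap.add_argument("--trials", type=int, default=150)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/cohort")
    args = ap.parse_args()

    configs = synthetic.default_cohort_configs(
        args.participants, base_seed=args.seed, n_trials=args.trials)
    for cfg in configs:
        trials, truth = synthetic.generate_participant(cfg)
        path = io.save_trialset(trials, args.out, truth=truth)
        print(f"{cfg.participant_id}: {trials.n_trials} trials -> {path}")
    print(f"cohort written to {Path(args.out).resolve()}")

if __name__ == "__main__":
    main()
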