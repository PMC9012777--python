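"""Influence of dataset size on decoding performance.

For one participant (default: a fresh 300-trial simulation), runs the grid
search on the first N trials for N in 50..300 (occurrence order, after
exclusion) and reports AUC and classifier-predicted MEP modulation per
size. Writes results/trial_curve.tsv.

Run:  python analysis/05_trial_count_curve.py
"""

import argparse
from pathlib import Path

import pandas as pd

from mepdecode import defaults, eeg, synthetic
from mepdecode.evaluation import trial_count_curve
from mepdecode.pipeline import prepare_labels

def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--trials", type=int, default=300)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/trial_curve.tsv")
    args = ap.parse_args()

    cfg = synthetic.SimConfig(n_trials=args.trials, seed=args.seed)
    tset, _ = synthetic.generate_participant(cfg)
    _, kept, y, amps = prepare_labels(tset)
    X = eeg.extract_features(tset, windows="last")[0].values[kept]
    sizes = tuple(s for s in range(50, 451, 50) if s <= len(y))
    rows = trial_count_curve(X, y, amps, sizes=sizes, seed=args.seed,
                             n_feature_grid=defaults.feature_count_grid(168, 8),
                             lambda_grid=defaults.lambda_grid(10))
    df = pd.DataFrame(rows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"-> {args.out}")

if __name__ == "__main__":
    main()
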