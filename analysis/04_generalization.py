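"""Cross-participant and temporal generalization.

(a) Trains each participant's personalized classifier (best configuration,
all trials) and tests it on every other participant; compares off-diagonal
AUCs to theoretical chance 0.5 with a right-tailed Wilcoxon signed rank
test. (b) Trains per window and generalizes the final-window classifier
backwards over the six pre-TMS windows. Writes
results/generalization_matrix.tsv and results/temporal.tsv.

Run:  python analysis/04_generalization.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mepdecode import defaults, eeg, io
from mepdecode.decoder import grid_search, make_folds
from mepdecode.evaluation import (cross_participant, temporal_generalization,
                                  wilcoxon_signed_rank)
from mepdecode.pipeline import prepare_labels

def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    n_grid = defaults.feature_count_grid(168, 8)
    lam_grid = defaults.lambda_grid(10)

    Xs, ys, results, pids, temporal_rows = [], [], [], [], []
    for p in sorted(Path(args.cohort).glob("*_trials.h5")):
        trials = io.load_trialset(p)
        _, kept, y, _ = prepare_labels(trials)
        fms = [fm.select_trials(kept)
               for fm in eeg.extract_features(trials, windows="all")]
        res = grid_search(fms[-1].values, y,
                          fold_plan=make_folds(y, seed=args.seed),
                          n_feature_grid=n_grid, lambda_grid=lam_grid)
        gen = temporal_generalization(res, fms[-1].values, fms, y)
        temporal_rows.append({"participant": trials.participant_id,
                              **{f"window_{i}": a for i, a in enumerate(gen)}})
        Xs.append(fms[-1].values)
        ys.append(y)
        results.append(res)
        pids.append(trials.participant_id)

    gm = cross_participant(Xs, ys, results, participants=tuple(pids))
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(gm.auc, index=pids, columns=pids).to_csv(
        out / "generalization_matrix.tsv", sep="\t")
    pd.DataFrame(temporal_rows).to_csv(out / "temporal.tsv", sep="\t",
                                       index=False)

    agg = gm.offdiag_mean_per_train()
    stat, p = wilcoxon_signed_rank(agg, reference=0.5, tail="greater")
    print(f"personalized (diagonal) mean AUC {np.diag(gm.auc).mean():.3f}")
    print(f"cross-participant mean AUC {agg.mean():.3f} "
          f"vs chance 0.5: W={stat:.1f}, p={p:.3f}")
    tail = np.mean([r["window_0"] for r in temporal_rows])
    head = np.mean([r[f"window_{len(defaults.WINDOWS)-1}"] for r in temporal_rows])
    print(f"temporal generalization: earliest-window AUC {tail:.3f}, "
          f"final-window (self) AUC {head:.3f}")

if __name__ == "__main__":
    main()
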