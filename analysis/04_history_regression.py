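#!/usr/bin/env python
"""Trial-history regression of the cohort and of model simulations.

Fits the 4-lag logistic regression to every subject's data, then
simulates each fitted model 20 times per subject and regresses the
synthetic behaviour, averaging coefficients across runs — the
posterior-predictive check of whether each model reproduces the
lag structure of choice behaviour.
"""

import argparse
from pathlib import Path

import pandas as pd

from twostep.io import read_fit_results, read_trials
from twostep.recovery import regression_of_simulations, simulate_from_fits
from twostep.regression import fit_session
from twostep.task import TaskConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-runs", type=int, default=20)
    ap.add_argument("--models", nargs="+", default=["hybrid", "ai_full"])
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    sessions = read_trials(args.out_dir / "cohort_trials.csv")
    frames = [fit_session(s).as_frame(s.subject_id).assign(source="data")
              for s in sessions]

    cfg = TaskConfig(n_trials=len(sessions[0]))
    for model in args.models:
        fits = read_fit_results(args.out_dir / f"fits_{model}.json")
        sims = simulate_from_fits(fits, cfg, n_runs=args.n_runs, seed=args.seed)
        coefs = regression_of_simulations(sims)
        frames += [c.as_frame(sid).assign(source=f"sim_{model}")
                   for sid, c in coefs.items()]

    table = pd.concat(frames, ignore_index=True)
    table.to_csv(args.out_dir / "history_regression.csv", index=False)
    lag1 = table[table["lag"] == 1].groupby(["source", "term"])["estimate"].mean()
    print("mean lag-1 coefficients by source:")
    print(lag1.unstack().round(3).to_string())


if __name__ == "__main__":
    main()
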