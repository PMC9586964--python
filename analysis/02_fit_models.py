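#!/usr/bin/env python
"""Fit the candidate models to every subject in the cohort.

Runs multi-restart maximum likelihood for the hybrid RL model and the
four active-inference learning variants, and writes one fits file per
model with parameters, log likelihood, AIC and BIC.
"""

import argparse
import time
from pathlib import Path

import numpy as np

from twostep.fitting import fit_subject
from twostep.io import read_trials, write_fit_results

DEFAULT_MODELS = ["hybrid", "ai_full", "ai_nud", "ai_nsd", "ai_nps"]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--restarts", type=int, default=25)
    ap.add_argument("--models", nargs="+", default=DEFAULT_MODELS)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    sessions = read_trials(args.out_dir / "cohort_trials.csv")
    for model in args.models:
        t0 = time.time()
        fits = []
        for i, ses in enumerate(sessions):
            seed = int(np.random.SeedSequence([args.seed, hash(model) % 2**31, i])
                       .generate_state(1)[0] % 2**31)
            fits.append(fit_subject(model, ses, n_restarts=args.restarts, seed=seed))
        write_fit_results(fits, args.out_dir / f"fits_{model}.json")
        mean_ll = np.mean([f.loglik for f in fits])
        print(f"{model}: {len(fits)} subjects, mean lnL {mean_ll:.1f} "
              f"({time.time() - t0:.0f} s)")


if __name__ == "__main__":
    main()
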