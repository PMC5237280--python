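#!/usr/bin/env python
"""Biomarker-recovery experiment on seeded infarct-evolution cohorts.

For each of 20 seeds: simulate a study-sized cohort with the published
per-class peak-height medians/IQRs, run the full pipeline, and check
whether the top-3 selected datapoints land within +/-0.05 ppm of the
three infarct-evolution biomarkers (Lac+ML 1.33, TCr 3.05, ML 0.85 ppm).
Writes per-seed results to results/recovery.tsv and prints the summary.

The third biomarker's class signal is partly redundant (in class
information) with the first two, which the CFS merit penalizes, so the
third greedy pick is the least stable — the pair {1.33, 3.05} recovers
far more reliably than the full triple.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from strokemrs.evaluate import feature_sweep
from strokemrs.preprocess import normalize_cohort
from strokemrs.simulate import default_config, simulate_cohort

TARGETS = (1.33, 3.05, 0.85)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-seeds", type=int, default=20)
    ap.add_argument("--out", default="results/recovery.tsv")
    args = ap.parse_args()

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(args.n_seeds):
            cfg = default_config("infarct_evolution", seed=seed)
            cohort = simulate_cohort(cfg)
            normalized, _ = normalize_cohort(cohort)
            sweep = feature_sweep(
                normalized.subset("train"),
                normalized.subset("test"),
                k_min=2,
                k_max=20,
                n_boot=0,
                seed=seed,
            )
            top3 = sweep.features.ppms[:3]
            hit = {t: bool(any(abs(p - t) <= 0.05 for p in top3)) for t in TARGETS}
            test_ber = next(r for r in sweep.rows if r.k == sweep.selected_k).test_ber
            rows.append(
                {
                    "seed": seed,
                    "top1_ppm": round(top3[0], 3),
                    "top2_ppm": round(top3[1], 3),
                    "top3_ppm": round(top3[2], 3),
                    **{f"hit_{t}": hit[t] for t in TARGETS},
                    "selected_k": sweep.selected_k,
                    "test_ber_pct": round(test_ber, 2),
                }
            )

    df = pd.DataFrame(rows)
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, sep="\t", index=False)

    triple = (df[[f"hit_{t}" for t in TARGETS]].all(axis=1)).mean()
    pair = (df[["hit_1.33", "hit_3.05"]].all(axis=1)).mean()
    print(df.to_string(index=False))
    print(f"\nfull triple recovered: {100 * triple:.0f}% of {args.n_seeds} seeds")
    print(f"{{1.33, 3.05}} pair recovered: {100 * pair:.0f}% of {args.n_seeds} seeds")
    print(f"median test BER at selected k: {df['test_ber_pct'].median():.1f}%")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
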