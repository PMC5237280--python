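#!/usr/bin/env python
"""Dichotomized diagnostic metrics from the published training-set counts.

The published one-vs-rest counts fully determine both 3x3 training-set
confusion matrices; this script reconstructs them, recomputes
sensitivity/specificity/PPV/NPV for every class and the balanced error
rate, and writes the table to results/tables/published_metrics.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from strokemrs.evaluate import ConfusionMatrix3, ber, dichotomize

MATRICES = {
    "infarct_evolution": ConfusionMatrix3(
        np.array([[32, 0, 0], [0, 13, 0], [0, 2, 7]]),
        ["non_infarcted", "acute", "subacute"],
    ),
    "brain_regions": ConfusionMatrix3(
        np.array([[27, 4, 1], [12, 41, 1], [0, 0, 22]]),
        ["non_infarcted", "svz", "infarcted"],
    ),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/tables/published_metrics.tsv")
    args = ap.parse_args()

    rows = []
    for name, cm in MATRICES.items():
        print(f"[{name}] training BER = {ber(cm):.1f}%")
        for cls in cm.class_names:
            d = dichotomize(cm, cls)
            rows.append(
                {
                    "classifier": name,
                    "class": cls,
                    "tp": d.tp,
                    "fn": d.fn,
                    "fp": d.fp,
                    "tn": d.tn,
                    "sensitivity": d.sensitivity,
                    "specificity": d.specificity,
                    "ppv": d.ppv,
                    "npv": d.npv,
                }
            )
            print(
                f"  {cls:14s} sens {d.sensitivity:5.1f}  spec {d.specificity:5.1f}  "
                f"ppv {d.ppv:5.1f}  npv {d.npv:5.1f}"
            )
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.2f")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
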