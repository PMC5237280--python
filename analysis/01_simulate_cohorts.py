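#!/usr/bin/env python
"""Generate the two study-sized synthetic MRS cohorts.

Writes, for each scenario, the spectrum table, the metadata table and
the ground-truth diagnostic-peak table under results/cohorts/.  The
infarct-evolution cohort has 48/20/14 spectra (non-infarcted / acute /
subacute), the brain-regions cohort 48/82/34 (non-infarcted / SVZ /
infarcted), each with contralateral reference pairing and a ~2/3
chronological train/test split by animal ID.
"""

import argparse

from strokemrs.pipeline import RunConfig, run_simulation


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", default="results/cohorts")
    args = ap.parse_args()

    for scenario in ("infarct_evolution", "brain_regions"):
        paths = run_simulation(
            RunConfig(scenario=scenario, seed=args.seed, out_dir=f"{args.out}/{scenario}")
        )
        print(f"[{scenario}]")
        for kind, path in paths.items():
            print(f"  {kind}: {path}")


if __name__ == "__main__":
    main()
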