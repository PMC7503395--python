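#!/usr/bin/env python
"""Run the full per-cell and per-AIS analysis over the saved cohort.

Per cell: passive properties from the seal test (Rs, Rin, Cm, tau), resting
potential, rheobase from the 5 pA protocol, f-I gain and maximal frequency
from the 20 pA protocol, and phase-plane AP metrics (threshold at 20 V/s,
dV/dt extrema, half-width, IS/SD components, after-potential class) from the
first AP at rheobase. Per AIS profile: length by the relative-threshold
(30% of maximum) method. Derived: per-group AIS capacitance, estimated AIS
inward current per cell, and the rheobase = V/R_In hyperbola.

Reads results/cohort/, writes results/run/ (features.csv, ais.csv,
group_derived.csv, stats/, manifest.json).
"""

import argparse
from pathlib import Path

from aismature.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    res = run_pipeline(args.cohort, out_dir=args.out, config=RunConfig(seed=args.seed))
    print(f"analyzed {len(res.features)} cells ({len(res.failures)} failed), "
          f"{len(res.ais)} AIS profiles")
    print(f"rheobase-Rin hyperbola: V = {res.hyperbola.V:.2f} mV over "
          f"{res.hyperbola.n} cells")
    cols = ["cm_pF", "rin_Mohm", "rheobase_pA", "threshold_mV", "half_width_ms",
            "est_i_in_ais_pA"]
    print(res.features.groupby("group")[cols].mean().round(2))


if __name__ == "__main__":
    main()
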