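#!/usr/bin/env python
"""Generate the five-age-group synthetic cohort and persist it with its truth.

The cohort emulates the study design for postnatal maturation of motor-cortex
layer-V pyramidal neurons: five age groups from the first postnatal week to
adulthood, ~20-25 cells from >= 3 animals per group for electrophysiology
(seal test, 5 pA rheobase protocol, 20 pA f-I protocol per cell) and 100 AIS
fluorescence line profiles per animal for morphometry. Ground truth for every
cell and AIS is written to manifest CSVs.

Writes results/cohort/ (raw data + manifests).
"""

import argparse
from pathlib import Path

from aismature.synth import CohortSpec, generate_cohort, save_cohort

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    spec = CohortSpec(seed=args.seed)
    cohort = generate_cohort(spec)
    save_cohort(cohort, args.out)

    m = cohort.manifest
    print(f"cohort written to {args.out}")
    print(f"  {len(m)} cells in {m['animal_id'].nunique()} animals, "
          f"{len(cohort.ais_manifest)} AIS profiles")
    print(m.groupby("group")[["cm_pF", "rin_Mohm", "ais_length_um"]].mean().round(1))


if __name__ == "__main__":
    main()
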