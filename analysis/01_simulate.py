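#!/usr/bin/env python
"""Generate the synthetic training (n=80) and validation (n=145) cohorts.

Writes full on-disk cohorts (patch tables, GeoJSON tumor loops, clinical
and ground-truth tables) under scratch/cohorts/ — they are several MB, so
they live outside results/ — and prints the cohort marginals that the
generator is meant to emulate (depth median, ulceration rate, TIL-grade
distribution, event fraction).
"""

import argparse
from pathlib import Path

import numpy as np

from adta.simulate import SimConfig, gen_cohort, write_cohort

ROOT = Path(__file__).resolve().parent.parent


def describe(name, cohort):
    recs = cohort.clinical_records()
    depth = np.array([r.depth_mm for r in recs])
    grades = np.array([r.til_grade for r in recs])
    print(f"{name}: n={len(recs)}")
    print(f"  depth median {np.median(depth):.2f} mm; "
          f"ulceration {np.mean([r.ulceration for r in recs]):.2f}; "
          f"events {np.mean([r.dss_event for r in recs]):.2f}")
    print(f"  TIL grades absent/non-brisk/brisk: "
          f"{(grades == 0).sum()}/{(grades == 1).sum()}/{(grades == 2).sum()}")
    print(f"  high-infiltrate (true low-risk) fraction: "
          f"{np.mean([p.true_risk_class == 'low_risk' for p in cohort.patients]):.2f}")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    out = ROOT / "scratch" / "cohorts"
    for name, n, seed in (("training", 80, 2 * args.seed),
                          ("validation", 145, 2 * args.seed + 1)):
        cohort = gen_cohort(SimConfig(seed=seed, n_patients=n))
        write_cohort(cohort, out / name)
        describe(name, cohort)
    print(f"cohorts written to {out}")


if __name__ == "__main__":
    main()
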