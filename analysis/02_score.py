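#!/usr/bin/env python
"""Score every image and patient in the on-disk cohorts.

Reads scratch/cohorts/{training,validation} (written by 01_simulate.py),
restricts each patch map to its tumor loop, applies the 0.775 positivity
threshold, and aggregates image positive-fractions to per-patient medians.
Writes image- and patient-level score tables under results/.
"""

import argparse
from pathlib import Path

from adta.pipeline import image_scores_to_frame, score_cohort_dir, scores_to_frame

ROOT = Path(__file__).resolve().parent.parent


def main():
    argparse.ArgumentParser().parse_args()
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    for name in ("training", "validation"):
        cohort_dir = ROOT / "scratch" / "cohorts" / name
        if not cohort_dir.exists():
            raise SystemExit(f"{cohort_dir} not found; run 01_simulate.py first")
        scores = score_cohort_dir(cohort_dir)
        image_scores_to_frame(scores).to_csv(
            out / f"{name}_image_scores.csv", index=False
        )
        frame = scores_to_frame(scores)
        frame.to_csv(out / f"{name}_patient_scores.csv", index=False)
        print(f"{name}: {len(frame)} patients; "
              f"score range {frame['adta'].min():.3f}-{frame['adta'].max():.3f}, "
              f"median {frame['adta'].median():.3f}")


if __name__ == "__main__":
    main()
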