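#!/usr/bin/env python
"""Select the risk cutoff on the training cohort.

Builds the ROC of per-patient scores against died-of-melanoma and picks
the Youden-optimal threshold (midpoint candidates, smaller threshold on
ties).  Writes results/roc.csv and results/cutoff.json and reports how the
chosen cutoff compares with the alternative criteria.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from adta.cutoff import select_cutoff
from adta.io import read_clinical_table
from adta.pipeline import train_cutoff
from adta.scoring import ImageScore, score_patient

ROOT = Path(__file__).resolve().parent.parent


def load_scores(name):
    df = pd.read_csv(ROOT / "results" / f"{name}_image_scores.csv")
    return [
        score_patient(
            str(pid),
            [ImageScore(str(r.image_id), int(r.n_total), int(r.n_pos))
             for r in sub.itertuples(index=False)],
        )
        for pid, sub in df.groupby("patient_id", sort=True)
    ]


def main():
    argparse.ArgumentParser().parse_args()
    scores = load_scores("training")
    clinical = read_clinical_table(
        ROOT / "scratch" / "cohorts" / "training" / "clinical.csv"
    )
    cut, roc = train_cutoff(scores, clinical)
    print(f"chosen cutoff (Youden): {cut:.4f}; AUC = {roc.auc:.3f}")
    for crit in ("accuracy", "closest_topleft"):
        print(f"  criterion {crit}: {select_cutoff(roc, crit):.4f}")
    out = ROOT / "results"
    pd.DataFrame({
        "threshold": roc.thresholds,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
        "youden_j": roc.youden_j,
    }).to_csv(out / "roc.csv", index=False)
    with open(out / "cutoff.json", "w") as fh:
        json.dump({"cutoff": cut, "auc": roc.auc}, fh, indent=2)


if __name__ == "__main__":
    main()
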