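#!/usr/bin/env python
"""Validate the risk classification on the held-out cohort.

Applies the training-derived cutoff to the validation cohort and runs the
survival and association analyses: Kaplan-Meier curves per risk group with
at-risk counts at 0 and 100 months, the log-rank test, univariable Cox
models for the risk indicator and each pathology covariate, the three
multivariable models (risk + depth + ulceration; risk + T stage;
risk + stage), score-vs-TIL-grade Spearman and Kruskal-Wallis, and
per-institution log-rank tests.  Writes results/validation_summary.csv and
results/km.csv, and a KM figure under scratch/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from adta.io import read_clinical_table
from adta.scoring import HIGH_RISK, LOW_RISK
from adta.pipeline import validate_cohort

ROOT = Path(__file__).resolve().parent.parent


def main():
    argparse.ArgumentParser().parse_args()
    import importlib.util

    spec = importlib.util.spec_from_file_location(
        "cutoff_step", Path(__file__).parent / "03_cutoff.py"
    )
    step3 = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(step3)

    scores = step3.load_scores("validation")
    clinical = read_clinical_table(
        ROOT / "scratch" / "cohorts" / "validation" / "clinical.csv"
    )
    with open(ROOT / "results" / "cutoff.json") as fh:
        cut = json.load(fh)["cutoff"]
    report = validate_cohort(scores, clinical, cut)

    print(f"cutoff {cut:.4f}: "
          f"{(report.scores['risk_class'] == LOW_RISK).sum()} low-risk, "
          f"{(report.scores['risk_class'] == HIGH_RISK).sum()} high-risk")
    print(f"log-rank p = {report.logrank.p_value:.4g}")
    print(f"at risk at 0 / 100 months: low {report.km_low.at_risk[0]} / "
          f"{report.km_low.at_risk[1]}, high {report.km_high.at_risk[0]} / "
          f"{report.km_high.at_risk[1]}")
    for name, fit in report.cox_multivariable.items():
        i = fit.covariates.index("high_risk")
        print(f"Cox [{name}]: risk HR = {fit.hazard_ratio[i]:.2f} "
              f"(CI {fit.ci_low[i]:.2f}-{fit.ci_high[i]:.2f}, "
              f"p = {fit.p_value[i]:.3g}, n = {fit.n_used})")
    if report.spearman:
        print(f"Spearman rho vs TIL grade: {report.spearman.rho:.3f} "
              f"(p = {report.spearman.p_value:.3g})")
    if report.grade_comparison:
        print(f"Kruskal-Wallis across grades: H = "
              f"{report.grade_comparison.statistic:.2f} "
              f"(p = {report.grade_comparison.p_value:.3g})")
    for inst, lr in report.per_institution_logrank.items():
        print(f"  {inst}: log-rank p = {lr.p_value:.4g}")

    out = ROOT / "results"
    report.summary_frame().to_csv(out / "validation_summary.csv", index=False)
    km_rows = []
    for label, km in ((LOW_RISK, report.km_low), (HIGH_RISK, report.km_high)):
        for t, s in zip(km.event_times, km.survival):
            km_rows.append({"group": label, "kind": "survival", "time": t,
                            "value": s})
        for t, n in zip(km.report_times, km.at_risk):
            km_rows.append({"group": label, "kind": "at_risk", "time": t,
                            "value": n})
    pd.DataFrame(km_rows).to_csv(out / "km.csv", index=False)

    _plot(report)


def _plot(report):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for km, label, color in ((report.km_low, "low risk", "tab:blue"),
                             (report.km_high, "high risk", "tab:red")):
        t = [0.0] + list(km.event_times)
        s = [1.0] + list(km.survival)
        ax.step(t, s, where="post", label=label, color=color)
    ax.set_xlabel("months")
    ax.set_ylabel("disease-specific survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    fig.savefig(scratch / "km_validation.png", dpi=150, bbox_inches="tight")
    print(f"KM figure -> {scratch / 'km_validation.png'}")


if __name__ == "__main__":
    main()
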