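#!/usr/bin/env python
"""Fit the statistical layer on the processed demonstration study.

Runs the mixed-effects regressions (trial + division, with and without EMG
covariates), residual diagnostics and the repeated-measures ANOVA of the
accelerometer summaries, writing all tables under ``results/analysis`` and
printing the Fatigue-trial coefficients — the study's headline contrast.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from ripfatigue.cli_reporting import cmd_analyze

    table = ROOT / "scratch" / "processed" / "decile_table.csv"
    if not table.exists():
        sys.exit("run analysis/02_process.py first")
    out = ROOT / "results" / "analysis"
    cmd_analyze(table, out, accel_table=ROOT / "results" / "accel_trials.csv")

    models = pd.read_csv(out / "mixed_models.csv")
    fatigue = models[models.term.str.startswith("trial[", na=False)]
    print("Fatigue-trial fixed effects (z-scored scale):")
    cols = ["dependent", "approach", "term", "beta", "z", "p"]
    print(fatigue[cols].round(3).to_string(index=False))

    neg = fatigue[fatigue.dependent.str.startswith("rip")]
    print(f"\nRIP trial coefficients negative: {(neg.beta < 0).sum()}/{len(neg)}"
          f" (synchrony drops from Baseline to the Fatigue trials)")
    anova = pd.read_csv(out / "accel_rm_anova.csv")
    print("\nrepeated-measures ANOVA of the accelerometer summaries:")
    print(anova[["metric", "F", "df1", "df2", "p", "partial_eta_sq"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
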