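#!/usr/bin/env python
"""Render decile-profile figures for the demonstration study.

Plots per-metric decile profiles per trial (mean +/- SD over subjects) to
``scratch/figures``; figures are advisory and are not version-controlled.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from ripfatigue.cli_reporting import cmd_report

    table = ROOT / "results" / "decile_table.csv"
    if not table.exists():
        sys.exit("run analysis/02_process.py first")
    out = ROOT / "scratch" / "figures"
    cmd_report(table, out)
    print(f"figures written to {out}")


if __name__ == "__main__":
    main()
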