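#!/usr/bin/env python
"""Generate the demonstration study.

Writes a synthetic multi-subject study to ``scratch/demo_study`` (raw
recordings are large and stay out of version control) and copies the study
manifest to ``results/``.  The demo uses a reduced design — 10 subjects,
200-s trials sampled at 500 Hz — that keeps every pipeline stage exercised
while the full-size defaults (22 subjects, 600-s trials, 1000 Hz) remain
the generator's defaults.
"""

import json
import shutil
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from ripfatigue.synthetic_data import StudyConfig, gen_study

    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    cfg = StudyConfig(n_subjects=10, trial_length_s=200.0, rest_length_s=20.0,
                      inter_trial_gap_s=10.0, sampling_rate_hz=500.0,
                      cycles_per_trial=(30, 28, 26), seed=seed)
    out = ROOT / "scratch" / "demo_study"
    if out.exists():
        shutil.rmtree(out)
    paths = gen_study(cfg, out)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    shutil.copy(out / "study_manifest.json", results / "study_manifest.json")

    manifest = json.loads((out / "study_manifest.json").read_text())
    print(f"wrote {len(paths)} subject recordings to {out}")
    print(f"  trials: 3 x {cfg.trial_length_s:.0f} s at {cfg.sampling_rate_hz:.0f} Hz, "
          f"seed {manifest['seed']}")
    print(f"  phase-lag means per trial (rad): {cfg.phase_lag_rad}")
    print(f"  biceps %MVC targets: {cfg.emg['biceps'].amp_pct_mvc}")


if __name__ == "__main__":
    main()
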