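"""In-memory study workflows shared by the analysis scripts and tests.

These run the generator and the signal pipelines without touching disk,
which keeps replicated parameter-recovery and calibration studies cheap.
"""

from __future__ import annotations

import numpy as np

from .accel_pipeline import AccelFrame, AccelParams, accel_trial_summary
from .emg_pipeline import EMGParams, emg_decile_records
from .rip_pipeline import RIPParams, compute_rip_synchrony, synchrony_decile_records
from .signal_model import DecileTable, Recording, slice_annotation
from .synthetic_data import StudyConfig, gen_recording

__all__ = ["simulate_study", "study_decile_table", "accel_trial_table",
           "null_decile_table"]

TRIALS = ("Baseline", "Fatigue 1", "Fatigue 2")


def simulate_study(cfg: StudyConfig, seed: int | None = None
                   ) -> list[tuple[Recording, dict]]:
    """Generate all subjects of a study in memory: [(Recording, truth), ...]."""
    root_seed = cfg.seed if seed is None else seed
    seeds = np.random.SeedSequence(root_seed).spawn(cfg.n_subjects)
    return [gen_recording(cfg, i, np.random.default_rng(seeds[i]))
            for i in range(cfg.n_subjects)]


def study_decile_table(study: list[tuple[Recording, dict]],
                       rip_params: RIPParams | None = None,
                       emg_params: EMGParams | None = None) -> DecileTable:
    """Decile metrics for every subject, for whichever modalities are present."""
    records: list[dict] = []
    for rec, _ in study:
        if "rip_chest" in rec.channels:
            records += synchrony_decile_records(
                compute_rip_synchrony(rec, rip_params), rec.subject_id)
        if "emg_biceps" in rec.channels:
            records += emg_decile_records(rec, emg_params)
    return DecileTable.from_records(records)


def accel_trial_table(study: list[tuple[Recording, dict]],
                      params: AccelParams | None = None):
    """Per-trial accelerometer summaries (n_cycles, pitch, roll) as a DataFrame."""
    import pandas as pd

    rows = []
    for rec, _ in study:
        for ann in sorted(rec.trial_annotations(), key=lambda a: a.start_s):
            sub = slice_annotation(rec, ann)
            frame = AccelFrame.from_channels(sub.channels["acc_x"],
                                             sub.channels["acc_y"],
                                             sub.channels["acc_z"])
            n_cycles, p_amp, r_amp = accel_trial_summary(frame, params=params)
            rows.append({"subject_id": rec.subject_id, "trial": ann.name,
                         "n_cycles": n_cycles, "pitch": p_amp, "roll": r_amp})
    return pd.DataFrame(rows)


def null_decile_table(n_subjects: int, rng: np.random.Generator,
                      subject_sd: float = 0.8, resid_sd: float = 0.6,
                      metric: str = "m") -> DecileTable:
    """A decile table with *no* trial or division effects.

    Value = subject random intercept + iid Gaussian noise; used to calibrate
    the type-I error of the mixed-model trial terms.
    """
    rows = []
    for s in range(n_subjects):
        off = rng.normal(0.0, subject_sd)
        for t in TRIALS:
            for d in range(1, 11):
                rows.append({"subject_id": f"S{s:02d}", "trial": t, "division": d,
                             "metric": metric, "value": off + rng.normal(0.0, resid_sd)})
    return DecileTable.from_records(rows)
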