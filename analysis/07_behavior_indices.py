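#!/usr/bin/env python
"""Behavioral indices from toy event data: sucrose preference and freezing.

Builds per-subject freezing-bout logs consistent with each subject's daily
counts (bouts placed inside the four tone-locked 60 s epochs), quantifies
them with the epoch machinery, and computes sucrose preference indices from
the consumed volumes.  Writes results/behavior_indices.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import fcnet as f
from fcnet.behavior import FearSessionSpec, FreezeEventLog, epoch_windows

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260930


def make_log(subject_id: str, day: int, n_bouts: int, rng) -> FreezeEventLog:
    """Place n_bouts 1.2-3 s bouts uniformly across the four epochs."""
    spec = FearSessionSpec()
    windows = epoch_windows(spec)
    events = []
    for b in range(n_bouts):
        w0, w1 = windows[b % len(windows)]
        slot = (w1 - w0) / (n_bouts // len(windows) + 1)
        start = w0 + (b // len(windows)) * slot + 0.1
        events.append((start, start + float(rng.uniform(1.2, 3.0))))
    events.sort()
    # drop any accidental overlap from dense packing
    clean = []
    for s, e in events:
        if not clean or s >= clean[-1][1]:
            clean.append((s, e))
    return FreezeEventLog(subject_id, day, clean)


if __name__ == "__main__":
    cohort_spec = f.CohortSpec(seed=SEED)
    behavior = pd.read_csv(ROOT / "results" / "behavior_tables.csv")
    session = FearSessionSpec()
    rng = np.random.default_rng(SEED)
    rows = []
    for rec in behavior.itertuples():
        row = {"subject_id": rec.subject_id, "group": rec.group,
               "sucrose_index": f.sucrose_index(
                   f.SucroseRecord(rec.subject_id, rec.sucrose_ml, rec.water_ml))}
        for day in (1, 2, 3):
            n = int(getattr(rec, f"freezing_counts_d{day}"))
            log = make_log(rec.subject_id, day, n, rng)
            counts, total, pct = f.freezing_counts(log, session)
            row[f"freezing_total_d{day}"] = total
            row[f"freezing_pct_time_d{day}"] = pct.mean()
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "behavior_indices.csv", index=False)

    print("behavioral indices by group:")
    cols = ["sucrose_index", "freezing_total_d1", "freezing_total_d3",
            "freezing_pct_time_d3"]
    print(df.groupby("group")[cols].mean().round(3).to_string())
    print("-> all groups prefer sucrose (index > 0); the 60wo group freezes "
          "most, mirroring the planted behavior effects.")
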