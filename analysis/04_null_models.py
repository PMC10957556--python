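#!/usr/bin/env python
"""Fidelity of the signed strength/degree-preserving randomization.

For each subject's full signed Fisher-z matrix: one randomization (5 swap
passes, greedy weight re-sorting), then the Pearson correlation between
original and randomized positive / negative strength sequences, plus the
small-world coefficient of the 16% network against a 10-matrix ensemble.
Writes results/null_fidelity.csv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import fcnet as f

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260930

if __name__ == "__main__":
    spec = f.CohortSpec(seed=SEED)
    rows = []
    for i, subj in enumerate(f.make_cohort(spec)):
        c = f.correlation_matrix(f.SubjectTimeseries(subj.subject_id, subj.timeseries))
        rand = f.randomize_signed(c, n_swap_iters=5, seed=SEED + i)
        pos = np.where(c.z > 0, c.z, 0).sum(1)
        neg = np.where(c.z < 0, -c.z, 0).sum(1)
        neg_rand = np.where(rand < 0, -rand, 0).sum(1)
        rows.append({
            "subject_id": subj.subject_id, "group": subj.group,
            "r_strength_pos": np.corrcoef(pos, np.where(rand > 0, rand, 0).sum(1))[0, 1],
            # subjects with (almost) no negative edges have no sequence to compare
            "r_strength_neg": (np.corrcoef(neg, neg_rand)[0, 1]
                               if neg.std() > 0 and neg_rand.std() > 0 else np.nan),
        })
        net = f.proportional_threshold(c, 0.16)
        ens = f.null_ensemble(net, m=10, seed=SEED + i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows[-1]["swc_16pct"] = f.small_world(net, ens.matrices).swc
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "null_fidelity.csv", index=False)

    print(f"strength-sequence fidelity over {len(df)} subjects:")
    print(f"  positive: mean r = {df.r_strength_pos.mean():.4f} "
          f"(min {df.r_strength_pos.min():.4f})")
    print(f"  negative: mean r = {df.r_strength_neg.mean():.4f} "
          f"(min {df.r_strength_neg.min():.4f})")
    print(f"  SWC at 16% density: mean {df.swc_16pct.mean():.3f} "
          "(> 1: modular networks are small-world-like vs matched nulls)")
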