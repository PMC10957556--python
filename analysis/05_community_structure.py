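#!/usr/bin/env python
"""Consensus modularity at 16% density and recovery of the planted modules.

Per subject: consensus over 100 Louvain restarts on the 16%-thresholded
network, module census, adjusted Rand index against the planted 4-module
partition, and mean participation coefficient under the consensus partition.
Writes results/module_census.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

import fcnet as f

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260930

if __name__ == "__main__":
    spec = f.CohortSpec(seed=SEED)
    rows = []
    for i, subj in enumerate(f.make_cohort(spec)):
        c = f.correlation_matrix(f.SubjectTimeseries(subj.subject_id, subj.timeseries))
        net = f.proportional_threshold(c, 0.16)
        res = f.consensus_partition(net, n_iter=100, seed=SEED + i)
        p = f.participation_coefficient(net, res.final_partition.affiliation)
        rows.append({
            "subject_id": subj.subject_id, "group": subj.group,
            "n_modules": res.n_modules,
            "q_consensus": res.final_partition.q,
            "q_median": res.q_summary,
            "ari_vs_planted": adjusted_rand_score(
                subj.planted_partition, res.final_partition.affiliation),
            "mean_participation": p.mean(),
        })
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "module_census.csv", index=False)

    print("consensus modularity at 16% density, by group:")
    print(df.groupby("group")[["n_modules", "q_consensus", "ari_vs_planted",
                               "mean_participation"]].mean().round(4).to_string())
    frac = (df.ari_vs_planted >= 0.9).mean()
    print(f"-> {frac:.0%} of subjects recover the planted partition at "
          "ARI >= 0.9.  At this sparse density nearly all retained edges are "
          "within-module in every group (hence participation ~ 0 and flat Q); "
          "the group difference in modularity emerges at higher densities "
          "and is captured by the AUC in step 03.")
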