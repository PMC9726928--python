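#!/usr/bin/env python
"""Baseline change-of-mind agent and the origin of its sunk-cost sensitivity.

Runs the original model (W_T = 18 s, sigma_W = 5, sigma_N = 3, threshold
accept policy) and its accept-all counterpart, then compares the three key
measures.  The accept-all variant removes most of the offer-zone selection:
if the sunk-cost bubble were an attrition artifact it should shrink with the
attrition slope — instead it persists (it typically grows), while the
attrition slope drops.

Writes results/baseline_measures.tsv and the two p(Earn) tables.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sunkddm import SimConfig, run_experiment
from sunkddm.measures import build_pearn_matrix, compute_measures

N_TRIALS = 200_000
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for policy in ("threshold", "accept_all"):
    cfg = SimConfig(accept_policy=policy, n_trials=N_TRIALS, seed=42)
    session = run_experiment(cfg)
    ms = compute_measures(session)
    rows.append(
        {
            "policy": policy,
            "n_trials": N_TRIALS,
            "accept_rate": session.df["accepted"].mean(),
            "quit_rate_given_accept": (session.df["outcome"] == "quit").sum()
            / session.df["accepted"].sum(),
            "bubble_total": ms.bubble_total,
            "baseline_slope": ms.baseline_slope,
            "attrition_slope": ms.attrition_slope,
            "probit_tangent": ms.probit_tangent,
        }
    )
    build_pearn_matrix(session).to_long().to_csv(
        OUT / f"pearn_{policy}.tsv", sep="\t", index=False
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "baseline_measures.tsv", sep="\t", index=False)
print(df.to_string(index=False))
thr, all_ = df.iloc[0], df.iloc[1]
print(
    f"\nAccept-all cuts the attrition slope from {thr.attrition_slope:.3f} to "
    f"{all_.attrition_slope:.3f} but the sunk-cost bubble goes from "
    f"{thr.bubble_total:.1f} to {all_.bubble_total:.1f}: the bubble is not an "
    "attrition artifact."
)
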