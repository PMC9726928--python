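#!/usr/bin/env python
"""The reset hypothesis: does commitment escalation include the decision time?

Accept-all agents are barred from quitting for the first DT seconds (a
covert offer-zone-like deliberation), with the willingness reset to W0 when
DT ends.  Two hypotheses about the quit bound:

* model 1 — the bound sits at the offer until DT ends, then descends 1 s/s:
  sunk costs start accruing only after the covert decision;
* model 2 — the bound descends from wait-zone entry: the decision time is
  part of the sunk costs.

Summed sunk-cost sensitivity vs DT separates them: model 1 declines almost
linearly, model 2 declines with strong deceleration (large positive
quadratic term).  Writes results/reset_experiment.tsv and .json.
"""

import dataclasses
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sunkddm import SimConfig
from sunkddm.experiments import run_reset_experiment

TRIALS_PER_DT = 100_000
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows, fits = [], {}
for model in ("model1", "model2"):
    res = run_reset_experiment(SimConfig(seed=9), model, trials_per_dt=TRIALS_PER_DT)
    fits[model] = dataclasses.asdict(res.linquad)
    for dt, b in zip(res.decision_times, res.bubble_totals):
        rows.append({"model": model, "decision_time_s": dt, "bubble_total": b})
    print(
        f"{model}: lin adjR2={res.linquad.linear_adj_r2:.4f}, "
        f"quad adjR2={res.linquad.quad_adj_r2:.4f}, "
        f"quad coef={res.linquad.quad_coef:+.3f}"
    )

pd.DataFrame(rows).to_csv(OUT / "reset_experiment.tsv", sep="\t", index=False)
(OUT / "reset_experiment.json").write_text(json.dumps(fits, indent=2) + "\n")
print(
    "\nModel 2's quadratic term dwarfs model 1's: the curvature of total "
    "sensitivity against decision time discriminates whether the expanding "
    "bound runs through the deliberation period."
)
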