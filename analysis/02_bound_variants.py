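#!/usr/bin/env python
"""Where the model's sunk-cost sensitivity comes from: bound-shape variants.

The original agent has an expanding lower bound (quit threshold starting at
the offer and descending 1 s/s) and no upper bound on the drifting
willingness-to-wait.  Both features inject time-spent information into the
quit decision.  This script runs the variants that remove or invert them:

* flat bound at the offer (descent removed)  -> sensitivity shrinks;
* flat bound at zero                         -> quits almost disappear;
* anti-sunk bound (ascending 1 s/s)          -> the bubble inverts;
* monotone drift (W may never rise), alone and combined with the flat bound.

Writes results/bound_variants.tsv.  Sparse p(Earn) cells are guarded with a
min-count of 10 so single stray trials cannot dominate a bubble sum.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sunkddm import SimConfig, run_experiment
from sunkddm.measures import PEarnMatrix, build_pearn_matrix, sunk_cost_bubble

N_TRIALS = 200_000
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

VARIANTS = {
    "original": {},
    "flat_bound_at_offer": {"twz_slope": 0.0},
    "flat_bound_at_zero": {"twz_init": "zero", "twz_slope": 0.0},
    "anti_sunk_ascending": {"twz_slope": +1.0},
    "monotone_drift": {"upper_bound": "non_increasing"},
    "flat_bound_monotone_drift": {"twz_slope": 0.0, "upper_bound": "non_increasing"},
}

rows = []
for name, kw in VARIANTS.items():
    cfg = SimConfig(n_trials=N_TRIALS, seed=7, **kw)
    session = run_experiment(cfg)
    m = build_pearn_matrix(session)
    guarded = PEarnMatrix(m.n_pass, m.n_earn, min_count=10)
    acc = session.df[session.df["accepted"]]
    rows.append(
        {
            "variant": name,
            "quit_rate": (acc["outcome"] == "quit").mean(),
            "bubble_total": sunk_cost_bubble(guarded).total,
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "bound_variants.tsv", sep="\t", index=False)
print(df.to_string(index=False))
print(
    "\nThe ascending bound inverts the bubble (easier to quit the longer the "
    "wait); removing the descent shrinks it; blocking upward drift erodes the "
    "surviving willingness toward the bound and pushes the bubble negative."
)
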