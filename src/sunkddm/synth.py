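"""Hazard-model synthetic behavioral sessions with known ground truth.

This generator deliberately lives outside the drift-diffusion family: it
emulates the statistical structure the measures assume (per-site accept
thresholds, a noisy psychometric accept rule, a per-second quit hazard with
an optional sunk-cost term) without sharing any machinery with the simulator
those measures are used to analyse.  That makes it an independent validation
bed: the sign and size of the sunk-cost bubble, the recovered thresholds and
the recovered sigma_W can all be checked against the generating parameters,
and p(Earn) has a closed form.

Model per trial (sites visited cyclically, offers uniform on the support):

* accept with probability ``lapse + (1 - 2*lapse) * Phi((threshold_site -
  offer) / accept_noise)`` (symmetric-lapse probit psychometric);
* if accepted, quit at the first second ``t = 1..offer-1`` with hazard
  ``h(t) = logistic(logit(h0) + c_rem*(offer - t) + c_spent*t)``;
  earn if no quit fires.

A negative ``hazard_coef_spent`` makes quitting harder the longer the agent
has waited — an explicit escalation of commitment, which the bubble measure
must recover as positive; zero gives a memoryless-in-spent hazard and a null
bubble.  Because the hazard is known, p(Earn | spent s, offer D) is exactly
the survival product over the remaining quit opportunities,
``prod_{t=s+1}^{D-1} (1 - h(t))`` — an analytic oracle for the entire
measurement chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .trials import CSV_COLUMNS, SessionSet, config_hash

__all__ = ["BehaviorGenConfig", "quit_hazard", "pearn_survival", "generate_sessions"]

DEFAULT_SITES = {"R1": 12.0, "R2": 16.0, "R3": 20.0, "R4": 24.0}


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Ground-truth parameters for a synthetic behavioral session.

    Defaults give four sites with distinct thresholds (as in the four
    restaurants/galleries), a probit accept rule with 5 s spread, a small
    lapse, and a mild sunk-cost hazard (quitting gets harder with time
    spent).
    """

    site_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_SITES))
    accept_noise: float = 5.0
    lapse: float = 0.02
    quit_hazard_base: float = 0.06
    hazard_coef_remaining: float = 0.08
    hazard_coef_spent: float = -0.15
    n_trials: int = 10_000
    offer_support: tuple[int, int] = (1, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.quit_hazard_base < 1):
            raise ValueError("quit_hazard_base must be in (0, 1)")
        if not (0 <= self.lapse < 0.5):
            raise ValueError("lapse must be in [0, 0.5)")
        if self.accept_noise <= 0:
            raise ValueError("accept_noise must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def quit_hazard(config: BehaviorGenConfig, offer: np.ndarray | int, t: np.ndarray | int):
    """Per-second quit probability at second ``t`` of an ``offer``-second delay."""
    offer = np.asarray(offer, dtype=float)
    t = np.asarray(t, dtype=float)
    eta = (
        logit(config.quit_hazard_base)
        + config.hazard_coef_remaining * (offer - t)
        + config.hazard_coef_spent * t
    )
    out = expit(eta)
    return out if out.ndim else float(out)


def pearn_survival(config: BehaviorGenConfig, offer: int, spent: int) -> float:
    """Closed-form p(Earn) from state (spent s, offer D): the survival product
    of (1 - hazard) over the remaining quit opportunities t = s+1 .. D-1."""
    ts = np.arange(spent + 1, offer)
    if ts.size == 0:
        return 1.0
    return float(np.prod(1.0 - quit_hazard(config, offer, ts)))


def generate_sessions(
    config: BehaviorGenConfig, subject_id: str = "synth", session_id: str | None = None
) -> SessionSet:
    """Generate one synthetic session; deterministic given the seed.

    Sites are visited cyclically, mirroring the serial restaurant/gallery
    encounters of the task.  The output always satisfies the trial-log
    invariants.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    lo, hi = config.offer_support
    n = config.n_trials
    sites = list(config.site_thresholds)
    site_idx = np.arange(n) % len(sites)
    thresholds = np.array([config.site_thresholds[s] for s in sites])[site_idx]
    offers = rng.integers(lo, hi + 1, size=n)

    from scipy.stats import norm

    p_accept = config.lapse + (1 - 2 * config.lapse) * norm.cdf(
        (thresholds - offers) / config.accept_noise
    )
    accepted = rng.random(n) < p_accept

    t = np.arange(1, hi)  # quit opportunities
    haz = quit_hazard(config, offers[:, None], t[None, :])
    live = t[None, :] <= (offers - 1)[:, None]
    fires = accepted[:, None] & live & (rng.random((n, t.size)) < haz)
    any_quit = fires.any(axis=1)
    quit_t = np.where(any_quit, fires.argmax(axis=1) + 1, 0)

    outcome = np.where(~accepted, "skip", np.where(any_quit, "quit", "earn"))
    time_spent = np.where(~accepted, 0, np.where(any_quit, quit_t, offers)).astype(int)
    cfg_dict = asdict(config)
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "session_id": session_id or f"synth-seed{config.seed}",
            "site_id": np.array(sites)[site_idx],
            "offer_s": offers.astype(int),
            "accepted": accepted,
            "time_spent_s": time_spent,
            "outcome": outcome,
            "w0": np.nan,
        },
        columns=CSV_COLUMNS,
    )
    meta = {
        "generator": "sunkddm.synth.generate_sessions",
        "config": cfg_dict,
        "config_hash": config_hash(cfg_dict),
        "seed": config.seed,
        "offer_support": list(config.offer_support),
    }
    return SessionSet(df=df, meta=meta)
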