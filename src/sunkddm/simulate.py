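"""Change-of-mind drift-diffusion agent for delay-foraging tasks.

The agent makes two decisions on every trial.  In the *offer zone* it draws an
initial willingness-to-wait ``W0 = W_T + N(0, sigma_w)`` around its preference
threshold ``W_T`` (default 18 s) and accepts the offered delay iff
``W0 >= offer`` (or unconditionally under the accept-all policy).  In the
*wait zone* the willingness drifts once per second,
``W(t+1) = W(t) + N(0, sigma_n)``, and the agent quits the countdown the first
second at which ``W(t)`` falls below a time-varying quit threshold ``T_WZ(t)``.
If it never quits before the countdown ends, it earns the reward.

In the original formulation ``T_WZ`` starts at the offer on wait-zone entry
and decreases by 1 s per second, reaching 0 exactly when the reward arrives —
an *expanding* lower bound that moves away from ``W0`` with time spent, which
is one of the two mechanisms that build sunk-cost sensitivity directly into
the model.  Variants exercised here:

* ``twz_slope``: -1 (original), 0 (flat bound), +1 (anti-sunk-cost,
  a collapsing bound that makes quitting easier with time spent);
* ``twz_init``: ``"offer"``, ``"zero"`` (flat bound at 0; quits then require
  ``W < 0`` and are vanishingly rare), or ``"offer_at_dt_end"`` (the bound
  sits at the offer until an imposed decision time ends, then descends —
  "reset" model 1);
* ``upper_bound="non_increasing"`` forces ``W(t) <= W(t-1)``, removing the
  upward drift of the unbounded walk (the other sunk-cost mechanism);
* ``decision_time_s > 0`` forbids quitting for the first DT seconds and
  resets ``W`` to ``W0`` when the decision time ends (drift during the
  decision time is discarded); offers no longer than DT are earned
  automatically.

Time is a discrete 1 s grid.  Quit checks run at ``t = 1 … offer-1`` only:
at ``t = offer`` the countdown has ended and the reward is delivered, and in
the original variant the bound is 0 there anyway.  Quitting uses the strict
inequality ``W(t) < T_WZ(t)``; acceptance uses the weak ``W0 >= offer``.

Reproducibility: a root seed spawns three named child streams (offers,
initial willingness, drift noise).  The drift-noise matrix is drawn in
row-major trial order, so enlarging ``n_trials`` extends the trial table
without reshuffling earlier trials, and the chunked executor draws the same
sequence regardless of chunk size.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .trials import SessionSet, config_hash

__all__ = [
    "SimConfig",
    "SimTrialOutcome",
    "quit_threshold_at",
    "simulate_trial",
    "run_trials",
    "run_experiment",
]

ACCEPT_POLICIES = ("threshold", "accept_all")
TWZ_INITS = ("offer", "zero", "offer_at_dt_end")
UPPER_BOUNDS = ("none", "non_increasing")


@dataclass(frozen=True)
class SimConfig:
    """All agent parameters and variant switches.

    Parameters
    ----------
    w_threshold : mean of the initial willingness-to-wait, seconds (W_T).
    sigma_w : s.d. of the initial willingness draw, seconds.
    sigma_n : per-second drift s.d. of the willingness, seconds.
    accept_policy : "threshold" (accept iff W0 >= offer) or "accept_all".
    twz_init, twz_slope : quit-threshold shape, see module docstring.
    upper_bound : "none" or "non_increasing" (W may never rise).
    decision_time_s : imposed no-quit interval at wait-zone entry, seconds.
    n_trials : number of independent trials.
    offer_support : inclusive integer range of offered delays.
    seed : root seed for all randomness.
    """

    w_threshold: float = 18.0
    sigma_w: float = 5.0
    sigma_n: float = 3.0
    accept_policy: str = "threshold"
    twz_init: str = "offer"
    twz_slope: float = -1.0
    upper_bound: str = "none"
    decision_time_s: int = 0
    n_trials: int = 100_000
    offer_support: tuple[int, int] = (1, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_w < 0 or self.sigma_n < 0:
            raise ValueError("sigma_w and sigma_n must be >= 0")
        if self.decision_time_s < 0:
            raise ValueError("decision_time_s must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.accept_policy not in ACCEPT_POLICIES:
            raise ValueError(f"accept_policy must be one of {ACCEPT_POLICIES}")
        if self.twz_init not in TWZ_INITS:
            raise ValueError(f"twz_init must be one of {TWZ_INITS}")
        if self.upper_bound not in UPPER_BOUNDS:
            raise ValueError(f"upper_bound must be one of {UPPER_BOUNDS}")
        lo, hi = self.offer_support
        if not (1 <= lo <= hi):
            raise ValueError("offer_support must satisfy 1 <= lo <= hi")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimTrialOutcome:
    """One simulated offer encounter.

    ``quit_time_s`` is present only for quits and always satisfies
    ``1 <= quit_time_s <= offer_s - 1``: the quit check never fires at the
    reward instant.
    """

    offer_s: int
    w0: float
    accepted: bool
    quit_time_s: int | None
    earned: bool


def quit_threshold_at(t: int | np.ndarray, offer: int | np.ndarray, config: SimConfig):
    """Quit threshold T_WZ at ``t`` seconds after wait-zone entry.

    ``twz_init="offer"``: offer + slope*t (the original model at slope -1).
    ``twz_init="zero"``: identically 0.
    ``twz_init="offer_at_dt_end"``: the bound holds at the offer through the
    decision time and moves with slope only afterwards,
    offer + slope*max(0, t - decision_time_s).

    The bound is never floored at 0: the anti-sunk variant grows without
    limit and the original variant is negative past the countdown end (where
    it is never evaluated).
    """
    t = np.asarray(t, dtype=float)
    offer = np.asarray(offer, dtype=float)
    if config.twz_init == "offer":
        out = offer + config.twz_slope * t
    elif config.twz_init == "zero":
        out = np.zeros(np.broadcast_shapes(t.shape, offer.shape))
    else:  # offer_at_dt_end
        out = offer + config.twz_slope * np.maximum(0.0, t - config.decision_time_s)
    return out if out.ndim else float(out)


def simulate_trial(offer: int, config: SimConfig, rng: np.random.Generator) -> SimTrialOutcome:
    """Simulate one trial with an explicit per-second loop.

    This is the readable reference path; :func:`run_trials` runs the same
    process vectorised.  The two are checked against each other (and against
    an external step-by-step oracle) in the test suite.
    """
    lo, hi = config.offer_support
    if not (lo <= offer <= hi):
        raise ValueError(f"offer {offer} outside support [{lo},{hi}]")
    w0 = config.w_threshold + rng.normal(0.0, config.sigma_w)
    accepted = config.accept_policy == "accept_all" or w0 >= offer
    if not accepted:
        return SimTrialOutcome(offer, w0, False, None, False)
    dt = config.decision_time_s
    w = w0
    for t in range(1, offer):
        if t <= dt:
            # no quitting during the decision time; W(dt) is reset to W0,
            # so intermediate drift is irrelevant and not drawn
            continue
        step = rng.normal(0.0, config.sigma_n)
        if config.upper_bound == "non_increasing" and step > 0:
            step = 0.0
        w += step
        if w < quit_threshold_at(t, offer, config):
            return SimTrialOutcome(offer, w0, True, t, False)
    return SimTrialOutcome(offer, w0, True, None, True)


def _threshold_matrix(offers: np.ndarray, t: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.twz_init == "offer":
        return offers[:, None] + config.twz_slope * t[None, :]
    if config.twz_init == "zero":
        return np.zeros((offers.size, t.size))
    return offers[:, None] + config.twz_slope * np.maximum(0.0, t - config.decision_time_s)[None, :]


def _simulate_block(
    config: SimConfig, offers: np.ndarray, w0: np.ndarray, noise: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised wait-zone pass; returns (accepted, quit_time, earned).

    ``quit_time`` is 0 where no quit occurred.
    """
    n, t_max = noise.shape
    if config.accept_policy == "accept_all":
        accepted = np.ones(n, dtype=bool)
    else:
        accepted = w0 >= offers
    inc = np.minimum(noise, 0.0) if config.upper_bound == "non_increasing" else noise
    dt = config.decision_time_s
    if dt > 0:
        inc = inc.copy()
        inc[:, : min(dt, t_max)] = 0.0  # W holds at W0 through the decision time
    w = w0[:, None] + np.cumsum(inc, axis=1)  # w[:, k] is W(t=k+1)
    t = np.arange(1, t_max + 1)
    thr = _threshold_matrix(offers.astype(float), t.astype(float), config)
    checkable = (t[None, :] <= (offers - 1)[:, None]) & (t[None, :] > dt)
    hit = checkable & accepted[:, None] & (w < thr)
    any_hit = hit.any(axis=1)
    quit_time = np.where(any_hit, hit.argmax(axis=1) + 1, 0)
    earned = accepted & ~any_hit
    return accepted, quit_time, earned


def run_trials(config: SimConfig, chunk_size: int = 1 << 17) -> pd.DataFrame:
    """Run ``config.n_trials`` independent trials; deterministic given the seed.

    Returns a per-trial table with columns ``offer_s, w0, accepted,
    quit_time_s, earned`` (``quit_time_s`` is NaN where the agent did not
    quit).  Offers are i.i.d. uniform integers on the offer support.
    """
    lo, hi = config.offer_support
    t_max = max(hi - 1, 1)
    ss = np.random.SeedSequence(config.seed)
    g_offer, g_w0, g_noise = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(3))
    parts = []
    done = 0
    while done < config.n_trials:
        m = min(chunk_size, config.n_trials - done)
        offers = g_offer.integers(lo, hi + 1, size=m)
        w0 = config.w_threshold + g_w0.normal(0.0, config.sigma_w, size=m)
        noise = g_noise.normal(0.0, config.sigma_n, size=(m, t_max))
        accepted, quit_time, earned = _simulate_block(config, offers, w0, noise)
        parts.append(
            pd.DataFrame(
                {
                    "offer_s": offers,
                    "w0": w0,
                    "accepted": accepted,
                    "quit_time_s": np.where(quit_time > 0, quit_time, np.nan),
                    "earned": earned,
                }
            )
        )
        done += m
    return pd.concat(parts, ignore_index=True) if len(parts) > 1 else parts[0]


def run_experiment(
    config: SimConfig,
    subject_id: str = "sim",
    session_id: str | None = None,
    site_id: str = "R1",
    chunk_size: int = 1 << 17,
) -> SessionSet:
    """Run a full experiment and map it to the shared trial-log schema.

    Outcomes map as skip (not accepted, 0 s spent), quit (time spent is the
    quit time) or earn (time spent is the full offer); W0 is recorded for
    every trial.
    """
    table = run_trials(config, chunk_size=chunk_size)
    outcome = np.where(
        ~table["accepted"], "skip", np.where(table["earned"], "earn", "quit")
    )
    time_spent = np.where(
        ~table["accepted"],
        0,
        np.where(table["earned"], table["offer_s"], table["quit_time_s"].fillna(0)),
    ).astype(int)
    cfg_dict = config.to_dict()
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "session_id": session_id or f"sim-seed{config.seed}",
            "site_id": site_id,
            "offer_s": table["offer_s"].astype(int),
            "accepted": table["accepted"],
            "time_spent_s": time_spent,
            "outcome": outcome,
            "w0": table["w0"],
        }
    )
    meta = {
        "generator": "sunkddm.simulate.run_experiment",
        "config": cfg_dict,
        "config_hash": config_hash(cfg_dict),
        "seed": config.seed,
        "offer_support": list(config.offer_support),
    }
    return SessionSet(df=df, meta=meta)


def derive_seed(root: int, *indices: int) -> int:
    """Deterministic child seed for (root, indices), kept below 2**31."""
    ss = np.random.SeedSequence([int(root), *map(int, indices)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
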