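"""Behavioral measures of sunk-cost sensitivity from trial logs.

All measures operate on the shared :class:`~sunkddm.trials.SessionSet` schema
regardless of whether the trials came from the drift-diffusion simulator, the
hazard-model synthetic generator, or a real session exported to the schema.

The central object is the p(Earn) matrix: over all accepted trials, for every
(time-spent s, time-remaining r) state passed through, the probability that
the agent went on to wait out the countdown and earn the reward.  A trial
with offer D that earned passes through states (s, D-s) for s = 0..D-1 and
counts as an earn in each; a trial that quit at q passes through
(s, D-s) for s = 0..q-1 and counts as a not-earn in each (the state from
which it quit on the next second is its last contribution).

From the matrix come the three summary scalars used throughout:

* **sunk-cost bubble** — for each s >= 1, sum over r of
  p(s, r) - p(0, r); the total bubble sums these over s.  Positive bubble =
  escalation of commitment with time already invested.
* **baseline slope** — OLS slope of p(0, r) against time remaining r.
* **attrition bias** — OLS slope of the surviving initial
  willingness-to-wait W0 against time spent, pooling one point per second
  each trial remained in the wait zone (simulation-origin data only).

Plus the offer-zone side: a grid maximum-likelihood threshold, a probit fit
of accept vs offer whose tangent at the 50% point estimates the initial
willingness spread sigma_W through a calibrated hyperbolic relation
sigma_W = a + b/tangent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .trials import SessionSet

__all__ = [
    "PEarnMatrix",
    "BubbleResult",
    "MeasureSet",
    "CalibrationFit",
    "ThresholdEstimate",
    "ProbitFit",
    "RankTestResult",
    "LatencyResult",
    "LinQuadFit",
    "InteractionFit",
    "estimate_threshold",
    "offer_value",
    "build_pearn_matrix",
    "sunk_cost_bubble",
    "baseline_slope",
    "attrition_slope",
    "probit_accept_fit",
    "estimate_sigma_w",
    "value_conditioned_deltas",
    "latency_to_accrual",
    "interaction_model",
    "linquad_convexity_fit",
    "compute_measures",
]

PHI0 = float(stats.norm.pdf(0.0))  # peak of the standard normal density


# ---------------------------------------------------------------------------
# p(Earn) matrix


@dataclass
class PEarnMatrix:
    """Counts and probabilities of eventually earning, by (spent, remaining).

    Arrays are indexed ``[s, r]`` with s = 0..max_offer-1 and
    r = 0..max_offer; only cells with s + r equal to some offered delay are
    ever populated.  ``p_earn`` is NaN wherever fewer than ``min_count``
    trials passed through the cell.
    """

    n_pass: np.ndarray
    n_earn: np.ndarray
    min_count: int = 1

    @property
    def p_earn(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.n_earn / np.where(self.n_pass > 0, self.n_pass, np.nan)
        p[self.n_pass < self.min_count] = np.nan
        return p

    def to_long(self) -> pd.DataFrame:
        """Long-format table (spent, remaining, n_pass, n_earn, p_earn)."""
        s_idx, r_idx = np.nonzero(self.n_pass)
        p = self.p_earn
        return pd.DataFrame(
            {
                "spent_s": s_idx,
                "remaining_s": r_idx,
                "n_pass": self.n_pass[s_idx, r_idx],
                "n_earn": self.n_earn[s_idx, r_idx],
                "p_earn": p[s_idx, r_idx],
            }
        )


def build_pearn_matrix(trials: SessionSet, min_count: int = 1) -> PEarnMatrix:
    """Accumulate pass/earn counts over every (spent, remaining) state.

    ``min_count`` guards small sessions: cells visited fewer times are left
    undefined (NaN probability), never zero-filled.  Simulation-scale data
    can use the default of 1.
    """
    df = trials.df
    acc = df[df["accepted"]]
    if acc.empty:
        raise ValueError("no accepted trials; p(Earn) matrix is empty")
    offers = acc["offer_s"].to_numpy(dtype=np.int64)
    stop = acc["time_spent_s"].to_numpy(dtype=np.int64)  # quit time, or offer if earned
    earned = (acc["outcome"] == "earn").to_numpy()
    _, hi = trials.offer_support
    hi = max(hi, int(offers.max()))

    # each trial contributes states s = 0 .. stop-1 (stop = offer for earns)
    total = int(stop.sum())
    trial_idx = np.repeat(np.arange(offers.size), stop)
    starts = np.concatenate(([0], np.cumsum(stop)[:-1]))
    s = np.arange(total) - starts[trial_idx]
    r = offers[trial_idx] - s
    flat = s * (hi + 1) + r
    size = hi * (hi + 1)
    n_pass = np.bincount(flat, minlength=size).reshape(hi, hi + 1)
    n_earn = np.bincount(flat, weights=earned[trial_idx].astype(float), minlength=size)
    return PEarnMatrix(
        n_pass=n_pass.astype(np.int64),
        n_earn=n_earn.reshape(hi, hi + 1).astype(np.int64),
        min_count=min_count,
    )


@dataclass
class BubbleResult:
    """Sunk-cost bubble: total and its per-time-spent profile B(s)."""

    total: float
    by_spent: np.ndarray  # index s; by_spent[0] == 0 by construction
    n_cells: int


def sunk_cost_bubble(m: PEarnMatrix) -> BubbleResult:
    """Summed increase of p(Earn) relative to the 0 s-invested row.

    B(s) = sum over r, where both p(s, r) and p(0, r) are defined, of
    p(s, r) - p(0, r); the total is the sum of B(s) over s >= 1.  All cells
    defined in both rows enter the sum.
    """
    p = m.p_earn
    base = p[0]
    by_spent = np.zeros(p.shape[0])
    n_cells = 0
    for s in range(1, p.shape[0]):
        both = ~np.isnan(p[s]) & ~np.isnan(base)
        if both.any():
            by_spent[s] = float(np.sum(p[s, both] - base[both]))
            n_cells += int(both.sum())
    if n_cells == 0:
        raise ValueError("no (spent, remaining) cell overlaps the 0 s-invested row")
    return BubbleResult(total=float(by_spent[1:].sum()), by_spent=by_spent, n_cells=n_cells)


def baseline_slope(m: PEarnMatrix) -> float:
    """OLS slope of p(Earn) with 0 s invested against time remaining."""
    base = m.p_earn[0]
    defined = ~np.isnan(base)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined cells at 0 s invested")
    r = np.nonzero(defined)[0].astype(float)
    return float(np.polyfit(r, base[defined], 1)[0])


def attrition_slope(trials: SessionSet) -> float:
    """OLS slope of surviving W0 samples against time spent.

    Each accepted trial contributes its W0 once for every second it was in
    the wait zone (s = 0 .. stop-1), i.e. the actual points of the attrition
    histogram, not the binned histogram.  Computed through exact sufficient
    statistics, so trial order is irrelevant.
    """
    df = trials.df
    if df["w0"].isna().all():
        raise ValueError("attrition slope needs W0 (simulation-origin data)")
    acc = df[df["accepted"] & df["w0"].notna()]
    stop = acc["time_spent_s"].to_numpy(dtype=np.float64)
    w0 = acc["w0"].to_numpy(dtype=np.float64)
    keep = stop > 0
    stop, w0 = stop[keep], w0[keep]
    # per-trial sums over s = 0..stop-1 of 1, s, s^2, and products with w0
    n = stop.sum()
    sum_s = (stop * (stop - 1) / 2).sum()
    sum_s2 = ((stop - 1) * stop * (2 * stop - 1) / 6).sum()
    sum_w = (w0 * stop).sum()
    sum_ws = (w0 * stop * (stop - 1) / 2).sum()
    denom = sum_s2 - sum_s**2 / n
    if denom <= 0:
        return 0.0
    return float((sum_ws - sum_s * sum_w / n) / denom)


# ---------------------------------------------------------------------------
# offer-zone measures


@dataclass(frozen=True)
class ThresholdEstimate:
    """Grid-MLE accept threshold with a degeneracy flag for one-sided data."""

    threshold: float
    degenerate: bool
    loglik: float

    def __float__(self) -> float:
        return self.threshold


def estimate_threshold(
    trials: SessionSet, site: str | None = None, lapse: float = 0.05
) -> ThresholdEstimate:
    """Maximum-likelihood step-function threshold on the integer grid 0..30.

    Offers at or below the candidate threshold T are accepted with
    probability 1-lapse, offers above with probability lapse; T* maximises
    the Bernoulli log likelihood over T in {0, .., max offer}.  Ties are
    broken toward the midpoint of the maximising set.  All-accept or
    all-skip data return the boundary with ``degenerate=True``.
    """
    if not (0 < lapse < 0.5):
        raise ValueError("lapse must be in (0, 0.5)")
    df = trials.df if site is None else trials.df[trials.df["site_id"] == site]
    if df.empty:
        raise ValueError(f"no trials for site {site!r}")
    offers = df["offer_s"].to_numpy(dtype=np.int64)
    acc = df["accepted"].to_numpy(dtype=bool)
    _, hi = trials.offer_support
    grid = np.arange(0, hi + 1)
    below = offers[None, :] <= grid[:, None]  # p(accept) = 1-lapse there
    p = np.where(below, 1.0 - lapse, lapse)
    ll = np.where(acc[None, :], np.log(p), np.log1p(-p)).sum(axis=1)
    best = np.flatnonzero(ll == ll.max())
    t_star = float((best.min() + best.max()) / 2.0)
    degenerate = bool(acc.all() or (~acc).all())
    return ThresholdEstimate(threshold=t_star, degenerate=degenerate, loglik=float(ll.max()))


def offer_value(threshold: float, offer: float) -> float:
    """Economic value of an offer: threshold minus offered (or remaining) delay."""
    return float(threshold) - float(offer)


@dataclass(frozen=True)
class ProbitFit:
    """Two-parameter probit of accept vs offer.

    ``tangent`` is |dP/d offer| at the 50% point; it is ``inf`` (with
    ``separated=True``) when the data are perfectly separable and the slope
    is unbounded.
    """

    midpoint: float
    tangent: float
    slope: float
    separated: bool = False


def probit_accept_fit(trials: SessionSet, site: str | None = None) -> ProbitFit:
    """ML probit of the accept/skip decision on the offered delay."""
    df = trials.df if site is None else trials.df[trials.df["site_id"] == site]
    acc = df["accepted"].to_numpy(dtype=float)
    offers = df["offer_s"].to_numpy(dtype=float)
    if acc.all() or (1 - acc).all():
        return ProbitFit(midpoint=np.nan, tangent=np.inf, slope=np.nan, separated=True)
    # perfect separation check: every accepted offer below every skipped one
    if offers[acc == 1].max() < offers[acc == 0].min():
        return ProbitFit(midpoint=np.nan, tangent=np.inf, slope=np.nan, separated=True)
    exog = sm.add_constant(offers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Probit(acc, exog).fit(disp=0, maxiter=200)
    b0, b1 = res.params
    if b1 == 0:
        return ProbitFit(midpoint=np.nan, tangent=0.0, slope=0.0, separated=False)
    return ProbitFit(
        midpoint=float(-b0 / b1),
        tangent=float(abs(b1) * PHI0),
        slope=float(b1),
        separated=False,
    )


@dataclass(frozen=True)
class CalibrationFit:
    """Hyperbolic calibration sigma_W = a + b / tangent."""

    a: float
    b: float
    adj_r2: float


def estimate_sigma_w(tangent: float, fit: CalibrationFit) -> float:
    """Map a probit tangent to a sigma_W estimate via the calibration."""
    if not tangent > 0:
        raise ValueError("tangent must be positive")
    return fit.a + fit.b / tangent


# ---------------------------------------------------------------------------
# value-conditioned deltas, latency, model fits


@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    n_neg: int
    n_pos: int
    median_neg: float
    median_pos: float


@dataclass
class ValueDeltaResult:
    table: pd.DataFrame  # columns value_remaining, spent_s, remaining_s, delta_p
    test: RankTestResult


def value_conditioned_deltas(m: PEarnMatrix, threshold: float) -> ValueDeltaResult:
    """Change in p(Earn) vs the value left in the countdown.

    For every cell (s >= 1, r) defined in both its own row and the 0 s row,
    value = threshold - r and delta_p = p(s, r) - p(0, r).  Cells with
    negative remaining value (delay still above threshold) are compared with
    positive-value cells by a two-sample Wilcoxon rank-sum (Mann-Whitney)
    test; zero-value cells are excluded from the test.
    """
    p = m.p_earn
    rows = []
    for s in range(1, p.shape[0]):
        both = np.flatnonzero(~np.isnan(p[s]) & ~np.isnan(p[0]))
        for r in both:
            rows.append(
                {
                    "value_remaining": threshold - r,
                    "spent_s": s,
                    "remaining_s": r,
                    "delta_p": p[s, r] - p[0, r],
                }
            )
    table = pd.DataFrame(rows)
    neg = table.loc[table["value_remaining"] < 0, "delta_p"].to_numpy()
    pos = table.loc[table["value_remaining"] > 0, "delta_p"].to_numpy()
    if neg.size == 0 or pos.size == 0:
        raise ValueError("rank test undefined: one value side has no cells")
    stat, pval = stats.mannwhitneyu(neg, pos, alternative="two-sided")
    test = RankTestResult(
        statistic=float(stat),
        pvalue=float(pval),
        n_neg=int(neg.size),
        n_pos=int(pos.size),
        median_neg=float(np.median(neg)),
        median_pos=float(np.median(pos)),
    )
    return ValueDeltaResult(table=table, test=test)


@dataclass(frozen=True)
class LatencyResult:
    """Latency to sunk-cost accrual; > 15 s is flagged as an outlier."""

    latency_s: int | None
    outlier: bool


def latency_to_accrual(
    bubble_by_spent: np.ndarray, kappa_frac: float = 0.10, outlier_cutoff_s: int = 15
) -> LatencyResult:
    """First time-spent at which the bubble begins to grow.

    Detection rule: the smallest s >= 1 whose B(s) exceeds
    ``kappa_frac * max_s B(s)`` with the next bin also above (two-bin
    persistence, to avoid triggering on noise).  Absent when the profile
    never crosses.
    """
    b = np.asarray(bubble_by_spent, dtype=float)
    if b.size < 3:
        return LatencyResult(None, False)
    peak = np.nanmax(b[1:])
    if not peak > 0:
        return LatencyResult(None, False)
    level = kappa_frac * peak
    above = b > level
    for s in range(1, b.size - 1):
        if above[s] and above[s + 1]:
            return LatencyResult(int(s), bool(s > outlier_cutoff_s))
    return LatencyResult(None, False)


@dataclass
class LinQuadFit:
    """Linear vs quadratic fit of sensitivity against decision time."""

    linear_adj_r2: float
    quad_adj_r2: float
    quad_coef: float
    curvature: str  # "convex" | "concave" | "flat"


def linquad_convexity_fit(x, y) -> LinQuadFit:
    """Fit y ~ x and y ~ x + x^2; curvature is the sign of the x^2 term."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("quadratic fit needs >= 4 points")
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
    q = float(quad.params[-1])
    curvature = "flat" if q == 0 else ("convex" if q > 0 else "concave")
    return LinQuadFit(
        linear_adj_r2=float(lin.rsquared_adj),
        quad_adj_r2=float(quad.rsquared_adj),
        quad_coef=q,
        curvature=curvature,
    )


@dataclass
class InteractionFit:
    """OLS of p(Earn) on time remaining, time spent, and their interaction."""

    params: dict
    pvalues: dict
    f_stat: float
    f_pvalue: float
    adj_r2: float
    df_resid: int


def interaction_model(m: PEarnMatrix) -> InteractionFit:
    """Linear model p(Earn) ~ remaining + spent + remaining:spent over all cells."""
    long = m.to_long().dropna(subset=["p_earn"])
    if len(long) < 5:
        raise ValueError("need >= 5 defined cells")
    r = long["remaining_s"].to_numpy(dtype=float)
    s = long["spent_s"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([r, s, r * s]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(long["p_earn"].to_numpy(), X).fit()
    names = ["const", "remaining", "spent", "remaining:spent"]
    return InteractionFit(
        params=dict(zip(names, map(float, res.params))),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        adj_r2=float(res.rsquared_adj),
        df_resid=int(res.df_resid),
    )


# ---------------------------------------------------------------------------
# bundled per-session measures


@dataclass
class MeasureSet:
    """Derived scalars for one session or agent."""

    threshold_s: float | None = None
    bubble_total: float = np.nan
    bubble_by_spent: np.ndarray = field(default_factory=lambda: np.zeros(0))
    baseline_slope: float = np.nan
    attrition_slope: float | None = None
    probit_tangent: float | None = None
    sigma_w_hat: float | None = None
    latency_to_accrual_s: int | None = None


def compute_measures(
    trials: SessionSet,
    min_count: int = 1,
    calibration: CalibrationFit | None = None,
    kappa_frac: float = 0.10,
) -> MeasureSet:
    """All measures computable from one session, in one pass."""
    m = build_pearn_matrix(trials, min_count=min_count)
    bubble = sunk_cost_bubble(m)
    out = MeasureSet(
        bubble_total=bubble.total,
        bubble_by_spent=bubble.by_spent,
        baseline_slope=baseline_slope(m),
    )
    lat = latency_to_accrual(bubble.by_spent, kappa_frac=kappa_frac)
    out.latency_to_accrual_s = lat.latency_s
    if not trials.df["w0"].isna().all():
        out.attrition_slope = attrition_slope(trials)
    has_skips = (~trials.df["accepted"]).any() and trials.df["accepted"].any()
    if has_skips:
        est = estimate_threshold(trials)
        out.threshold_s = est.threshold
        fit = probit_accept_fit(trials)
        if not fit.separated and fit.tangent > 0:
            out.probit_tangent = fit.tangent
            if calibration is not None:
                out.sigma_w_hat = estimate_sigma_w(fit.tangent, calibration)
    return out
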