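"""Simulation campaigns over the drift-diffusion foraging agent.

Four orchestrated experiments:

* :func:`run_parameter_sweep` — a grid over (sigma_W, sigma_N), one or more
  replicate experiments per cell, with the full measure set per run and a
  mesh of per-cell means.
* :func:`sweep_regressions` — the linear models relating the per-cell
  attrition bias, baseline slope and sunk-cost bubble to the two noise
  parameters, and the bubble to the attrition bias (whose null result shows
  that attrition is neither necessary nor sufficient for sunk-cost
  sensitivity in this model).
* :func:`calibrate_sigma_w_relation` — the hyperbolic calibration
  sigma_W = a + b/x between the generating sigma_W and the probit tangent x
  at the 50% accept point, fit over replicated simulations.  The ideal-data
  limit is a = 0, b = phi(0) ~= 0.3989, since the true accept curve is
  Phi((W_T - offer)/sigma_W) with tangent phi(0)/sigma_W.
* :func:`run_reset_experiment` — accept-all agents with an imposed decision
  time DT during which quitting is forbidden; model 1 holds the quit bound
  at the offer until DT ends (sunk costs accrue only after the covert
  decision), model 2 lets the bound descend from wait-zone entry (sunk
  costs include the decision time).  Summed bubble vs DT is convex under
  model 1 and concave under model 2.

Seeds for every run derive deterministically from (root seed, cell index,
replicate), so a sweep is bitwise reproducible and individual cells can be
recomputed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .measures import (
    CalibrationFit,
    LinQuadFit,
    MeasureSet,
    compute_measures,
    linquad_convexity_fit,
    probit_accept_fit,
)
from .simulate import SimConfig, derive_seed, run_experiment

__all__ = [
    "SIGMA_W_GRID",
    "SIGMA_N_GRID",
    "SweepResult",
    "run_parameter_sweep",
    "RegressionSummary",
    "sweep_regressions",
    "CalibrationResult",
    "fit_hyperbolic",
    "calibrate_sigma_w_relation",
    "ResetResult",
    "run_reset_experiment",
    "MeshComparisonResult",
    "mesh_comparison",
]

SIGMA_W_GRID = (0.0, 0.25, 0.5, 1.0, 3.0, 5.0, 8.0, 10.0, 20.0)
SIGMA_N_GRID = (0.0, 2.0, 3.0, 5.0)
CALIBRATION_SIGMA_W = (0.25, 0.5, 1.0, 3.0, 5.0, 8.0, 10.0, 20.0)  # sigma_W = 0 is degenerate


@dataclass
class SweepResult:
    """Per-cell replicate measures plus the mesh of means."""

    grid: list[tuple[float, float]]
    replicates: int
    measures: dict[tuple[float, float], list[MeasureSet]]
    mesh: pd.DataFrame  # one row per cell: sigma_w, sigma_n, mean measures


def _cell_mean(values: list[float | None]) -> float:
    arr = np.array([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    return float(arr.mean()) if arr.size else np.nan


def run_parameter_sweep(
    base: SimConfig,
    grid: list[tuple[float, float]] | None = None,
    replicates: int = 1,
    trials_per_run: int = 100_000,
) -> SweepResult:
    """Run a full experiment for every (sigma_W, sigma_N) cell x replicate."""
    if grid is None:
        grid = [(sw, sn) for sw in SIGMA_W_GRID for sn in SIGMA_N_GRID]
    if not grid:
        raise ValueError("grid must be non-empty")
    measures: dict[tuple[float, float], list[MeasureSet]] = {}
    for ci, (sw, sn) in enumerate(grid):
        cell: list[MeasureSet] = []
        for rep in range(replicates):
            cfg = base.with_(
                sigma_w=sw,
                sigma_n=sn,
                n_trials=trials_per_run,
                seed=derive_seed(base.seed, ci, rep),
            )
            session = run_experiment(cfg)
            cell.append(compute_measures(session))
        measures[(sw, sn)] = cell
    mesh = pd.DataFrame(
        [
            {
                "sigma_w": sw,
                "sigma_n": sn,
                "bubble_total": _cell_mean([m.bubble_total for m in cell]),
                "baseline_slope": _cell_mean([m.baseline_slope for m in cell]),
                "attrition_slope": _cell_mean([m.attrition_slope for m in cell]),
                "probit_tangent": _cell_mean([m.probit_tangent for m in cell]),
                "sigma_w_hat": _cell_mean([m.sigma_w_hat for m in cell]),
            }
            for (sw, sn), cell in measures.items()
        ]
    )
    return SweepResult(grid=list(grid), replicates=replicates, measures=measures, mesh=mesh)


@dataclass
class RegressionSummary:
    """One OLS model over sweep cells with per-predictor partial F tests."""

    response: str
    predictors: list[str]
    coefs: dict
    predictor_f: dict  # F = t^2 for each predictor
    predictor_p: dict
    model_f: float
    model_p: float
    adj_r2: float
    df_resid: int
    n_cells: int


def _regress(df: pd.DataFrame, response: str, predictors: list[str]) -> RegressionSummary:
    sub = df.dropna(subset=[response] + predictors)
    y = sub[response].to_numpy(dtype=float)
    X = sm.add_constant(sub[predictors].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    tvals = res.tvalues[1:]
    return RegressionSummary(
        response=response,
        predictors=list(predictors),
        coefs=dict(zip(["const"] + predictors, map(float, res.params))),
        predictor_f=dict(zip(predictors, (float(t**2) for t in tvals))),
        predictor_p=dict(zip(predictors, map(float, res.pvalues[1:]))),
        model_f=float(res.fvalue),
        model_p=float(res.f_pvalue),
        adj_r2=float(res.rsquared_adj),
        df_resid=int(res.df_resid),
        n_cells=len(sub),
    )


def sweep_regressions(sweep: SweepResult) -> dict[str, RegressionSummary]:
    """The four linear models over per-cell mean measures.

    One point per grid cell (replicate means), which with the full 9 x 4
    grid and two predictors gives 33 residual degrees of freedom.
    """
    mesh = sweep.mesh
    return {
        "attrition~sigma": _regress(mesh, "attrition_slope", ["sigma_w", "sigma_n"]),
        "baseline~sigma": _regress(mesh, "baseline_slope", ["sigma_w", "sigma_n"]),
        "bubble~sigma": _regress(mesh, "bubble_total", ["sigma_w", "sigma_n"]),
        "bubble~attrition": _regress(mesh, "bubble_total", ["attrition_slope"]),
    }


# ---------------------------------------------------------------------------
# sigma_W calibration


@dataclass
class CalibrationResult:
    """Fitted hyperbolic calibration plus the underlying (tangent, sigma_W) points."""

    a: float
    b: float
    adj_r2: float
    points: pd.DataFrame  # columns sigma_w, replicate, tangent
    n_dropped: int

    @property
    def fit(self) -> CalibrationFit:
        return CalibrationFit(a=self.a, b=self.b, adj_r2=self.adj_r2)


def fit_hyperbolic(tangent: np.ndarray, sigma_w: np.ndarray) -> CalibrationFit:
    """Least-squares fit of sigma_W = a + b / tangent (linear in 1/tangent)."""
    x = np.asarray(tangent, dtype=float)
    y = np.asarray(sigma_w, dtype=float)
    res = sm.OLS(y, sm.add_constant(1.0 / x)).fit()
    a, b = res.params
    return CalibrationFit(a=float(a), b=float(b), adj_r2=float(res.rsquared_adj))


def calibrate_sigma_w_relation(
    base: SimConfig,
    sigma_w_values: tuple[float, ...] = CALIBRATION_SIGMA_W,
    replicates: int = 10,
    trials_per_run: int = 100_000,
) -> CalibrationResult:
    """Replicated simulations across a sigma_W grid -> hyperbolic calibration.

    For each sigma_W x replicate, one full threshold-policy experiment is
    run at the base sigma_N, the accept/skip psychometric is probit-fit, and
    the tangent magnitude at the 50% point is recorded.  Perfectly separated
    replicates (possible at vanishing sigma_W) are dropped with a count.
    """
    if any(s <= 0 for s in sigma_w_values):
        raise ValueError("sigma_w_values must be positive (0 gives an infinite tangent)")
    rows = []
    n_dropped = 0
    for si, sw in enumerate(sigma_w_values):
        for rep in range(replicates):
            cfg = base.with_(
                sigma_w=sw,
                accept_policy="threshold",
                n_trials=trials_per_run,
                seed=derive_seed(base.seed, 1000 + si, rep),
            )
            session = run_experiment(cfg)
            fit = probit_accept_fit(session)
            if fit.separated or not np.isfinite(fit.tangent) or fit.tangent <= 0:
                n_dropped += 1
                continue
            rows.append({"sigma_w": sw, "replicate": rep, "tangent": fit.tangent})
    points = pd.DataFrame(rows)
    cal = fit_hyperbolic(points["tangent"].to_numpy(), points["sigma_w"].to_numpy())
    return CalibrationResult(
        a=cal.a, b=cal.b, adj_r2=cal.adj_r2, points=points, n_dropped=n_dropped
    )


# ---------------------------------------------------------------------------
# reset experiment


@dataclass
class ResetResult:
    model: str
    decision_times: list[int]
    bubble_totals: list[float]
    linquad: LinQuadFit


def run_reset_experiment(
    base: SimConfig,
    model: str,
    decision_times: tuple[int, ...] = tuple(range(0, 11)),
    trials_per_dt: int = 100_000,
) -> ResetResult:
    """Total sunk-cost sensitivity as a function of an imposed decision time.

    Agents accept every offer and cannot quit for the first DT seconds, after
    which W is reset to W0.  ``model="model1"`` holds the quit bound at the
    offer until DT ends; ``model="model2"`` lets it descend from entry.
    """
    if model not in ("model1", "model2"):
        raise ValueError("model must be 'model1' or 'model2'")
    twz_init = "offer_at_dt_end" if model == "model1" else "offer"
    bubbles = []
    for di, dt in enumerate(decision_times):
        cfg = base.with_(
            accept_policy="accept_all",
            twz_init=twz_init,
            twz_slope=-1.0,
            decision_time_s=int(dt),
            n_trials=trials_per_dt,
            seed=derive_seed(base.seed, 2000 + (0 if model == "model1" else 100) + di),
        )
        session = run_experiment(cfg)
        ms = compute_measures(session)
        bubbles.append(ms.bubble_total)
    fit = linquad_convexity_fit(np.array(decision_times, float), np.array(bubbles))
    return ResetResult(
        model=model,
        decision_times=[int(d) for d in decision_times],
        bubble_totals=[float(b) for b in bubbles],
        linquad=fit,
    )


# ---------------------------------------------------------------------------
# subject-vs-mesh comparison


@dataclass
class MeshComparisonResult:
    """Signed subject-minus-mesh differences and their signed-rank tests."""

    table: pd.DataFrame  # per subject: matched cell, delta_baseline, delta_bubble
    p_baseline: float
    p_bubble: float
    low_power: bool
    rule: str = (
        "nearest sigma_w_hat first, then Euclidean distance in z-scored "
        "(baseline_slope, bubble_total) space; deltas are subject minus mesh"
    )


def _signed_rank_p(deltas: np.ndarray) -> float:
    nz = deltas[deltas != 0]
    if nz.size == 0:
        return np.nan  # degenerate: all differences exactly zero
    return float(stats.wilcoxon(nz, alternative="two-sided").pvalue)


def mesh_comparison(subjects: pd.DataFrame, sweep: SweepResult) -> MeshComparisonResult:
    """Match each subject to the closest mesh cell and test residual offsets.

    ``subjects`` needs columns ``baseline_slope``, ``bubble_total`` and
    ``sigma_w_hat``.  Candidate cells are those whose generating sigma_W is
    nearest the subject's fitted sigma_W; among candidates the cell
    minimising Euclidean distance on z-scored (baseline slope, bubble) axes
    is chosen.  If model noise explains the data, the signed differences
    should center at zero (one-sample signed-rank test per axis).
    """
    mesh = sweep.mesh.dropna(subset=["baseline_slope", "bubble_total"]).reset_index(drop=True)
    if mesh.empty:
        raise ValueError("mesh has no usable cells")
    b_sd = mesh["baseline_slope"].std(ddof=0) or 1.0
    s_sd = mesh["bubble_total"].std(ddof=0) or 1.0
    rows = []
    for _, subj in subjects.iterrows():
        cand = mesh
        if np.isfinite(subj.get("sigma_w_hat", np.nan)):
            d_sw = (mesh["sigma_w"] - subj["sigma_w_hat"]).abs()
            cand = mesh[d_sw == d_sw.min()]
        dz = ((cand["baseline_slope"] - subj["baseline_slope"]) / b_sd) ** 2 + (
            (cand["bubble_total"] - subj["bubble_total"]) / s_sd
        ) ** 2
        cell = cand.loc[dz.idxmin()]
        rows.append(
            {
                "sigma_w": cell["sigma_w"],
                "sigma_n": cell["sigma_n"],
                "delta_baseline": subj["baseline_slope"] - cell["baseline_slope"],
                "delta_bubble": subj["bubble_total"] - cell["bubble_total"],
            }
        )
    table = pd.DataFrame(rows)
    return MeshComparisonResult(
        table=table,
        p_baseline=_signed_rank_p(table["delta_baseline"].to_numpy()),
        p_bubble=_signed_rank_p(table["delta_bubble"].to_numpy()),
        low_power=len(table) < 6,
    )
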