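"""Behavioral measures: hand-computed values, exhaustive oracles, recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sunkddm import SimConfig, run_experiment
from sunkddm.measures import (
    CalibrationFit,
    PEarnMatrix,
    PHI0,
    attrition_slope,
    baseline_slope,
    build_pearn_matrix,
    estimate_sigma_w,
    estimate_threshold,
    interaction_model,
    latency_to_accrual,
    linquad_convexity_fit,
    offer_value,
    probit_accept_fit,
    sunk_cost_bubble,
    value_conditioned_deltas,
)
from sunkddm.trials import SessionSet, TrialRecord


def _session(triples, w0=None):
    """Build a session from (offer, stop, earned) triples."""
    recs = []
    for i, (offer, stop, earned) in enumerate(triples):
        outcome = "earn" if earned else "quit"
        recs.append(
            TrialRecord("s", "x", "R1", offer, True, stop, outcome, None if w0 is None else w0[i])
        )
    return SessionSet.from_records(recs)


# ---------------------------------------------------------------------------
# threshold MLE and value


def test_threshold_perfectly_separable():
    """Accepting exactly offers <= 12 over the full range recovers 12."""
    recs = [
        TrialRecord("s", "x", "R1", o, o <= 12, o if o <= 12 else 0, "earn" if o <= 12 else "skip")
        for o in range(1, 31)
    ]
    est = estimate_threshold(SessionSet.from_records(recs), lapse=0.05)
    assert est.threshold == 12
    assert not est.degenerate


def test_threshold_recovers_probit_generator():
    """Data from a probit accept rule (W_T=18, sigma_W=5) recover 18 +- 1."""
    rng = np.random.default_rng(21)
    offers = rng.integers(1, 31, 10_000)
    acc = rng.random(10_000) < stats.norm.cdf((18 - offers) / 5)
    recs = [
        TrialRecord("s", "x", "R1", int(o), bool(a), int(o) if a else 0, "earn" if a else "skip")
        for o, a in zip(offers, acc)
    ]
    est = estimate_threshold(SessionSet.from_records(recs))
    assert abs(est.threshold - 18) <= 1


def test_threshold_degenerate_data_hits_boundary():
    recs = [TrialRecord("s", "x", "R1", o, True, o, "earn") for o in range(1, 31)]
    est = estimate_threshold(SessionSet.from_records(recs))
    assert est.threshold == 30
    assert est.degenerate
    assert 0 <= est.threshold <= 30


@pytest.mark.parametrize("threshold, offer, expected", [(18, 10, 8), (18, 20, -2), (7.5, 7.5, 0)])
def test_offer_value(threshold, offer, expected):
    assert offer_value(threshold, offer) == expected


# ---------------------------------------------------------------------------
# p(Earn) matrix


def test_pearn_worked_example_quit():
    """Offer 5, quit at 3: states (0,5),(1,4),(2,3) each pass once, earn never."""
    m = build_pearn_matrix(_session([(5, 3, False)]))
    for s, r in [(0, 5), (1, 4), (2, 3)]:
        assert m.n_pass[s, r] == 1
        assert m.n_earn[s, r] == 0
    assert m.n_pass[3, 2] == 0  # the quit second itself contributes nothing


def test_pearn_worked_example_earn():
    m = build_pearn_matrix(_session([(3, 3, True)]))
    for s, r in [(0, 3), (1, 2), (2, 1)]:
        assert m.n_pass[s, r] == 1
        assert m.p_earn[s, r] == 1.0


def _pearn_oracle(triples, hi=30):
    """Per-trial exhaustive enumeration of pass/earn counts."""
    n_pass = np.zeros((hi, hi + 1), dtype=int)
    n_earn = np.zeros((hi, hi + 1), dtype=int)
    for offer, stop, earned in triples:
        for s in range(stop):
            n_pass[s, offer - s] += 1
            n_earn[s, offer - s] += int(earned)
    return n_pass, n_earn


def test_pearn_matches_exhaustive_oracle(rng):
    offers = rng.integers(1, 31, 500)
    earned = rng.random(500) < 0.6
    stops = np.where(
        earned, offers, np.maximum(1, (rng.random(500) * (offers - 1)).astype(int) + 1)
    )
    stops = np.minimum(stops, np.where(earned, offers, np.maximum(offers - 1, 1)))
    triples = [
        (int(o), int(st), bool(e)) for o, st, e in zip(offers, stops, earned) if e or o >= 2
    ]
    m = build_pearn_matrix(_session(triples))
    n_pass, n_earn = _pearn_oracle(triples)
    np.testing.assert_array_equal(m.n_pass, n_pass)
    np.testing.assert_array_equal(m.n_earn, n_earn)


def test_min_count_masks_sparse_cells():
    m = build_pearn_matrix(_session([(5, 5, True)]), min_count=5)
    assert np.isnan(m.p_earn[0, 5])
    assert m.n_pass[0, 5] == 1


# ---------------------------------------------------------------------------
# bubble, baseline, attrition


def _matrix_from_p(p_rows, counts=1000):
    """PEarnMatrix with exact p values at given (s -> {r: p}) cells."""
    hi = 30
    n_pass = np.zeros((hi, hi + 1), dtype=int)
    n_earn = np.zeros((hi, hi + 1), dtype=int)
    for s, row in p_rows.items():
        for r, p in row.items():
            n_pass[s, r] = counts
            n_earn[s, r] = int(round(p * counts))
    return PEarnMatrix(n_pass=n_pass, n_earn=n_earn)


def test_bubble_null_when_rows_identical():
    m = _matrix_from_p({0: {5: 0.5, 6: 0.7}, 1: {5: 0.5, 6: 0.7}, 2: {5: 0.5, 6: 0.7}})
    res = sunk_cost_bubble(m)
    assert res.total == 0.0
    assert np.all(res.by_spent == 0)


def test_bubble_hand_computation():
    """p(0,.) = (0.5, 0.5), p(1,.) = (0.7, 0.6) -> B(1) = 0.3."""
    m = _matrix_from_p({0: {4: 0.5, 5: 0.5}, 1: {4: 0.7, 5: 0.6}})
    res = sunk_cost_bubble(m)
    assert res.by_spent[1] == pytest.approx(0.3)
    assert res.total == pytest.approx(0.3)


def test_bubble_ignores_cells_without_baseline_overlap():
    m = _matrix_from_p({0: {4: 0.5}, 1: {4: 0.8, 9: 1.0}})  # r=9 has no s=0 partner
    assert sunk_cost_bubble(m).total == pytest.approx(0.3)


def test_bubble_requires_overlap():
    m = _matrix_from_p({0: {4: 0.5}, 1: {9: 1.0}})
    with pytest.raises(ValueError, match="overlap"):
        sunk_cost_bubble(m)


def test_baseline_slope_exact_line():
    """p(0, r) = 1 - 0.02 r exactly -> slope -0.02."""
    m = _matrix_from_p({0: {r: 1 - 0.02 * r for r in range(1, 26)}}, counts=10_000)
    assert baseline_slope(m) == pytest.approx(-0.02, abs=1e-6)


def test_baseline_slope_constant_is_zero():
    m = _matrix_from_p({0: {r: 0.4 for r in range(1, 20)}})
    assert baseline_slope(m) == pytest.approx(0.0, abs=1e-12)


def test_attrition_all_w0_equal_is_zero():
    triples = [(10, 10, True), (20, 20, True), (15, 7, False)]
    s = _session(triples, w0=[25.0, 25.0, 25.0])
    assert attrition_slope(s) == pytest.approx(0.0, abs=1e-12)


def test_attrition_matches_pooled_scatter_oracle(rng):
    """Sufficient-statistic slope equals an explicit pooled-point polyfit."""
    n = 300
    offers = rng.integers(2, 31, n)
    stops = rng.integers(1, offers)
    w0 = rng.normal(18, 5, n)
    triples = [(int(o), int(st), False) for o, st in zip(offers, stops)]
    sess = _session(triples, w0=list(w0))
    xs, ys = [], []
    for (o, st, _), w in zip(triples, w0):
        xs.extend(range(st))
        ys.extend([w] * st)
    expected = np.polyfit(xs, ys, 1)[0]
    assert attrition_slope(sess) == pytest.approx(expected, rel=1e-9)


def test_attrition_requires_w0(tiny_session):
    df = tiny_session.df.copy()
    df["w0"] = np.nan
    with pytest.raises(ValueError, match="W0"):
        attrition_slope(SessionSet(df=df))


def test_attrition_zero_without_any_selection():
    """Accept-all with a flat zero bound and no drift: nobody skips and nobody
    quits, so survival is independent of W0 and the slope vanishes."""
    cfg = SimConfig(
        accept_policy="accept_all", twz_init="zero", twz_slope=0.0, sigma_n=0.0,
        n_trials=50_000, seed=31,
    )
    slope = attrition_slope(run_experiment(cfg))
    assert slope == pytest.approx(0.0, abs=0.01)


def test_attrition_accept_all_retains_selection_through_quits():
    """Even with sigma_N = 0, accept-all agents quit once the descending bound
    crosses W0, so low-W0 agents exit early and the slope stays positive."""
    cfg = SimConfig(accept_policy="accept_all", sigma_n=0.0, n_trials=50_000, seed=31)
    assert attrition_slope(run_experiment(cfg)) > 0.1


def test_attrition_positive_under_baseline_threshold_policy(baseline_session):
    assert attrition_slope(baseline_session) > 0.05


# ---------------------------------------------------------------------------
# probit fit and sigma_W


def test_probit_tangent_closed_form(baseline_session):
    """Data generated with sigma_W = 5 give tangent ~ phi(0)/5 ~ 0.0798."""
    fit = probit_accept_fit(baseline_session)
    assert fit.tangent == pytest.approx(PHI0 / 5, rel=0.05)
    assert fit.midpoint == pytest.approx(18, abs=0.5)


def test_probit_tangent_halves_when_sigma_doubles():
    a = probit_accept_fit(run_experiment(SimConfig(sigma_w=4, n_trials=80_000, seed=32)))
    b = probit_accept_fit(run_experiment(SimConfig(sigma_w=8, n_trials=80_000, seed=33)))
    assert a.tangent / b.tangent == pytest.approx(2.0, rel=0.1)


def test_probit_perfect_separation_flagged():
    recs = [
        TrialRecord("s", "x", "R1", o, o <= 15, o if o <= 15 else 0, "earn" if o <= 15 else "skip")
        for o in range(1, 31)
    ]
    fit = probit_accept_fit(SessionSet.from_records(recs))
    assert fit.separated
    assert fit.tangent == np.inf


def test_estimate_sigma_w_arithmetic():
    assert estimate_sigma_w(0.08, CalibrationFit(-0.13, 0.40, 1.0)) == pytest.approx(4.87)


def test_estimate_sigma_w_ideal_inverse():
    """With the ideal calibration (0, phi(0)), tangent phi(0)/sigma -> sigma."""
    for sigma in (1, 3, 5, 8):
        cal = CalibrationFit(0.0, PHI0, 1.0)
        assert estimate_sigma_w(PHI0 / sigma, cal) == pytest.approx(sigma)


def test_estimate_sigma_w_rejects_nonpositive_tangent():
    with pytest.raises(ValueError):
        estimate_sigma_w(0.0, CalibrationFit(0, PHI0, 1))


# ---------------------------------------------------------------------------
# value-conditioned deltas and rank tests


def test_value_deltas_null_case():
    m = _matrix_from_p(
        {0: {r: 0.5 for r in range(10, 26)}, 1: {r: 0.5 for r in range(10, 26)}}
    )
    res = value_conditioned_deltas(m, threshold=18)
    assert (res.table["delta_p"] == 0).all()
    assert res.test.pvalue > 0.05


def test_value_deltas_rank_test_matches_permutation_oracle():
    """Small two-group comparison agrees with exhaustive permutation of the
    Mann-Whitney U statistic over every group assignment."""
    # tie-free deltas: ~0.2 lift for bad deals (v < 0), ~0 for good deals
    m = _matrix_from_p(
        {
            0: {r: 0.5 for r in (14, 15, 16, 20, 21, 22)},
            1: {
                14: 0.503, 15: 0.509, 16: 0.506,
                20: 0.704, 21: 0.712, 22: 0.698,
            },
        },
        counts=1000,
    )
    res = value_conditioned_deltas(m, threshold=18)
    neg = res.table.loc[res.table.value_remaining < 0, "delta_p"].to_numpy()
    pos = res.table.loc[res.table.value_remaining > 0, "delta_p"].to_numpy()
    pooled = np.concatenate([neg, pos])
    n1 = neg.size

    def u_stat(group):  # U for the chosen "neg" group
        ranks = stats.rankdata(pooled)
        return ranks[list(group)].sum() - n1 * (n1 + 1) / 2

    observed = u_stat(range(n1))
    null = np.array([u_stat(c) for c in itertools.combinations(range(pooled.size), n1)])
    p_exact = min(
        1.0,
        2 * min((null <= observed + 1e-12).mean(), (null >= observed - 1e-12).mean()),
    )
    assert res.test.pvalue == pytest.approx(p_exact, abs=1e-9)
    assert res.test.median_neg > res.test.median_pos


def test_value_deltas_requires_both_sides():
    m = _matrix_from_p({0: {20: 0.5, 21: 0.5}, 1: {20: 0.6, 21: 0.6}})
    with pytest.raises(ValueError):
        value_conditioned_deltas(m, threshold=18)  # values all > 0? no: 18-20 < 0
        # threshold far above every r puts all cells on one side
    with pytest.raises(ValueError):
        value_conditioned_deltas(m, threshold=50)


# ---------------------------------------------------------------------------
# latency to accrual


def test_latency_immediate_growth():
    b = np.array([0.0, 2.0, 2.5, 3.0, 3.0])
    res = latency_to_accrual(b)
    assert res.latency_s == 1
    assert not res.outlier


def test_latency_detects_delayed_accrual():
    b = np.zeros(20)
    b[6:] = np.linspace(1, 4, 14)
    assert latency_to_accrual(b).latency_s == 6


def test_latency_requires_persistence():
    b = np.zeros(20)
    b[3] = 5.0  # single-bin spike is not accrual
    b[10:] = 4.0
    assert latency_to_accrual(b).latency_s == 10


def test_latency_outlier_flag_past_15s():
    b = np.zeros(40)
    b[29:] = 3.0
    res = latency_to_accrual(b)
    assert res.latency_s == 29
    assert res.outlier


def test_latency_absent_when_never_crossed():
    assert latency_to_accrual(np.zeros(10)).latency_s is None


# ---------------------------------------------------------------------------
# interaction model and linear/quadratic fits


def test_interaction_model_exact_planar_surface():
    """p = 0.2 + 0.01 r + 0.02 s exactly -> zero interaction, R^2 = 1."""
    cells = {}
    for s in range(0, 8):
        cells[s] = {r: 0.2 + 0.01 * r + 0.02 * s for r in range(1, 15)}
    m = _matrix_from_p(cells, counts=100_000)
    fit = interaction_model(m)
    assert fit.params["remaining:spent"] == pytest.approx(0.0, abs=1e-6)
    assert fit.params["remaining"] == pytest.approx(0.01, abs=1e-4)
    assert fit.params["spent"] == pytest.approx(0.02, abs=1e-4)
    assert fit.adj_r2 > 0.999


def test_interaction_model_constant_surface():
    m = _matrix_from_p({s: {r: 0.4 for r in range(1, 10)} for s in range(4)})
    fit = interaction_model(m)
    for k in ("remaining", "spent", "remaining:spent"):
        assert fit.params[k] == pytest.approx(0.0, abs=1e-9)


def test_interaction_model_matches_normal_equations(rng):
    """Coefficients equal the brute-force normal-equations solution."""
    cells = {s: {r: float(rng.random()) for r in range(5, 10)} for s in range(4)}
    m = _matrix_from_p(cells, counts=10_000_000)
    fit = interaction_model(m)
    rows = [(r, s, p) for s, row in cells.items() for r, p in row.items()]
    X = np.array([[1, r, s, r * s] for r, s, _ in rows], dtype=float)
    y = np.round(np.array([p for _, _, p in rows]) * 10_000_000) / 10_000_000
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert fit.params["const"] == pytest.approx(beta[0], abs=1e-8)
    assert fit.params["remaining:spent"] == pytest.approx(beta[3], abs=1e-8)


def test_linquad_pure_quadratic():
    x = np.arange(-2, 3, dtype=float)
    fit = linquad_convexity_fit(x, x**2)
    assert fit.quad_adj_r2 == pytest.approx(1.0)
    assert fit.curvature == "convex"


def test_linquad_exact_line_has_zero_curvature():
    x = np.arange(8, dtype=float)
    fit = linquad_convexity_fit(x, 3 - 2 * x)
    assert fit.quad_coef == pytest.approx(0.0, abs=1e-10)
    assert fit.linear_adj_r2 == pytest.approx(1.0)


def test_linquad_refuses_short_input():
    with pytest.raises(ValueError):
        linquad_convexity_fit([0, 1, 2], [0, 1, 4])
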