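"""ROR/PRR/BCPNN/MGPS against independent oracles and known patterns."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate, special

import pvsignals.signal_stats as ss
from pvsignals.contingency import ContingencyTable, Level, build_table
from pvsignals.signal_stats import (BcpnnPriors, DEFAULT_MGPS_START, MgpsPriors,
                                    SignalResult, bcpnn_ic, bcpnn_ic_mc,
                                    classify_signal, ebgm, ebgm_arrays,
                                    fit_mgps_priors, fit_mgps_priors_counts,
                                    prr_with_chi2, ror_with_ci)

from conftest import make_report


def T(a, b, c, d):
    return ContingencyTable("x", Level.PT, a, b, c, d)


# ---------------------------------------------------------------------------
# ROR / PRR closed forms


def test_ror_example():
    ror, lo, hi = ror_with_ci(T(10, 90, 100, 9900))
    assert ror == pytest.approx(11.00, abs=0.005)
    assert lo == pytest.approx(5.56, abs=0.01)
    assert hi == pytest.approx(21.77, abs=0.01)


def test_ror_symmetry_and_zero_cell():
    ror, lo, hi = ror_with_ci(T(5, 5, 5, 5))
    assert ror == 1.0 and lo < 1 < hi

    _, _, _, corrected = ss.ror_arrays(2, 8, 0, 90)
    assert bool(corrected)
    # corrected estimate is the Haldane-Anscombe value
    ror_c, _, _, _ = ss.ror_arrays(2, 8, 0, 90)
    assert float(ror_c) == pytest.approx((2.5 * 90.5) / (8.5 * 0.5))

    with pytest.raises(ValueError):
        ror_with_ci(T(0, 0, 5, 5))


def test_prr_examples():
    prr, chi2 = prr_with_chi2(T(10, 90, 100, 9900))
    assert prr == pytest.approx(10.0)
    assert chi2 == pytest.approx(66.33, abs=0.01)

    prr_eq, _ = prr_with_chi2(T(5, 45, 10, 90))  # equal proportions
    assert prr_eq == pytest.approx(1.0)

    _, chi2_floor = prr_with_chi2(T(1, 1, 1, 1))  # |ad-bc| <= N/2 floors to 0
    assert chi2_floor == 0.0

    prr_inf, _ = prr_with_chi2(T(3, 7, 0, 100))
    assert prr_inf == math.inf


def brute_force_counts(target, background, event):
    a = sum(1 for r in target if event in r.events)
    b = sum(1 for r in target if event not in r.events)
    c = sum(1 for r in background if event in r.events)
    d = sum(1 for r in background if event not in r.events)
    return a, b, c, d


def brute_force_stats(a, b, c, d):
    """Textbook formulas written independently of the array kernels."""
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    prr = (a / (a + b)) / (c / (c + d))
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = max(num / den, 0.0) if abs(a * d - b * c) > n / 2 else 0.0
    return ror, math.exp(math.log(ror) - 1.96 * se), prr, chi2


def test_oracle_equivalence_on_small_report_fixture():
    """Count loops over <=20 reports reproduce the pipeline statistics."""
    target = [make_report(str(i), f"C{i}",
                          events=("diarrhoea",) if i < 4 else ("headache",))
              for i in range(6)]
    background = [make_report(str(50 + i), f"B{i}", drug="OTHER",
                              events=("diarrhoea",) if i < 2 else ("nausea",))
                  for i in range(14)]
    table = build_table(target, background, "diarrhoea")
    assert (table.a, table.b, table.c, table.d) == \
        brute_force_counts(target, background, "diarrhoea")
    ror, lo, hi = ror_with_ci(table)
    prr, chi2 = prr_with_chi2(table)
    b_ror, b_lo, b_prr, b_chi2 = brute_force_stats(table.a, table.b, table.c, table.d)
    assert ror == pytest.approx(b_ror)
    assert lo == pytest.approx(b_lo)
    assert prr == pytest.approx(b_prr)
    assert chi2 == pytest.approx(b_chi2)


# ---------------------------------------------------------------------------
# BCPNN


def test_bcpnn_example_value():
    ic, ic025 = bcpnn_ic(T(10, 90, 100, 9900))
    assert ic == pytest.approx(2.38, abs=0.005)
    assert ic025 < ic


def test_bcpnn_zero_cooccurrence_negative():
    ic, _ = bcpnn_ic(T(0, 100, 100, 9800))
    assert ic < 0


def test_bcpnn_independence_limit():
    # a = (a+b)(a+c)/N exactly at N=1e6
    n = 1_000_000
    a = 100
    row = 10_000
    col = 10_000  # a = row*col/N = 100
    ic, _ = bcpnn_ic(T(a, row - a, col - a, n - row - col + a))
    assert abs(ic) < 0.05


def test_bcpnn_monte_carlo_agrees_with_closed_form():
    table = T(25, 475, 300, 9200)
    ic, _ = bcpnn_ic(table)
    ic_mc, _ = bcpnn_ic_mc(table, n_draws=400_000, seed=0)
    # the closed form approximates the simulated posterior mean
    assert ic_mc == pytest.approx(ic, abs=0.05)


# ---------------------------------------------------------------------------
# MGPS


def _tables_from_a_e(a_vals, e_vals, n=200_000):
    tables = []
    for a, e in zip(a_vals, e_vals):
        row = int(round(math.sqrt(e * n)))
        col = max(int(round(e * n / row)), int(a))
        row = max(row, int(a))
        tables.append(T(int(a), row - int(a), col - int(a), n - row - col + int(a)))
    return tables


def test_mgps_requires_enough_tables():
    with pytest.raises(ValueError, match=">= 50"):
        fit_mgps_priors(_tables_from_a_e([5] * 10, [5.0] * 10))


def test_mgps_null_prior_concentrates_near_one():
    """lambda == 1 for every pair: every posterior EBGM must stay in [0.5, 2]."""
    rng = np.random.default_rng(42)
    e = rng.uniform(0.5, 50, size=500)
    a = rng.poisson(e)
    priors = fit_mgps_priors_counts(a, e, seed=0)
    g, _ = ebgm_arrays(a, np.maximum(e, 1e-12), priors)
    assert g.min() > 0.5 and g.max() < 2.0


def test_mgps_mixture_recovery():
    """Two-gamma truth (p=0.1, means 1 and 10) recovered within 25%."""
    rng = np.random.default_rng(7)
    n_pairs = 2000
    is_signal = rng.random(n_pairs) < 0.1
    lam = np.where(is_signal, rng.gamma(4.0, 10 / 4.0, n_pairs),
                   rng.gamma(4.0, 1 / 4.0, n_pairs))
    e = rng.uniform(1, 30, n_pairs)
    a = rng.poisson(lam * e)
    priors = fit_mgps_priors_counts(a, e, seed=0)
    means = sorted([priors.shape1 / priors.rate1, priors.shape2 / priors.rate2])
    assert means[0] == pytest.approx(1.0, rel=0.25)
    assert means[1] == pytest.approx(10.0, rel=0.25)


def ebgm_numerical_oracle(a, e, priors):
    """Numerical integration of the posterior density (independent route)."""
    def log_post_unnorm(lam):
        loglik = a * np.log(lam * e) - lam * e
        p1 = priors.mix_p * lam ** (priors.shape1 - 1) * np.exp(-priors.rate1 * lam) \
            * priors.rate1 ** priors.shape1 / special.gamma(priors.shape1)
        p2 = (1 - priors.mix_p) * lam ** (priors.shape2 - 1) \
            * np.exp(-priors.rate2 * lam) \
            * priors.rate2 ** priors.shape2 / special.gamma(priors.shape2)
        return loglik + np.log(p1 + p2)

    grid = np.linspace(1e-6, 60, 400_001)
    logw = log_post_unnorm(grid)
    w = np.exp(logw - logw.max())
    z = integrate.trapezoid(w, grid)
    mean_log2 = integrate.trapezoid(w * np.log2(grid), grid) / z
    cdf = integrate.cumulative_trapezoid(w, grid, initial=0) / z
    q05 = grid[np.searchsorted(cdf, 0.05)]
    return 2.0 ** mean_log2, q05


@pytest.mark.parametrize("a,e", [(100, 10.0), (3, 3.0), (12, 2.0), (1, 8.0)])
def test_ebgm_matches_numerical_integration(a, e):
    priors = MgpsPriors(shape1=1.2, rate1=1.1, shape2=2.0, rate2=0.5, mix_p=0.8)
    g, g05 = ebgm_arrays(np.array([float(a)]), np.array([e]), priors)
    oracle_g, oracle_q05 = ebgm_numerical_oracle(a, e, priors)
    assert g.item() == pytest.approx(oracle_g, abs=1e-3)
    assert g05.item() == pytest.approx(oracle_q05, abs=2e-3)


def test_ebgm_shrinks_and_calibrates():
    g, g05 = ebgm_arrays(np.array([100.0]), np.array([10.0]), DEFAULT_MGPS_START)
    assert 8 < g.item() < 10  # pulled below the raw ratio 10
    assert g05.item() < g.item()

    informative = MgpsPriors(shape1=50.0, rate1=50.0, shape2=50.0, rate2=50.0,
                             mix_p=0.5)
    g_eq, _ = ebgm_arrays(np.array([20.0]), np.array([20.0]), informative)
    assert g_eq.item() == pytest.approx(1.0, abs=0.1)


def test_ebgm05_below_ebgm_across_grid():
    rng = np.random.default_rng(0)
    a = rng.integers(1, 200, 100).astype(float)
    e = rng.uniform(0.1, 100, 100)
    g, g05 = ebgm_arrays(a, e, DEFAULT_MGPS_START)
    assert np.all(g05 < g)


# ---------------------------------------------------------------------------
# monotonicity and classification


def test_statistics_monotone_in_a_with_margins_fixed():
    n, row, col = 10_000, 300, 200
    stats = []
    for a in [5, 10, 20, 40]:
        t = T(a, row - a, col - a, n - row - col + a)
        ror, _, _ = ror_with_ci(t)
        prr, _ = prr_with_chi2(t)
        ic, _ = bcpnn_ic(t)
        g, _ = ebgm(t, DEFAULT_MGPS_START)
        stats.append((ror, prr, ic, g))
    for i in range(3):
        assert all(x < y for x, y in zip(stats[i], stats[i + 1]))


def _result(n, ror_lo, prr, chi2, ebgm05, ic025):
    return SignalResult(event_name="x", level="soc", n=n, ror=ror_lo + 0.1,
                        ror_lo=ror_lo, ror_hi=ror_lo + 1, ror_corrected=False,
                        prr=prr, chi2=chi2, ic=ic025 + 0.1, ic025=ic025,
                        ebgm=ebgm05 + 0.1, ebgm05=ebgm05)


def test_classification_reproduces_printed_soc_patterns():
    # psychiatric-disorders style row: ROR, PRR, BCPNN positive, MGPS not
    psych = classify_signal(_result(983, 2.02, 2.03, 541.95, 1.92, 0.92))
    assert psych.flags == {"ror": True, "prr": True, "bcpnn": True, "mgps": False}
    assert psych.positive_any and not psych.positive_all

    # respiratory style row meets all four simultaneously
    resp = classify_signal(_result(898, 2.19, 2.2, 617.68, 2.08, 1.04))
    assert resp.positive_all

    # two cases with an enormous ROR still fail the case-minimum rule
    tiny = classify_signal(_result(2, 50.0, 100.0, 500.0, 30.0, 3.0))
    assert not tiny.flags["ror"] and not tiny.flags["prr"] and not tiny.flags["mgps"]
    assert tiny.flags["bcpnn"]  # IC criterion carries no case minimum
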