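"""Disproportionality statistics: ROR, PRR+chi2, BCPNN IC, MGPS EBGM.

For a 2x2 table (a, b, c, d) with N = a+b+c+d and independence-expected
count E = (a+b)(a+c)/N:

* ROR = (a*d)/(b*c), Woolf CI exp(ln ROR +/- z*sqrt(1/a+1/b+1/c+1/d));
  a zero cell triggers the Haldane-Anscombe +0.5 correction (flagged).
* PRR = [a/(a+b)] / [c/(c+d)], paired with the Yates-corrected chi-square
  N(|ad-bc|-N/2)^2 / [(a+b)(c+d)(a+c)(b+d)], floored at 0.
* The BCPNN information component IC = log2 of the shrunk observed-to-
  expected ratio, with a closed-form posterior expectation and variance;
  IC025 = E(IC) - 2*sqrt(V(IC)) is the conventional lower bound.
* MGPS models the relative reporting rate lambda of each pair as a draw
  from a two-component gamma mixture, a ~ Poisson(lambda*E); the mixture
  hyperparameters are fitted by maximum marginal (negative-binomial)
  likelihood over the database's full pair universe.  EBGM is the
  geometric mean of the posterior, 2^{E[log2 lambda | a]}, and EBGM05 its
  5th percentile.

A pair is flagged positive per algorithm using the conventional criteria
(ror: a>=3 and CI lower >1; prr: a>=3, PRR>=2, chi2>=4; bcpnn: IC025>0;
mgps: a>=3 and EBGM05>2); a pair positive on at least one algorithm is a
signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable

log = logging.getLogger(__name__)

LN2 = np.log(2.0)

# ---------------------------------------------------------------------------
# Priors and criteria


@dataclass(frozen=True)
class BcpnnPriors:
    """Pseudo-counts of the standard closed-form BCPNN.

    alpha1/beta1 are the row/column margin priors, alpha/beta the total
    pseudo-counts, gamma11 the joint cell prior; the defaults (1,1,2,2,1)
    make the prior IC centre on 0 for an empty database.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ValueError("BCPNN pseudo-counts must be positive")


@dataclass(frozen=True)
class MgpsPriors:
    """Two-component gamma mixture prior on the relative reporting rate.

    lambda ~ mix_p * Gamma(shape1, rate1) + (1-mix_p) * Gamma(shape2, rate2).
    """

    shape1: float
    rate1: float
    shape2: float
    rate2: float
    mix_p: float

    def __post_init__(self) -> None:
        if min(self.shape1, self.rate1, self.shape2, self.rate2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0.0 <= self.mix_p <= 1.0:
            raise ValueError("mix_p must lie in [0, 1]")


#: DuMouchel's classic starting prior, also the default optimizer start.
DEFAULT_MGPS_START = MgpsPriors(shape1=0.2, rate1=0.1, shape2=2.0, rate2=4.0, mix_p=1 / 3)


@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm positivity thresholds."""

    min_count: int = 3
    ror_lo_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


DEFAULT_CRITERIA = SignalCriteria()


@dataclass
class SignalResult:
    """The four statistics and positivity flags for one drug-event pair."""

    event_name: str
    level: str
    n: int
    ror: float
    ror_lo: float
    ror_hi: float
    ror_corrected: bool
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float | None = None
    ebgm05: float | None = None
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def positive_any(self) -> bool:
        return any(self.flags.values())

    @property
    def positive_all(self) -> bool:
        return bool(self.flags) and all(self.flags.values())


# ---------------------------------------------------------------------------
# Array kernels (used by both the per-table API and the batch pipeline)


def ror_arrays(a, b, c, d, z: float = 1.96):
    """Vectorized ROR with Woolf CI; returns (ror, lo, hi, corrected)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    corrected = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    aa, bb, cc, dd = (np.where(corrected, x + 0.5, x) for x in (a, b, c, d))
    ror = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    with np.errstate(invalid="ignore"):
        lo = ror * np.exp(-z * se)
        hi = ror * np.exp(z * se)
    return ror, lo, hi, corrected


def prr_arrays(a, b, c, d):
    """Vectorized PRR and Yates-corrected chi-square (floored at 0).

    c == 0 yields PRR = +inf (reported, not corrected).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a / (a + b)) / np.where(c + d > 0, c / (c + d), np.nan)
        prr = np.where((c == 0) & (a > 0), np.inf, prr)
        diff = np.abs(a * d - b * c) - n / 2
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where((diff > 0) & (denom > 0), n * diff**2 / denom, 0.0)
    return prr, chi2


def bcpnn_arrays(a, b, c, d, priors: BcpnnPriors = BcpnnPriors()):
    """Vectorized closed-form IC expectation and IC025 = E - 2*sqrt(V)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    p = priors
    row = a + b + p.alpha1          # target-drug margin + prior
    col = a + c + p.beta1           # event margin + prior
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (row * col)
    e_ic = np.log2((a + p.gamma11) * (n + p.alpha) * (n + p.beta)
                   / ((n + gamma) * row * col))
    v_ic = ((n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
            + (n - a - b + p.alpha - p.alpha1) / (row * (1 + n + p.alpha))
            + (n - a - c + p.beta - p.beta1) / (col * (1 + n + p.beta))) / LN2**2
    return e_ic, e_ic - 2.0 * np.sqrt(v_ic)


def _nb_logpmf(a, shape, rate, e):
    """log P(a) for the gamma-Poisson marginal (negative binomial)."""
    return (special.gammaln(a + shape) - special.gammaln(shape)
            - special.gammaln(a + 1)
            + shape * np.log(rate / (rate + e))
            + a * np.log(e / (rate + e)))


def mgps_marginal_loglik(priors: MgpsPriors, a, e) -> float:
    """Sum over pairs of the log marginal likelihood of the mixture."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    l1 = _nb_logpmf(a, priors.shape1, priors.rate1, e)
    l2 = _nb_logpmf(a, priors.shape2, priors.rate2, e)
    w = np.clip(priors.mix_p, 1e-12, 1 - 1e-12)
    return float(np.logaddexp(np.log(w) + l1, np.log1p(-w) + l2).sum())


def ebgm_arrays(a, e, priors: MgpsPriors):
    """Vectorized posterior EBGM and EBGM05 under the fitted mixture prior.

    The posterior is again a two-gamma mixture with shapes shifted by the
    observed count and rates by the expected count; component weights are
    proportional to prior weight times marginal likelihood.  EBGM05 is
    found by bisection on the mixture CDF (tolerance 1e-8).
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    s1, r1 = priors.shape1 + a, priors.rate1 + e
    s2, r2 = priors.shape2 + a, priors.rate2 + e
    w = np.clip(priors.mix_p, 1e-12, 1 - 1e-12)
    lw1 = np.log(w) + _nb_logpmf(a, priors.shape1, priors.rate1, e)
    lw2 = np.log1p(-w) + _nb_logpmf(a, priors.shape2, priors.rate2, e)
    norm = np.logaddexp(lw1, lw2)
    q1 = np.exp(lw1 - norm)
    q2 = 1.0 - q1
    # geometric mean: E[ln lambda] of a Gamma(s, r) is psi(s) - ln r
    e_ln = q1 * (special.digamma(s1) - np.log(r1)) + q2 * (special.digamma(s2) - np.log(r2))
    ebgm = np.exp(e_ln)

    # 5th percentile of the posterior mixture by bisection
    p1 = stats.gamma.ppf(0.05, s1, scale=1 / r1)
    p2 = stats.gamma.ppf(0.05, s2, scale=1 / r2)
    lo = np.minimum(p1, p2)
    hi = np.maximum(p1, p2)

    def cdf(x):
        return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) \
            + q2 * stats.gamma.cdf(x, s2, scale=1 / r2)

    for _ in range(100):
        mid = 0.5 * (lo + hi)
        below = cdf(mid) < 0.05
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
        if np.all(np.abs(cdf(0.5 * (lo + hi)) - 0.05) < 1e-8):
            break
    ebgm05 = 0.5 * (lo + hi)
    return ebgm, ebgm05


def classify_arrays(a, ror_lo, prr, chi2, ic025, ebgm05,
                    criteria: SignalCriteria = DEFAULT_CRITERIA):
    """Vectorized positivity flags; returns dict of boolean arrays."""
    a = np.asarray(a)
    return {
        "ror": (a >= criteria.min_count) & (np.asarray(ror_lo) > criteria.ror_lo_gt),
        "prr": (a >= criteria.min_count) & (np.asarray(prr) >= criteria.prr_ge)
               & (np.asarray(chi2) >= criteria.chi2_ge),
        "bcpnn": np.asarray(ic025) > criteria.ic025_gt,
        "mgps": (a >= criteria.min_count) & (np.asarray(ebgm05) > criteria.ebgm05_gt),
    }


# ---------------------------------------------------------------------------
# Per-table API


def ror_with_ci(table: ContingencyTable, z: float = 1.96) -> tuple[float, float, float]:
    """ROR with Woolf CI; zero cells use the +0.5 correction.

    Raises when the target drug has no reports at all (a = b = 0).
    """
    if table.a == 0 and table.b == 0:
        raise ValueError("undefined ROR: no target-drug reports")
    ror, lo, hi, _ = ror_arrays(table.a, table.b, table.c, table.d, z)
    return float(ror), float(lo), float(hi)


def prr_with_chi2(table: ContingencyTable) -> tuple[float, float]:
    """PRR and Yates chi-square.  c = 0 returns +inf PRR, never raises."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("PRR undefined: empty margin")
    prr, chi2 = prr_arrays(table.a, table.b, table.c, table.d)
    return float(prr), float(chi2)


def bcpnn_ic(table: ContingencyTable,
             priors: BcpnnPriors = BcpnnPriors()) -> tuple[float, float]:
    """Closed-form IC and IC025 for one table."""
    if table.n_total <= 0:
        raise ValueError("empty table")
    ic, ic025 = bcpnn_arrays(table.a, table.b, table.c, table.d, priors)
    return float(ic), float(ic025)


def bcpnn_ic_mc(table: ContingencyTable, priors: BcpnnPriors = BcpnnPriors(),
                n_draws: int = 200_000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo IC posterior (validation only; the closed form is canonical).

    Draws the joint cell probability from its Dirichlet-like posterior
    (p11 ~ Beta(a+gamma11, N-a+gamma-gamma11) given margins drawn from their
    Beta posteriors) and reports the mean and 2.5th percentile of
    log2(p11/(p1.*p.1)).
    """
    rng = np.random.default_rng(seed)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n_total
    p = priors
    row = a + b + p.alpha1
    col = a + c + p.beta1
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (row * col)
    p1 = rng.beta(row, n - a - b + p.alpha - p.alpha1, size=n_draws)
    p2 = rng.beta(col, n - a - c + p.beta - p.beta1, size=n_draws)
    p11 = rng.beta(a + p.gamma11, n - a + gamma - p.gamma11, size=n_draws)
    ic = np.log2(p11 / (p1 * p2))
    return float(ic.mean()), float(np.quantile(ic, 0.025))


def fit_mgps_priors(tables: Sequence[ContingencyTable], seed: int = 0,
                    n_starts: int = 8) -> MgpsPriors:
    """Fit the two-gamma mixture prior by maximum marginal likelihood.

    Requires the full pair universe of the database (>= 50 tables).
    Multi-start bounded quasi-Newton optimization in log/logit-transformed
    parameters; start points are deterministic for a given seed.  The
    component with the smaller prior mean is reported first.
    """
    if len(tables) < 50:
        raise ValueError(f"need >= 50 tables to fit the MGPS prior, got {len(tables)}")
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    return fit_mgps_priors_counts(a, e, seed=seed, n_starts=n_starts)


def fit_mgps_priors_counts(a, e, seed: int = 0, n_starts: int = 8) -> MgpsPriors:
    """Array variant of :func:`fit_mgps_priors` taking observed and expected
    counts directly (used by large simulation studies)."""
    a = np.asarray(a, dtype=float)
    e = np.maximum(np.asarray(e, dtype=float), 1e-12)

    def unpack(theta) -> MgpsPriors:
        s1, r1, s2, r2 = np.exp(np.clip(theta[:4], -20, 20))
        p = 1 / (1 + np.exp(-np.clip(theta[4], -30, 30)))
        return MgpsPriors(s1, r1, s2, r2, float(np.clip(p, 1e-9, 1 - 1e-9)))

    def nll(theta) -> float:
        try:
            return -mgps_marginal_loglik(unpack(theta), a, e)
        except (ValueError, FloatingPointError):
            return np.inf

    rng = np.random.default_rng(seed)
    d0 = DEFAULT_MGPS_START
    starts = [np.array([np.log(d0.shape1), np.log(d0.rate1),
                        np.log(d0.shape2), np.log(d0.rate2), 0.0])]
    for _ in range(n_starts - 1):
        starts.append(rng.normal(scale=1.5, size=5))

    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 500})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("MGPS prior fit failed from all starts")
    pri = unpack(best.x)
    if pri.shape1 / pri.rate1 > pri.shape2 / pri.rate2:
        pri = MgpsPriors(pri.shape2, pri.rate2, pri.shape1, pri.rate1,
                         1.0 - pri.mix_p)
    log.info("MGPS prior: %s (nll=%.2f)", pri, best.fun)
    return pri


def ebgm(table: ContingencyTable, priors: MgpsPriors) -> tuple[float, float]:
    """Posterior EBGM (geometric mean) and EBGM05 for one table."""
    g, g05 = ebgm_arrays(table.a, max(table.expected, 1e-12), priors)
    return float(g), float(g05)


def classify_signal(result: SignalResult,
                    criteria: SignalCriteria = DEFAULT_CRITERIA) -> SignalResult:
    """Set per-algorithm flags on a computed result (in place; returned)."""
    ok_n = result.n >= criteria.min_count
    result.flags = {
        "ror": bool(ok_n and result.ror_lo > criteria.ror_lo_gt),
        "prr": bool(ok_n and result.prr >= criteria.prr_ge
                    and result.chi2 >= criteria.chi2_ge),
        "bcpnn": bool(result.ic025 > criteria.ic025_gt),
        "mgps": bool(ok_n and result.ebgm05 is not None
                     and result.ebgm05 > criteria.ebgm05_gt),
    }
    return result


def compute_signals(
    tables: Sequence[ContingencyTable],
    mgps_priors: MgpsPriors | None = None,
    bcpnn_priors: BcpnnPriors = BcpnnPriors(),
    criteria: SignalCriteria = DEFAULT_CRITERIA,
) -> list[SignalResult]:
    """All four statistics plus flags for a batch of tables.

    When ``mgps_priors`` is None the EBGM columns are left unset and the
    MGPS flag is False (the prior must be fitted on the database-wide pair
    universe, which the caller owns).
    """
    if not tables:
        return []
    a = np.array([t.a for t in tables], dtype=float)
    b = np.array([t.b for t in tables], dtype=float)
    c = np.array([t.c for t in tables], dtype=float)
    d = np.array([t.d for t in tables], dtype=float)
    ror, lo, hi, corr = ror_arrays(a, b, c, d)
    prr, chi2 = prr_arrays(a, b, c, d)
    ic, ic025 = bcpnn_arrays(a, b, c, d, bcpnn_priors)
    if mgps_priors is not None:
        e = np.maximum((a + b) * (a + c) / (a + b + c + d), 1e-12)
        g, g05 = ebgm_arrays(a, e, mgps_priors)
    else:
        g = g05 = np.full(len(tables), np.nan)
    out = []
    for i, t in enumerate(tables):
        r = SignalResult(
            event_name=t.event_name, level=t.level.value, n=int(t.a),
            ror=float(ror[i]), ror_lo=float(lo[i]), ror_hi=float(hi[i]),
            ror_corrected=bool(corr[i]), prr=float(prr[i]), chi2=float(chi2[i]),
            ic=float(ic[i]), ic025=float(ic025[i]),
            ebgm=None if np.isnan(g[i]) else float(g[i]),
            ebgm05=None if np.isnan(g05[i]) else float(g05[i]),
        )
        out.append(classify_signal(r, criteria))
    return out
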