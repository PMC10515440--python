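"""The value-of-information metric ladder.

Every metric compares the expected objective value (total social cost for
the benefit-risk decision maker, total health cost for the target-risk
decision maker) attainable *now* with what could be attained after learning
more:

* EV|CI — expected value given current information: the prior-optimal
  objective value (baseline).
* EVIPI — expected value of immediate perfect information: gain from acting
  with the truth revealed, an upper bound on any test's worth.
* EVIPPI — the same for a parameter subset (e.g. toxicity only), since a
  toxicity test leaves exposure uncertainty untouched.
* EVISI / EVDSI — expected value of immediate / delayed sample information:
  the worth of an actual, imperfect test; the delayed form charges the test
  duration inside the cost model, which is where timeliness enters.
* CoD — cost of delay, EVISI - EVDSI; together with EVDSI it partitions
  EVISI.
* ENBS = EVDSI - cost of testing; ROI = ENBS / cost; the best test maximises
  ROI.

All preposterior integrals reduce to one dimension in the conditional mean
of the location difference mu_exp - mu_tox, whatever scenario is analysed:
if the outer (learnable) uncertainty has spread ``outer_sd`` and the
unresolvable remainder has spread ``residual_sd``, the conditional mean is
normal around the prior difference and conditional risks keep their probit
closed form. The target-risk expectations are then exact bivariate-normal
probabilities; the benefit-risk expectations (a running minimum over the
mitigation grid, continuous but kinked) use Gauss-Hermite quadrature, with
a seeded Monte-Carlo path retained for verification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import multivariate_normal, norm

from .decision import (
    BRDMPolicy,
    TRDMPolicy,
    Verdict,
    _difference_frame,
    _etsc_matrix,
    _preposterior_geometry,
    brdm_optimize,
    decision_probabilities,
    trdm_decide,
)
from .econ import EconTiming, discounted_sum
from .errors import InvalidParameterError
from .risk import MitigationLevel, RiskParams, expected_risk
from .uncertainty import TestSpec, UncertaintyState

__all__ = [
    "DecisionContext",
    "InfoValue",
    "TestMetrics",
    "VOIReport",
    "ev_current_information",
    "ev_perfect_information",
    "ev_partial_perfect_information",
    "ev_sample_information",
    "ev_sample_information_mc",
    "cost_of_delay",
    "cod_perfect_information",
    "cod_partial_perfect_information",
    "enbs_roi",
    "compute_report",
]


@dataclass(frozen=True)
class DecisionContext:
    """A fully specified scenario for one decision maker."""

    params: RiskParams
    prior: UncertaintyState
    econ: EconTiming
    policy: TRDMPolicy | BRDMPolicy
    quadrature_nodes: int = 64

    @property
    def is_trdm(self) -> bool:
        return isinstance(self.policy, TRDMPolicy)


class InfoValue(NamedTuple):
    """Expected objective value given some information, and the gain over EV|CI."""

    ev_given: float
    gain: float


class EnbsRoi(NamedTuple):
    enbs: float
    roi: float


# ---------------------------------------------------------------------------
# core expectations

def _phi2(x: float, y: float, rho: float) -> float:
    """Standard bivariate normal CDF P(X < x, Y < y) with correlation rho."""
    if math.isinf(x) or math.isinf(y):
        if x == -math.inf or y == -math.inf:
            return 0.0
        if x == math.inf:
            return float(norm.cdf(y))
        return float(norm.cdf(x))
    cov = [[1.0, rho], [rho, 1.0]]
    return float(multivariate_normal.cdf([x, y], mean=[0.0, 0.0], cov=cov))


def _expect_probit_above(
    d0: float, outer_sd: float, s_res: float, shift: float, tau: float
) -> float:
    """E[Phi((m + shift)/s_res) * 1{m > tau}] for m ~ N(d0, outer_sd)."""
    if shift == -math.inf:
        return 0.0
    if outer_sd == 0:
        if d0 > tau:
            return float(norm.cdf((d0 + shift) / s_res))
        return 0.0
    denom = math.hypot(outer_sd, s_res)
    rho = outer_sd / denom
    return _phi2((d0 - tau) / outer_sd, (d0 + shift) / denom, rho)


def _trdm_tau(policy: TRDMPolicy, b: float, residual_sd: float) -> float:
    """Regulate threshold on the conditional mean of mu_exp - mu_tox."""
    base = b * norm.ppf(policy.trl)
    if residual_sd == 0:
        return base
    return base - norm.ppf(policy.lower_pct) * residual_sd


def _ev_given(
    ctx: DecisionContext, outer_sd: float, residual_sd: float, delay_years: float
) -> float:
    """Expected objective value after observing the learnable component.

    ``outer_sd`` is the preposterior spread of the conditional mean of the
    location difference; ``residual_sd`` the uncertainty that remains after
    the information arrives. ``outer_sd = 0`` is the current-information
    case; ``residual_sd = 0`` the perfect-information case.
    """
    d0, u_tox, u_exp = _difference_frame(ctx.params, ctx.prior)
    b = ctx.params.combined_sigma
    econ = ctx.econ
    if ctx.is_trdm:
        policy = ctx.policy
        s_res = math.hypot(b, residual_sd)
        d_all = discounted_sum(1, econ)
        d_impl = discounted_sum(econ.first_controlled_year(delay_years), econ)
        tau = _trdm_tau(policy, b, residual_sd)
        alpha = MitigationLevel(policy.action_k).log10_retention
        er_total = float(norm.cdf(d0 / math.hypot(outer_sd, s_res)))
        saved = _expect_probit_above(
            d0, outer_sd, s_res, 0.0, tau
        ) - _expect_probit_above(d0, outer_sd, s_res, alpha, tau)
        return econ.value_rate * (er_total * d_all - saved * d_impl)
    # BRDM: Gauss-Hermite over the conditional mean, grid minimum inside
    grid = np.asarray(ctx.policy.k_grid)
    s_res = math.hypot(b, residual_sd)
    if outer_sd == 0:
        tsc = _etsc_matrix(np.array([d0]), s_res, grid, delay_years, econ)
        return float(tsc.min())
    x, w = hermegauss(ctx.quadrature_nodes)
    w = w / w.sum()
    m = d0 + outer_sd * x
    tsc = _etsc_matrix(m, s_res, grid, delay_years, econ)
    return float(np.sum(w * tsc.min(axis=1)))


def _ev_given_mc(
    ctx: DecisionContext,
    outer_sd: float,
    residual_sd: float,
    delay_years: float,
    n: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo twin of :func:`_ev_given`; returns (estimate, se)."""
    d0, _, _ = _difference_frame(ctx.params, ctx.prior)
    b = ctx.params.combined_sigma
    econ = ctx.econ
    rng = np.random.default_rng(seed)
    m = d0 + outer_sd * rng.standard_normal(n)
    s_res = math.hypot(b, residual_sd)
    if ctx.is_trdm:
        policy = ctx.policy
        d_all = discounted_sum(1, econ)
        d_impl = discounted_sum(econ.first_controlled_year(delay_years), econ)
        tau = _trdm_tau(policy, b, residual_sd)
        alpha = MitigationLevel(policy.action_k).log10_retention
        r = norm.cdf(m / s_res)
        r_act = norm.cdf((m + alpha) / s_res) if alpha > -math.inf else 0.0
        vals = econ.value_rate * (
            r * d_all - np.where(m > tau, (r - r_act) * d_impl, 0.0)
        )
    else:
        grid = np.asarray(ctx.policy.k_grid)
        tsc = _etsc_matrix(m, s_res, grid, delay_years, econ)
        vals = tsc.min(axis=1)
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n))


# ---------------------------------------------------------------------------
# the ladder

def ev_current_information(ctx: DecisionContext) -> float:
    """Baseline objective value using prior information only, $M.

    BRDM: minimised prior expected total social cost. TRDM: expected total
    health cost under the prior verdict (unmitigated when undecided or when
    no action is warranted; mitigated at the action level when the prior
    alone already justifies regulation).
    """
    if ctx.is_trdm:
        verdict = trdm_decide(ctx.params, ctx.prior, ctx.policy)
        econ = ctx.econ
        er = expected_risk(ctx.params, ctx.prior, MitigationLevel(0.0))
        d_all = discounted_sum(1, econ)
        if verdict.verdict is Verdict.REGULATE:
            er_act = expected_risk(
                ctx.params, ctx.prior, MitigationLevel(ctx.policy.action_k)
            )
            d_impl = discounted_sum(econ.first_controlled_year(0.0), econ)
            return econ.value_rate * (er * d_all - (er - er_act) * d_impl)
        return econ.value_rate * er * d_all
    _, breakdown = brdm_optimize(ctx.params, ctx.prior, 0.0, ctx.econ, ctx.policy)
    return breakdown.tsc


def _prior_spreads(ctx: DecisionContext) -> tuple[float, float]:
    _, u_tox, u_exp = _difference_frame(ctx.params, ctx.prior)
    return u_tox, u_exp


def ev_perfect_information(
    ctx: DecisionContext, delay_years: float = 0.0
) -> InfoValue:
    """Value of learning every uncertain parameter exactly.

    ``delay_years > 0`` gives the delayed variant (EVDPI): the revelation
    takes time, and health costs keep accruing unmitigated meanwhile.
    """
    u_tox, u_exp = _prior_spreads(ctx)
    outer = math.hypot(u_tox, u_exp)
    ev_ci = ev_current_information(ctx)
    ev_g = _ev_given(ctx, outer, 0.0, delay_years)
    return InfoValue(ev_g, ev_ci - ev_g)


def ev_partial_perfect_information(
    ctx: DecisionContext,
    subset: Iterable[str],
    delay_years: float = 0.0,
) -> InfoValue:
    """Value of learning only ``subset`` (e.g. {"mu_tox"}) exactly.

    Reduces to :func:`ev_perfect_information` when the subset covers all
    uncertain parameters, and to zero gain when it is empty.
    """
    subset = tuple(subset)
    uncertain = set(ctx.prior.entries)
    unknown = set(subset) - uncertain
    if unknown:
        raise InvalidParameterError(
            f"subset names parameters without uncertainty: {sorted(unknown)}"
        )
    u_tox, u_exp = _prior_spreads(ctx)
    outer_var = 0.0
    if "mu_tox" in subset:
        outer_var += u_tox**2
    if "mu_exp" in subset:
        outer_var += u_exp**2
    residual_var = u_tox**2 + u_exp**2 - outer_var
    ev_ci = ev_current_information(ctx)
    ev_g = _ev_given(
        ctx, math.sqrt(outer_var), math.sqrt(residual_var), delay_years
    )
    return InfoValue(ev_g, ev_ci - ev_g)


def ev_sample_information(
    ctx: DecisionContext, test: TestSpec, delayed: bool = True
) -> InfoValue:
    """Value of an actual toxicity test, with (EVDSI) or without (EVISI) its delay.

    Integrates the re-optimised objective over the preposterior distribution
    of the post-test state; the test narrows toxicity uncertainty to its
    achieved width and leaves exposure uncertainty in place.
    """
    d0, outer_sd, residual_sd, delay = _preposterior_geometry(
        ctx.params, ctx.prior, test
    )
    ev_ci = ev_current_information(ctx)
    ev_g = _ev_given(ctx, outer_sd, residual_sd, delay if delayed else 0.0)
    return InfoValue(ev_g, ev_ci - ev_g)


def ev_sample_information_mc(
    ctx: DecisionContext,
    test: TestSpec,
    delayed: bool = True,
    n: int = 10**5,
    seed: int = 20220422,
) -> tuple[float, float]:
    """Seeded Monte-Carlo cross-check of :func:`ev_sample_information`.

    Returns ``(ev_given_estimate, standard_error)``.
    """
    _, outer_sd, residual_sd, delay = _preposterior_geometry(
        ctx.params, ctx.prior, test
    )
    return _ev_given_mc(ctx, outer_sd, residual_sd, delay if delayed else 0.0, n, seed)


def cost_of_delay(ctx: DecisionContext, test: TestSpec) -> float:
    """EVISI - EVDSI: the value destroyed by waiting for the test."""
    evisi = ev_sample_information(ctx, test, delayed=False).gain
    evdsi = ev_sample_information(ctx, test, delayed=True).gain
    return evisi - evdsi


def cod_perfect_information(ctx: DecisionContext, delay_years: float) -> float:
    """EVIPI - EVDPI at the given revelation delay."""
    return (
        ev_perfect_information(ctx, 0.0).gain
        - ev_perfect_information(ctx, delay_years).gain
    )


def cod_partial_perfect_information(
    ctx: DecisionContext, subset: Iterable[str], delay_years: float
) -> float:
    """EVIPPI - EVDPPI at the given revelation delay."""
    subset = tuple(subset)
    return (
        ev_partial_perfect_information(ctx, subset, 0.0).gain
        - ev_partial_perfect_information(ctx, subset, delay_years).gain
    )


def enbs_roi(ctx: DecisionContext, test: TestSpec) -> EnbsRoi:
    """Expected net benefit of sampling and return on investment.

    ENBS = EVDSI - cost of testing; ROI = ENBS / cost. ROI is NaN (with a
    warning) for a zero-cost test.
    """
    evdsi = ev_sample_information(ctx, test, delayed=True).gain
    enbs = evdsi - test.cost
    if test.cost > 0:
        roi = enbs / test.cost
    else:
        warnings.warn(f"ROI undefined for zero-cost test {test.name!r}", stacklevel=2)
        roi = math.nan
    return EnbsRoi(enbs, roi)


# ---------------------------------------------------------------------------
# reports

@dataclass(frozen=True)
class TestMetrics:
    """Per-test slice of the metric ladder, $M except the unitless ROI."""

    evisi: float
    evdsi: float
    cod: float
    enbs: float
    roi: float


@dataclass(frozen=True)
class VOIReport:
    """Complete metric ladder for one scenario and one decision maker."""

    decision_maker: str
    ev_ci: float
    evipi: float
    evippi: float
    cod_pi: float
    cod_ppi: float
    ore_prior: float | None
    prior_verdict: str
    best_test: str | None
    tests: dict[str, TestMetrics] = field(default_factory=dict)
    decision_probs: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def compute_report(
    ctx: DecisionContext, tests: Sequence[TestSpec] = ()
) -> VOIReport:
    """Assemble the full ladder plus decision probabilities for a scenario.

    The delayed-perfect variants (behind ``cod_pi``/``cod_ppi``) are
    evaluated at the longest test duration in ``tests`` — the natural bound
    when comparing the slowest actual strategy against perfection — or 0
    with no tests, making both CoD terms vanish.
    """
    ev_ci = ev_current_information(ctx)
    evipi = ev_perfect_information(ctx).gain
    tox_subset = ("mu_tox",) if "mu_tox" in ctx.prior.entries else ()
    evippi = ev_partial_perfect_information(ctx, tox_subset).gain
    ref_delay = max((t.delay_years for t in tests), default=0.0)
    cod_pi = cod_perfect_information(ctx, ref_delay)
    cod_ppi = cod_partial_perfect_information(ctx, tox_subset, ref_delay)

    if ctx.is_trdm:
        ore = None
        verdict = trdm_decide(ctx.params, ctx.prior, ctx.policy).verdict.value
    else:
        decision, _ = brdm_optimize(ctx.params, ctx.prior, 0.0, ctx.econ, ctx.policy)
        ore = decision.chosen_k
        verdict = decision.verdict.value

    per_test: dict[str, TestMetrics] = {}
    probs: dict[str, tuple[float, float, float]] = {
        "perfect": decision_probabilities(
            ctx.params, ctx.prior, None, ctx.policy, ctx.econ
        )
    }
    for test in tests:
        evisi = ev_sample_information(ctx, test, delayed=False).gain
        evdsi = ev_sample_information(ctx, test, delayed=True).gain
        enbs = evdsi - test.cost
        roi = enbs / test.cost if test.cost > 0 else math.nan
        per_test[test.name] = TestMetrics(
            evisi=evisi, evdsi=evdsi, cod=evisi - evdsi, enbs=enbs, roi=roi
        )
        probs[test.name] = decision_probabilities(
            ctx.params, ctx.prior, test, ctx.policy, ctx.econ
        )

    priced = {n: m for n, m in per_test.items() if not math.isnan(m.roi)}
    best = max(priced, key=lambda n: priced[n].roi) if priced else None
    return VOIReport(
        decision_maker="trdm" if ctx.is_trdm else "brdm",
        ev_ci=ev_ci,
        evipi=evipi,
        evippi=evippi,
        cod_pi=cod_pi,
        cod_ppi=cod_ppi,
        ore_prior=ore,
        prior_verdict=verdict,
        best_test=best,
        tests=per_test,
        decision_probs=probs,
    )
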