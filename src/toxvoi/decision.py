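"""Decision-maker models: target-risk (TRDM) and benefit-risk (BRDM).

The TRDM regulates when the population risk credibly exceeds a target risk
level (TRL): under uncertainty it compares the lower and upper percentiles
(default 5th/95th) of the risk uncertainty distribution with the TRL and may
come away undecided when the band straddles it. When it regulates, it
applies a fixed proportionate cut in mean exposure (default 90%, one log10
unit).

The BRDM minimises expected total social cost over a grid of mitigation
levels and therefore always reaches a decision; its optimum is the optimal
reduction in exposure (ORE).

Because risk is a monotone (probit) transform of the location difference
mu_exp - mu_tox, every percentile comparison reduces to a threshold on that
difference, and preposterior decision probabilities have closed forms when
the uncertainty being integrated is normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import norm

from .econ import CostBreakdown, EconTiming, control_cost, discounted_sum, total_social_cost
from .errors import InvalidParameterError
from .risk import MitigationLevel, RiskParams, expected_risk
from .uncertainty import TestSpec, UncertaintyState, preposterior_mean_distribution

__all__ = [
    "Verdict",
    "Decision",
    "TRDMPolicy",
    "BRDMPolicy",
    "trdm_decide",
    "brdm_optimize",
    "decision_probabilities",
]


class Verdict(str, Enum):
    REGULATE = "regulate"
    NO_ACTION = "no_action"
    UNDECIDED = "undecided"


@dataclass(frozen=True)
class Decision:
    """Outcome of a decision rule. ``chosen_k`` is 0 unless regulating."""

    verdict: Verdict
    chosen_k: float = 0.0


@dataclass(frozen=True)
class TRDMPolicy:
    """Target-risk rule: percentile band of risk compared against a TRL."""

    trl: float
    lower_pct: float = 0.05
    upper_pct: float = 0.95
    action_k: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.trl < 1:
            raise InvalidParameterError(f"trl must lie in (0, 1), got {self.trl!r}")
        if not 0 < self.lower_pct < self.upper_pct < 1:
            raise InvalidParameterError("need 0 < lower_pct < upper_pct < 1")
        if not 0 <= self.action_k <= 100:
            raise InvalidParameterError("action_k must lie in [0, 100]")


def _default_grid() -> tuple[float, ...]:
    return tuple(float(k) for k in range(101))


@dataclass(frozen=True)
class BRDMPolicy:
    """Benefit-risk rule: minimise ETSC over an ordered mitigation grid."""

    k_grid: tuple[float, ...] = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        grid = tuple(float(k) for k in self.k_grid)
        if len(grid) == 0 or grid[0] != 0.0:
            raise InvalidParameterError("k_grid must be nonempty and contain 0 first")
        arr = np.asarray(grid)
        if np.any(np.diff(arr) <= 0) or arr[0] < 0 or arr[-1] > 100:
            raise InvalidParameterError("k_grid must be strictly increasing within [0, 100]")
        object.__setattr__(self, "k_grid", grid)


# ---------------------------------------------------------------------------
# shared vectorised kernels (also used by the voi module)

def _k_shifts(k_grid: np.ndarray) -> np.ndarray:
    """log10 retention per grid level; -inf at k = 100."""
    k = np.asarray(k_grid, dtype=float)
    out = np.full(k.shape, -np.inf)
    mask = k < 100
    out[mask] = np.log10(1.0 - k[mask] / 100.0)
    return out


def _risk_matrix(m_d: np.ndarray, s_res: float, shifts: np.ndarray) -> np.ndarray:
    """E[R_k | m_d]: probit of the location difference, (n, K)."""
    m_d = np.atleast_1d(np.asarray(m_d, dtype=float))
    return norm.cdf((m_d[:, None] + shifts[None, :]) / s_res)


def _etsc_matrix(
    m_d: np.ndarray,
    s_res: float,
    k_grid: np.ndarray,
    delay_years: float,
    econ: EconTiming,
) -> np.ndarray:
    """Expected TSC per (conditional-mean, mitigation-level) pair, (n, K)."""
    shifts = _k_shifts(k_grid)
    rk = _risk_matrix(m_d, s_res, shifts)
    r0 = rk[:, [0]]  # grid contains k = 0 first
    d_all = discounted_sum(1, econ)
    d_impl = discounted_sum(econ.first_controlled_year(delay_years), econ)
    acc = np.array([control_cost(MitigationLevel(k), econ) for k in k_grid])
    return acc[None, :] * d_impl + econ.value_rate * (
        r0 * d_all - (r0 - rk) * d_impl
    )


def _difference_frame(params: RiskParams, unc: UncertaintyState):
    """(d0, u_tox, u_exp) of the location difference mu_exp - mu_tox."""
    mt = unc.center("mu_tox", params.mu_tox)
    me = unc.center("mu_exp", params.mu_exp)
    return me - mt, unc.width("mu_tox"), unc.width("mu_exp")


# ---------------------------------------------------------------------------
# decision rules

def trdm_decide(
    params: RiskParams, unc: UncertaintyState, policy: TRDMPolicy
) -> Decision:
    """Percentile-band comparison of the risk distribution against the TRL.

    With zero-width uncertainty the rule degenerates to a direct comparison
    of the (known) risk with the TRL. Risk percentiles are computed through
    the monotone probit map, so no sampling is involved.
    """
    d0, u_tox, u_exp = _difference_frame(params, unc)
    b = params.combined_sigma
    u_d = math.hypot(u_tox, u_exp)
    if u_d == 0:
        risk = float(norm.cdf(d0 / b))
        if risk > policy.trl:
            return Decision(Verdict.REGULATE, policy.action_k)
        return Decision(Verdict.NO_ACTION, 0.0)
    q_lo = float(norm.cdf((d0 + norm.ppf(policy.lower_pct) * u_d) / b))
    q_up = float(norm.cdf((d0 + norm.ppf(policy.upper_pct) * u_d) / b))
    if q_lo > policy.trl:
        return Decision(Verdict.REGULATE, policy.action_k)
    if q_up <= policy.trl:
        return Decision(Verdict.NO_ACTION, 0.0)
    return Decision(Verdict.UNDECIDED, 0.0)


def brdm_optimize(
    params: RiskParams,
    unc: UncertaintyState,
    delay_years: float,
    econ: EconTiming,
    policy: BRDMPolicy,
) -> tuple[Decision, CostBreakdown]:
    """Minimise expected total social cost over the mitigation grid.

    Ties are resolved toward the smaller mitigation level (least
    intervention). Returns the decision and the cost breakdown at the
    optimum.
    """
    d0, u_tox, u_exp = _difference_frame(params, unc)
    s_res = math.sqrt(params.combined_sigma**2 + u_tox**2 + u_exp**2)
    grid = np.asarray(policy.k_grid)
    tsc = _etsc_matrix(np.array([d0]), s_res, grid, delay_years, econ)[0]
    best = int(np.argmin(tsc))  # first minimum -> smallest k on ties
    k_star = float(grid[best])
    level = MitigationLevel(k_star)
    breakdown = total_social_cost(
        expected_risk(params, unc, MitigationLevel(0.0)),
        expected_risk(params, unc, level),
        level,
        delay_years,
        econ,
    )
    verdict = Verdict.REGULATE if k_star > 0 else Verdict.NO_ACTION
    return Decision(verdict, k_star), breakdown


# ---------------------------------------------------------------------------
# preposterior decision probabilities

def _preposterior_geometry(
    params: RiskParams, prior: UncertaintyState, test: TestSpec | None
):
    """Spread of the post-test conditional mean of the location difference
    (outer_sd), residual post-test uncertainty (residual_sd), and delay."""
    d0, u_tox, u_exp = _difference_frame(params, prior)
    if test is None:  # perfect toxicity information
        post_tox, delay = 0.0, 0.0
    else:
        post_tox, delay = test.posterior_sd, test.delay_years
    if u_tox > 0:
        _, outer_sd = preposterior_mean_distribution(0.0, u_tox, post_tox)
    else:
        if post_tox > 0:
            raise InvalidParameterError("prior has no toxicity uncertainty to reduce")
        outer_sd = 0.0
    residual_sd = math.hypot(post_tox, u_exp)
    return d0, outer_sd, residual_sd, delay


def _trdm_probabilities(
    d0: float, outer_sd: float, residual_sd: float, b: float, policy: TRDMPolicy
) -> tuple[float, float, float]:
    # regulate iff conditional mean m > tau_reg; no action iff m <= tau_no
    base = b * norm.ppf(policy.trl)
    if residual_sd == 0:
        tau_reg = tau_no = base
    else:
        tau_reg = base - norm.ppf(policy.lower_pct) * residual_sd
        tau_no = base - norm.ppf(policy.upper_pct) * residual_sd
    if outer_sd == 0:
        p1 = 1.0 if d0 > tau_reg else 0.0
        p0 = 1.0 if d0 <= tau_no else 0.0
    else:
        p1 = float(norm.sf((tau_reg - d0) / outer_sd))
        p0 = float(norm.cdf((tau_no - d0) / outer_sd))
    return p1, p0, max(1.0 - p1 - p0, 0.0)


def _brdm_regulate_probability(
    d0: float,
    outer_sd: float,
    residual_sd: float,
    b: float,
    delay: float,
    econ: EconTiming,
    policy: BRDMPolicy,
) -> float:
    """P(optimal mitigation > 0) under the preposterior distribution.

    Locates the switch points of the piecewise-constant optimal policy by a
    coarse scan over quantiles of the conditional-mean distribution followed
    by bisection, then sums the exact normal masses of the regulate region.
    """
    grid = np.asarray(policy.k_grid)
    s_res = math.sqrt(b**2 + residual_sd**2)

    def regulates(m: np.ndarray) -> np.ndarray:
        tsc = _etsc_matrix(np.atleast_1d(m), s_res, grid, delay, econ)
        return grid[np.argmin(tsc, axis=1)] > 0

    if outer_sd == 0:
        return float(regulates(np.array([d0]))[0])

    probs = np.linspace(1e-10, 1 - 1e-10, 257)
    m_scan = d0 + outer_sd * norm.ppf(probs)
    flags = regulates(m_scan)
    flips = np.nonzero(flags[:-1] != flags[1:])[0]
    boundaries = []
    for i in flips:
        lo, hi = m_scan[i], m_scan[i + 1]
        f_lo = flags[i]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if regulates(np.array([mid]))[0] == f_lo:
                lo = mid
            else:
                hi = mid
        boundaries.append(0.5 * (lo + hi))
    edges = [-np.inf, *boundaries, np.inf]
    total = 0.0
    # classify each interval by its (clipped) midpoint and accumulate mass
    for lo_e, hi_e in zip(edges[:-1], edges[1:]):
        mid = np.clip(
            0.5 * (max(lo_e, d0 - 12 * outer_sd) + min(hi_e, d0 + 12 * outer_sd)),
            d0 - 12 * outer_sd,
            d0 + 12 * outer_sd,
        )
        if regulates(np.array([mid]))[0]:
            total += norm.cdf((hi_e - d0) / outer_sd) - norm.cdf((lo_e - d0) / outer_sd)
    return float(min(max(total, 0.0), 1.0))


def decision_probabilities(
    params: RiskParams,
    prior: UncertaintyState,
    test: TestSpec | None,
    policy: TRDMPolicy | BRDMPolicy,
    econ: EconTiming | None = None,
) -> tuple[float, float, float]:
    """Preposterior (P[regulate], P[no action], P[undecided]).

    ``test=None`` denotes perfect toxicity information: the decision is
    integrated over the prior of the toxicity location, with any exposure
    uncertainty left in place. For a :class:`TestSpec`, the decision is
    integrated over the preposterior distribution of the posterior mean at
    the test's achieved width. The BRDM (which requires ``econ``) never
    returns undecided. The triple sums to 1.
    """
    d0, outer_sd, residual_sd, delay = _preposterior_geometry(params, prior, test)
    b = params.combined_sigma
    if isinstance(policy, TRDMPolicy):
        return _trdm_probabilities(d0, outer_sd, residual_sd, b, policy)
    if econ is None:
        raise InvalidParameterError("BRDM decision probabilities require econ")
    p1 = _brdm_regulate_probability(d0, outer_sd, residual_sd, b, delay, econ, policy)
    return p1, 1.0 - p1, 0.0
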