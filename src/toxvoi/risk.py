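"""Population-risk model for a chemical with lognormal tolerance and exposure.

Inter-individual tolerance (the dose at which an individual exhibits the
adverse effect) and inter-individual exposure are both taken to be lognormal.
On the log10 dose scale they are normal with locations mu_tox, mu_exp and
spreads sigma_tox, sigma_exp, and the population average risk — the chance
that a random individual's exposure exceeds their tolerance — has the probit
closed form

    R = Phi((mu_exp - mu_tox) / sqrt(sigma_exp**2 + sigma_tox**2)).

A mitigation that cuts mean exposure by k% shifts mu_exp by
log10(1 - k/100); complete elimination (k = 100) drives the risk to zero.
Normal uncertainty about the location parameters folds into the same closed
form: the uncertainty variances simply add to the variability variances
inside the probit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .errors import InvalidParameterError
from .uncertainty import UncertaintyState, sample_prior

__all__ = [
    "RiskParams",
    "MitigationLevel",
    "population_risk",
    "population_risk_mc",
    "mitigated_risk",
    "tox_location_threshold",
    "expected_risk",
    "expected_risk_mc",
]

_LOCATION_FIELDS = frozenset({"mu_tox", "mu_exp"})
_SIGMA_FIELDS = frozenset({"sigma_tox", "sigma_exp"})


@dataclass(frozen=True)
class RiskParams:
    """Lognormal toxicity/exposure parameters on the log10 dose scale.

    ``mu_tox`` is the log10 of the population median tolerance (for a
    dichotomous endpoint, the log10 ED50 in mg/kg-bw/day); ``sigma_tox`` the
    log10 spread of inter-individual tolerance; ``mu_exp``/``sigma_exp`` the
    analogous location and spread of the exposure distribution.
    """

    mu_tox: float
    sigma_tox: float
    mu_exp: float
    sigma_exp: float

    def __post_init__(self) -> None:
        for name in ("mu_tox", "mu_exp"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        for name in ("sigma_tox", "sigma_exp"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be positive, got {v!r}")

    @property
    def combined_sigma(self) -> float:
        """sqrt(sigma_exp**2 + sigma_tox**2), the probit denominator."""
        return math.hypot(self.sigma_tox, self.sigma_exp)


@dataclass(frozen=True)
class MitigationLevel:
    """A proportionate reduction in mean exposure, in percent."""

    k: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and 0 <= self.k <= 100):
            raise InvalidParameterError(f"k must lie in [0, 100], got {self.k!r}")

    @property
    def log10_retention(self) -> float:
        """log10(1 - k/100): the shift applied to mu_exp (-inf at k = 100)."""
        if self.k >= 100:
            return -math.inf
        return math.log10(1.0 - self.k / 100.0)


def population_risk(params: RiskParams) -> float:
    """Closed-form population average risk, strictly inside (0, 1)."""
    return float(norm.cdf((params.mu_exp - params.mu_tox) / params.combined_sigma))


def population_risk_mc(
    params: RiskParams, n: int = 10**6, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo evaluation of the defining risk integral.

    Averages the tolerance CDF over exposure draws; returns ``(estimate,
    standard_error)``. Serves as a verification path for
    :func:`population_risk`, not as its implementation.
    """
    rng = np.random.default_rng(seed)
    log_x = rng.normal(params.mu_exp, params.sigma_exp, size=n)
    g = norm.cdf((log_x - params.mu_tox) / params.sigma_tox)
    return float(g.mean()), float(g.std(ddof=1) / math.sqrt(n))


def mitigated_risk(params: RiskParams, level: MitigationLevel) -> float:
    """Population risk after reducing mean exposure by ``level.k`` percent."""
    if level.k >= 100:
        return 0.0
    shifted = replace(params, mu_exp=params.mu_exp + level.log10_retention)
    return population_risk(shifted)


def tox_location_threshold(trl: float, params: RiskParams) -> float:
    """Toxicity location at which the population risk equals ``trl``.

    Returns mu_tox* = mu_exp - Phi^-1(trl) * combined_sigma, holding the
    other parameters fixed. Because risk is strictly decreasing in mu_tox,
    population risk exceeds ``trl`` exactly when mu_tox < mu_tox*.
    """
    if not 0 < trl < 1:
        raise InvalidParameterError(f"trl must lie in (0, 1), got {trl!r}")
    return params.mu_exp - norm.ppf(trl) * params.combined_sigma


def _location_uncertainty(params: RiskParams, unc: UncertaintyState):
    """Validate that uncertainty sits on location fields only; return
    (effective mu_tox, effective mu_exp, extra variance)."""
    for name in unc:
        if name in _SIGMA_FIELDS:
            raise NotImplementedError(
                "uncertainty on spread parameters is not supported"
            )
        if name not in _LOCATION_FIELDS:
            raise InvalidParameterError(f"unknown risk parameter {name!r}")
    mt = unc.center("mu_tox", params.mu_tox)
    me = unc.center("mu_exp", params.mu_exp)
    extra_var = unc.width("mu_tox") ** 2 + unc.width("mu_exp") ** 2
    return mt, me, extra_var


def expected_risk(
    params: RiskParams, unc: UncertaintyState, level: MitigationLevel
) -> float:
    """E[R_k] over independent normal uncertainty on the location parameters.

    Uses the closed form E[Phi((a - X)/b)] = Phi((a - E[X]) / sqrt(b^2 +
    Var[X])): the uncertainty variances add to the variability variances
    inside the probit. With zero-width uncertainty this reduces exactly to
    :func:`mitigated_risk`.
    """
    if level.k >= 100:
        return 0.0
    mt, me, extra_var = _location_uncertainty(params, unc)
    s = math.sqrt(params.combined_sigma**2 + extra_var)
    return float(norm.cdf((me + level.log10_retention - mt) / s))


def expected_risk_mc(
    params: RiskParams,
    unc: UncertaintyState,
    level: MitigationLevel,
    n: int = 10**5,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo verification path for :func:`expected_risk`.

    Draws locations from the uncertainty state, evaluates the mitigated risk
    closed form per draw, and returns ``(estimate, standard_error)``.
    """
    _location_uncertainty(params, unc)  # validation only
    draws = sample_prior(unc, n, seed)
    mt = draws.get("mu_tox", np.full(n, params.mu_tox))
    me = draws.get("mu_exp", np.full(n, params.mu_exp))
    if level.k >= 100:
        return 0.0, 0.0
    r = norm.cdf((me + level.log10_retention - mt) / params.combined_sigma)
    return float(r.mean()), float(r.std(ddof=1) / math.sqrt(n))
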