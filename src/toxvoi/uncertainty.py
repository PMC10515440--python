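"""Uncertainty over risk parameters and conjugate Bayesian updating.

Prior knowledge about each risk parameter (a location on the log10 dose
scale) is described by an independent normal distribution on that scale,
i.e. a lognormal distribution of the dose quantity itself. A toxicity test
delivers a noisy log10-scale observation of the true parameter; because the
observation noise is also normal, the update is conjugate: precisions add
and the posterior mean is the precision-weighted average of prior mean and
observation.

Uncertainty magnitudes are quoted in *orders of magnitude* (OM): the width
of the central 99.975% range of the distribution, measured in factors of 10.
That central range spans 7.325 standard deviations of a normal, so an OM
span converts to a log10-scale standard deviation by dividing by 7.325.

A test is characterised by the posterior width it achieves, not by its
observation noise: the noise standard deviation is back-derived per prior
(``implied_sigma_s``) so that the update lands exactly on the advertised
posterior width. Preposterior analysis — valuing a test before running it —
then needs the distribution of the posterior mean over possible outcomes,
which is again normal (``preposterior_mean_distribution``), with spread
sqrt(prior_sd**2 - posterior_sd**2): information moves the posterior mean
exactly as much as it shrinks the posterior spread (law of total variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

import numpy as np

from .errors import InfeasibleTestError, InvalidParameterError

__all__ = [
    "OM_SPAN",
    "ParamUncertainty",
    "UncertaintyState",
    "TestSpec",
    "om_to_sd",
    "sd_to_om",
    "bayes_update",
    "implied_sigma_s",
    "preposterior_mean_distribution",
    "observation_marginal",
    "sample_prior",
]

#: Standard deviations of a normal spanned by its central 99.975% range.
OM_SPAN = 7.325


def om_to_sd(om: float) -> float:
    """Convert an uncertainty range in orders of magnitude to a log10-scale sd.

    Parameters
    ----------
    om
        Width of the central 99.975% uncertainty range, in factors of 10.
        Must be positive.
    """
    if not om > 0:
        raise InvalidParameterError(f"OM range must be positive, got {om!r}")
    return om / OM_SPAN


def sd_to_om(sd: float) -> float:
    """Inverse of :func:`om_to_sd` (sd must be nonnegative)."""
    if sd < 0:
        raise InvalidParameterError(f"sd must be nonnegative, got {sd!r}")
    return sd * OM_SPAN


class ParamUncertainty(NamedTuple):
    """Normal uncertainty on one log10-scale parameter."""

    center: float
    width: float  # standard deviation on the log10 scale, >= 0


@dataclass(frozen=True)
class UncertaintyState:
    """Independent normal uncertainty over a subset of risk parameters.

    Parameters absent from ``entries`` are treated as known exactly. Entries
    are mutually independent. A zero width marks a parameter whose value is
    pinned to its center (useful for degenerate/posterior states).
    """

    entries: Mapping[str, ParamUncertainty] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, entry in dict(self.entries).items():
            entry = ParamUncertainty(float(entry[0]), float(entry[1]))
            if not math.isfinite(entry.center):
                raise InvalidParameterError(f"center for {name!r} must be finite")
            if not (math.isfinite(entry.width) and entry.width >= 0):
                raise InvalidParameterError(
                    f"width for {name!r} must be finite and >= 0, got {entry.width!r}"
                )
            clean[name] = entry
        object.__setattr__(self, "entries", clean)

    @classmethod
    def from_widths(cls, params, widths: Mapping[str, float]) -> "UncertaintyState":
        """Build a state centred on ``params`` fields with the given sds.

        Zero widths are dropped (the parameter is simply known).
        """
        entries = {
            name: ParamUncertainty(getattr(params, name), float(w))
            for name, w in widths.items()
            if w > 0
        }
        return cls(entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def width(self, name: str) -> float:
        """Uncertainty sd for ``name`` (0 when the parameter is known)."""
        entry = self.entries.get(name)
        return entry.width if entry is not None else 0.0

    def center(self, name: str, default: float | None = None) -> float:
        entry = self.entries.get(name)
        if entry is not None:
            return entry.center
        if default is None:
            raise KeyError(name)
        return float(default)

    def replace_entry(self, name: str, center: float, width: float) -> "UncertaintyState":
        entries = dict(self.entries)
        if width > 0:
            entries[name] = ParamUncertainty(center, width)
        else:
            entries.pop(name, None)
        return UncertaintyState(entries)


@dataclass(frozen=True)
class TestSpec:
    """A toxicity test, characterised by what it achieves and what it costs.

    Attributes
    ----------
    name
        Label used in reports.
    posterior_width_om
        Posterior uncertainty range for the toxicity location achieved by the
        test, in orders of magnitude. Zero denotes perfect toxicity
        information (a theoretical limit used in response surfaces).
    duration_years
        Time to conduct and analyse the test.
    decision_years
        Additional time to evaluate results and reach a decision (default 0;
        the illustrative applications fold evaluation time into the test
        duration).
    cost
        Cost of testing, $M per test.
    """

    __test__ = False  # keep pytest from collecting this as a test class

    name: str
    posterior_width_om: float
    duration_years: float
    cost: float
    decision_years: float = 0.0

    def __post_init__(self) -> None:
        for fname in ("posterior_width_om", "duration_years", "decision_years", "cost"):
            v = getattr(self, fname)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{fname} must be finite and >= 0, got {v!r}")

    @property
    def posterior_sd(self) -> float:
        """Achieved posterior sd on the log10 scale (0 for perfect information)."""
        return 0.0 if self.posterior_width_om == 0 else om_to_sd(self.posterior_width_om)

    @property
    def delay_years(self) -> float:
        """Total decision delay the test imposes."""
        return self.duration_years + self.decision_years


def bayes_update(
    prior_center: float, prior_sd: float, s: float, sigma_s: float
) -> tuple[float, float]:
    """Conjugate normal update of a log10-scale prior with one observation.

    Posterior precision is the sum of prior and observation precisions; the
    posterior center is the precision-weighted mean of prior center and
    observation ``s``. Returns ``(posterior_center, posterior_sd)``.
    """
    if not prior_sd > 0:
        raise InvalidParameterError(f"prior_sd must be positive, got {prior_sd!r}")
    if not sigma_s > 0:
        raise InvalidParameterError(f"sigma_s must be positive, got {sigma_s!r}")
    prec = prior_sd**-2 + sigma_s**-2
    post_var = 1.0 / prec
    post_center = post_var * (prior_center / prior_sd**2 + s / sigma_s**2)
    return post_center, math.sqrt(post_var)


def implied_sigma_s(prior_sd: float, target_posterior_sd: float) -> float:
    """Observation noise sd that shrinks ``prior_sd`` to ``target_posterior_sd``.

    Inverts the conjugate update so a test can be specified by its achieved
    posterior width: sigma_s = (target**-2 - prior**-2) ** -0.5.
    """
    if not prior_sd > 0:
        raise InvalidParameterError(f"prior_sd must be positive, got {prior_sd!r}")
    if not target_posterior_sd > 0:
        raise InvalidParameterError(
            f"target_posterior_sd must be positive, got {target_posterior_sd!r}"
        )
    if target_posterior_sd >= prior_sd:
        raise InfeasibleTestError(
            f"a test cannot widen uncertainty: target sd {target_posterior_sd!r} "
            f">= prior sd {prior_sd!r}"
        )
    return (target_posterior_sd**-2 - prior_sd**-2) ** -0.5


def preposterior_mean_distribution(
    prior_center: float, prior_sd: float, target_posterior_sd: float
) -> tuple[float, float]:
    """Distribution of the posterior center before the test is run.

    Under the conjugate model the posterior mean, viewed preposteriorly,
    is normal with mean ``prior_center`` and sd
    sqrt(prior_sd**2 - target_posterior_sd**2). ``target_posterior_sd`` may
    equal ``prior_sd`` (an uninformative test: the posterior mean cannot
    move) or be 0 (perfect information: the posterior mean is the truth).
    """
    if not prior_sd > 0:
        raise InvalidParameterError(f"prior_sd must be positive, got {prior_sd!r}")
    if not 0 <= target_posterior_sd:
        raise InvalidParameterError(
            f"target_posterior_sd must be >= 0, got {target_posterior_sd!r}"
        )
    if target_posterior_sd > prior_sd:
        raise InfeasibleTestError(
            f"a test cannot widen uncertainty: target sd {target_posterior_sd!r} "
            f"> prior sd {prior_sd!r}"
        )
    spread = math.sqrt(max(prior_sd**2 - target_posterior_sd**2, 0.0))
    return prior_center, spread


def observation_marginal(
    prior_center: float, prior_sd: float, sigma_s: float
) -> tuple[float, float]:
    """Marginal distribution of the observation s: N(prior_center, sqrt(u0^2+sigma_s^2))."""
    if not prior_sd > 0 or not sigma_s > 0:
        raise InvalidParameterError("prior_sd and sigma_s must be positive")
    return prior_center, math.hypot(prior_sd, sigma_s)


def sample_prior(
    state: UncertaintyState, n: int, seed: int
) -> dict[str, np.ndarray]:
    """Reproducible draws from the joint (independent) prior.

    Returns one array of length ``n`` per entry of ``state``; parameters not
    in the state are known exactly and are not sampled.
    """
    if not n > 0:
        raise InvalidParameterError(f"n must be positive, got {n!r}")
    rng = np.random.default_rng(seed)
    draws = {}
    for name in sorted(state.entries):
        center, width = state.entries[name]
        if width == 0:
            draws[name] = np.full(n, center)
        else:
            draws[name] = rng.normal(center, width, size=n)
    return draws
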