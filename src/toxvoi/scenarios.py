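"""Scenario presets, configuration I/O, sweeps and report writing.

Six presets span two illustrative applications — a fatal outcome (lifetime
risk, valued at a $8.8M value of statistical life) and an acute outcome (a
daily-risk airway event valued at $50) — each under three prior-uncertainty
scenarios:

* scenario 1 — 7 orders of magnitude (OM) of prior uncertainty about the
  toxicity location, exposure known;
* scenario 2 — 5 OM about toxicity, exposure known;
* scenario 3 — 5 OM about toxicity plus sqrt(24) OM about exposure, so the
  *combined* prior uncertainty matches scenario 1 while part of it is
  unreducible by toxicity testing.

Both applications share a 350M-person population, a 20-year horizon, a 5%
discount rate, a 2-year implementation time, a $2.2B/year maximum control
cost with exponential steepness 2, and two candidate tests: Test A (1 year,
$5K, posterior toxicity width 4 OM) and Test B (5 years, $5M, 2 OM).

Configurations are plain YAML mappings whose keys mirror the scenario
parameter names (``N``, ``r``, ``t_imp``, ``t_TH``, ``CC_max``, ``eta``,
``TRL`` ...); unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .decision import BRDMPolicy, TRDMPolicy
from .econ import EconTiming
from .errors import ConfigError
from .risk import RiskParams
from .uncertainty import TestSpec, UncertaintyState, om_to_sd
from .voi import DecisionContext, VOIReport, compute_report, ev_sample_information

__all__ = [
    "ScenarioConfig",
    "ApplicationResult",
    "PRESET_NAMES",
    "load_scenario",
    "run_application",
    "response_surface",
    "sensitivity_sweep",
    "result_frame",
    "result_json",
    "write_report",
    "config_hash",
]

_OUTCOME_DEFAULTS = {
    # valuation $M/case, annualization /year, TRL, median risk
    "fatal": dict(valuation=8.8, annualization=1 / 80, trl=1e-7, median_risk=1e-8),
    "acute": dict(valuation=50e-6, annualization=365.0, trl=1e-5, median_risk=1e-6),
}

_SCENARIO_WIDTHS = {
    1: (7.0, 0.0),
    2: (5.0, 0.0),
    3: (5.0, math.sqrt(24.0)),
}

_DEFAULT_TESTS = (
    TestSpec(name="A", posterior_width_om=4.0, duration_years=1.0, cost=0.005),
    TestSpec(name="B", posterior_width_om=2.0, duration_years=5.0, cost=5.0),
)

PRESET_NAMES = tuple(
    f"{outcome}-s{sid}" for outcome in ("fatal", "acute") for sid in (1, 2, 3)
)


@dataclass
class ScenarioConfig:
    """Raw scenario parameters; derived model objects are exposed as properties."""

    label: str
    outcome: str
    scenario_id: int
    ed50: float = 50.0
    sigma_tox: float = 0.697
    sigma_exp: float = 0.5
    median_risk: float = 1e-8
    valuation: float = 8.8
    annualization: float = 1 / 80
    trl: float = 1e-7
    prior_tox_om: float = 7.0
    prior_exp_om: float = 0.0
    population: float = 350e6
    discount_rate: float = 0.05
    horizon_years: int = 20
    implement_years: float = 2.0
    acc_max: float = 2200.0
    acc_fixed: float = 0.0
    eta: float = 2.0
    impl_year_offset: int = 1
    action_k: float = 90.0
    tests: tuple[TestSpec, ...] = _DEFAULT_TESTS
    rng_seed: int = 20220422
    quadrature_nodes: int = 64
    mc_draws: int = 100_000

    def __post_init__(self) -> None:
        if self.outcome not in ("fatal", "acute"):
            raise ConfigError(f"outcome must be 'fatal' or 'acute', got {self.outcome!r}")
        if self.prior_tox_om < 0 or self.prior_exp_om < 0:
            raise ConfigError("prior uncertainty widths must be >= 0")
        if not 0 < self.median_risk < 1:
            raise ConfigError("median_risk must lie in (0, 1)")
        if self.quadrature_nodes < 2 or self.mc_draws < 1:
            raise ConfigError("quadrature_nodes >= 2 and mc_draws >= 1 required")
        self.tests = tuple(self.tests)
        names = [t.name for t in self.tests]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate test names: {names}")
        # building the derived objects validates the remaining fields
        self.risk_params, self.econ, self.trdm_policy, self.brdm_policy

    # -- derived model objects ------------------------------------------------

    @property
    def mu_tox(self) -> float:
        return math.log10(self.ed50)

    @property
    def mu_exp(self) -> float:
        """Exposure location implied by (ED50, median risk).

        The population median risk pins down the exposure median through the
        probit closed form, so the printed median exposure is treated as a
        rounded report of this derived value.
        """
        b = math.hypot(self.sigma_tox, self.sigma_exp)
        return self.mu_tox + norm.ppf(self.median_risk) * b

    @property
    def risk_params(self) -> RiskParams:
        return RiskParams(
            mu_tox=self.mu_tox,
            sigma_tox=self.sigma_tox,
            mu_exp=self.mu_exp,
            sigma_exp=self.sigma_exp,
        )

    @property
    def prior(self) -> UncertaintyState:
        widths = {}
        if self.prior_tox_om > 0:
            widths["mu_tox"] = om_to_sd(self.prior_tox_om)
        if self.prior_exp_om > 0:
            widths["mu_exp"] = om_to_sd(self.prior_exp_om)
        return UncertaintyState.from_widths(self.risk_params, widths)

    @property
    def econ(self) -> EconTiming:
        return EconTiming(
            population=self.population,
            valuation=self.valuation,
            annualization=self.annualization,
            discount_rate=self.discount_rate,
            horizon_years=self.horizon_years,
            implement_years=self.implement_years,
            acc_max=self.acc_max,
            acc_fixed=self.acc_fixed,
            steepness=self.eta,
            impl_year_offset=self.impl_year_offset,
        )

    @property
    def trdm_policy(self) -> TRDMPolicy:
        return TRDMPolicy(trl=self.trl, action_k=self.action_k)

    @property
    def brdm_policy(self) -> BRDMPolicy:
        return BRDMPolicy()

    def context(self, decision_maker: str) -> DecisionContext:
        if decision_maker == "trdm":
            policy = self.trdm_policy
        elif decision_maker == "brdm":
            policy = self.brdm_policy
        else:
            raise ConfigError(f"decision_maker must be 'trdm' or 'brdm', got {decision_maker!r}")
        return DecisionContext(
            params=self.risk_params,
            prior=self.prior,
            econ=self.econ,
            policy=policy,
            quadrature_nodes=self.quadrature_nodes,
        )


# ---------------------------------------------------------------------------
# presets and configuration I/O

def preset(name: str) -> ScenarioConfig:
    """Build one of the six illustrative presets ('fatal-s1' ... 'acute-s3')."""
    if name not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    outcome, sid_tag = name.split("-s")
    sid = int(sid_tag)
    tox_om, exp_om = _SCENARIO_WIDTHS[sid]
    return ScenarioConfig(
        label=name,
        outcome=outcome,
        scenario_id=sid,
        prior_tox_om=tox_om,
        prior_exp_om=exp_om,
        **_OUTCOME_DEFAULTS[outcome],
    )


_KEY_TO_FIELD = {
    "label": "label",
    "outcome": "outcome",
    "scenario": "scenario_id",
    "ED50": "ed50",
    "sigma_tox": "sigma_tox",
    "sigma_exp": "sigma_exp",
    "median_risk": "median_risk",
    "V": "valuation",
    "B_y": "annualization",
    "TRL": "trl",
    "prior_tox_om": "prior_tox_om",
    "prior_exp_om": "prior_exp_om",
    "N": "population",
    "r": "discount_rate",
    "t_TH": "horizon_years",
    "t_imp": "implement_years",
    "CC_max": "acc_max",
    "CC_overhead": "acc_fixed",
    "eta": "eta",
    "impl_year_offset": "impl_year_offset",
    "action_k": "action_k",
    "tests": "tests",
    "seed": "rng_seed",
    "quadrature_nodes": "quadrature_nodes",
    "mc_draws": "mc_draws",
}
_FIELD_TO_KEY = {v: k for k, v in _KEY_TO_FIELD.items()}

_TEST_KEYS = {"name", "posterior_om", "duration", "cost", "decision_years"}


def _parse_tests(raw, path: str) -> tuple[TestSpec, ...]:
    if not isinstance(raw, list):
        raise ConfigError(f"{path}: expected a list of test mappings")
    out = []
    for i, item in enumerate(raw):
        if not isinstance(item, Mapping):
            raise ConfigError(f"{path}[{i}]: expected a mapping")
        unknown = set(item) - _TEST_KEYS
        if unknown:
            raise ConfigError(f"{path}[{i}]: unknown keys {sorted(unknown)}")
        try:
            out.append(
                TestSpec(
                    name=str(item["name"]),
                    posterior_width_om=float(item["posterior_om"]),
                    duration_years=float(item["duration"]),
                    cost=float(item["cost"]),
                    decision_years=float(item.get("decision_years", 0.0)),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"{path}[{i}]: missing key {exc}") from exc
    return tuple(out)


def _from_mapping(raw: Mapping) -> ScenarioConfig:
    unknown = set(raw) - set(_KEY_TO_FIELD)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        fname = _KEY_TO_FIELD[key]
        if key == "tests":
            value = _parse_tests(value, "tests")
        kwargs[fname] = value
    base = dict(
        label=str(raw.get("label", "custom")),
        outcome=raw.get("outcome", "fatal"),
        scenario_id=int(raw.get("scenario", 0)),
    )
    outcome = base["outcome"]
    if outcome in _OUTCOME_DEFAULTS:
        for fname, v in _OUTCOME_DEFAULTS[outcome].items():
            base.setdefault(fname, v)
    base.update({k: v for k, v in kwargs.items() if k not in ("label", "outcome", "scenario_id")})
    try:
        return ScenarioConfig(**base)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_scenario(source) -> ScenarioConfig:
    """Load a scenario from a preset name, a mapping, a YAML file, or YAML text."""
    if isinstance(source, ScenarioConfig):
        return source
    if isinstance(source, Mapping):
        return _from_mapping(source)
    if isinstance(source, Path) or (
        isinstance(source, str) and source.endswith((".yml", ".yaml"))
    ):
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: expected a YAML mapping at top level")
        return _from_mapping(raw)
    if isinstance(source, str):
        if source in PRESET_NAMES:
            return preset(source)
        if "\n" in source or ":" in source:
            raw = yaml.safe_load(source)
            if not isinstance(raw, Mapping):
                raise ConfigError("expected a YAML mapping")
            return _from_mapping(raw)
        raise ConfigError(f"unknown preset {source!r}; choose from {PRESET_NAMES}")
    raise ConfigError(f"cannot interpret scenario source of type {type(source)!r}")


def to_dict(config: ScenarioConfig) -> dict:
    """Serialise a configuration to the YAML key schema (round-trips)."""
    out = {}
    for fname, key in _FIELD_TO_KEY.items():
        value = getattr(config, fname)
        if fname == "tests":
            value = [
                dict(
                    name=t.name,
                    posterior_om=t.posterior_width_om,
                    duration=t.duration_years,
                    cost=t.cost,
                    decision_years=t.decision_years,
                )
                for t in value
            ]
        out[key] = value
    return out


def config_hash(config: ScenarioConfig) -> str:
    payload = json.dumps(to_dict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# applications

@dataclass(frozen=True)
class ApplicationResult:
    """Both decision makers' reports for one scenario configuration."""

    config: ScenarioConfig
    trdm: VOIReport
    brdm: VOIReport


def run_application(config: ScenarioConfig | str) -> ApplicationResult:
    """Run the full analysis (both decision makers) for one scenario."""
    config = load_scenario(config)
    return ApplicationResult(
        config=config,
        trdm=compute_report(config.context("trdm"), config.tests),
        brdm=compute_report(config.context("brdm"), config.tests),
    )


def response_surface(
    config: ScenarioConfig | str,
    decision_maker: str = "trdm",
    durations: Sequence[float] = tuple(range(0, 11)),
    reductions: Sequence[float] = tuple(np.round(np.linspace(0, 1, 11), 10)),
) -> pd.DataFrame:
    """EVDSI over a (testing time x uncertainty reduction) grid.

    ``reductions`` are fractions of the prior toxicity uncertainty removed
    (1 = perfect toxicity information). Returns a long-format frame with
    columns ``duration``, ``reduction``, ``evdsi``.
    """
    config = load_scenario(config)
    ctx = config.context(decision_maker)
    rows = []
    for rho in reductions:
        if not 0 <= rho <= 1:
            raise ConfigError(f"reductions must lie in [0, 1], got {rho!r}")
        width_om = config.prior_tox_om * (1.0 - rho)
        for dur in durations:
            probe = TestSpec(
                name="probe", posterior_width_om=width_om,
                duration_years=float(dur), cost=0.0,
            )
            evdsi = ev_sample_information(ctx, probe, delayed=True).gain
            rows.append((float(dur), float(rho), evdsi))
    return pd.DataFrame(rows, columns=["duration", "reduction", "evdsi"])


_SWEEP_ALIASES = {
    "r": "discount_rate",
    "discount_rate": "discount_rate",
    "CC_max": "acc_max",
    "acc_max": "acc_max",
    "CC_overhead": "acc_fixed",
    "acc_fixed": "acc_fixed",
    "eta": "eta",
    "TRL": "trl",
    "trl": "trl",
    "t_imp": "implement_years",
    "t_TH": "horizon_years",
    "N": "population",
    "V": "valuation",
    "action_k": "action_k",
}


def sensitivity_sweep(
    config: ScenarioConfig | str,
    param: str,
    values: Sequence[float],
) -> pd.DataFrame:
    """Re-run the application across values of one economic/policy parameter.

    Returns a tidy frame: ``param``, ``param_value``, ``decision_maker``,
    ``metric``, ``test``, ``value``.
    """
    config = load_scenario(config)
    fname = _SWEEP_ALIASES.get(param)
    if fname is None:
        raise ConfigError(
            f"unknown sweep parameter {param!r}; choose from {sorted(_SWEEP_ALIASES)}"
        )
    frames = []
    for v in values:
        kwargs = {fname: int(v) if fname == "horizon_years" else float(v)}
        result = run_application(replace(config, **kwargs))
        frame = result_frame(result)
        frame.insert(0, "param", param)
        frame.insert(1, "param_value", v)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# report serialisation

def _report_rows(label: str, report: VOIReport):
    dm = report.decision_maker
    yield (label, dm, "ev_ci", None, report.ev_ci)
    yield (label, dm, "evipi", None, report.evipi)
    yield (label, dm, "evippi", None, report.evippi)
    yield (label, dm, "cod_pi", None, report.cod_pi)
    yield (label, dm, "cod_ppi", None, report.cod_ppi)
    if report.ore_prior is not None:
        yield (label, dm, "ore", None, report.ore_prior)
    for name, m in report.tests.items():
        for metric in ("evisi", "cod", "evdsi", "enbs", "roi"):
            yield (label, dm, metric, name, getattr(m, metric))
    for context, (p1, p0, pu) in report.decision_probs.items():
        yield (label, dm, "p_regulate", context, p1)
        yield (label, dm, "p_no_action", context, p0)
        yield (label, dm, "p_undecided", context, pu)


def result_frame(result: ApplicationResult) -> pd.DataFrame:
    """Long-format metric table: scenario, decision_maker, metric, test, value."""
    rows = []
    for report in (result.trdm, result.brdm):
        rows.extend(_report_rows(result.config.label, report))
    return pd.DataFrame(
        rows, columns=["scenario", "decision_maker", "metric", "test", "value"]
    )


def result_json(result: ApplicationResult) -> dict:
    """Nested JSON mirror of the reports, stamped for reproducibility."""
    return {
        "scenario": result.config.label,
        "config_hash": config_hash(result.config),
        "seed": result.config.rng_seed,
        "settings": {
            "quadrature_nodes": result.config.quadrature_nodes,
            "mc_draws": result.config.mc_draws,
            "impl_year_offset": result.config.impl_year_offset,
        },
        "config": to_dict(result.config),
        "reports": {
            "trdm": asdict(result.trdm),
            "brdm": asdict(result.brdm),
        },
    }


def write_report(
    result: ApplicationResult,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Write the long-format CSV and/or the nested JSON mirror."""
    if csv_path is not None:
        frame = result_frame(result)
        frame.insert(0, "config_hash", config_hash(result.config))
        frame.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(result_json(result), indent=2))
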