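"""The VOI metric ladder: identities, orderings, limits and oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import norm

from toxvoi import (
    MitigationLevel,
    TestSpec,
    UncertaintyState,
    cod_perfect_information,
    compute_report,
    cost_of_delay,
    enbs_roi,
    ev_current_information,
    ev_partial_perfect_information,
    ev_perfect_information,
    ev_sample_information,
    ev_sample_information_mc,
    expected_risk,
    load_scenario,
    om_to_sd,
    total_social_cost,
)

PRESETS = ["fatal-s1", "fatal-s2", "fatal-s3", "acute-s1", "acute-s2", "acute-s3"]
DMS = ["trdm", "brdm"]


@pytest.fixture(scope="module", params=PRESETS)
def config(request):
    return load_scenario(request.param)


@pytest.fixture(scope="module", params=DMS)
def ctx(request, config):
    return config.context(request.param)


class TestLadderStructure:
    def test_partition_identity(self, config, ctx):
        # EVISI decomposes exactly into cost of delay plus EVDSI
        for test in config.tests:
            evisi = ev_sample_information(ctx, test, delayed=False).gain
            evdsi = ev_sample_information(ctx, test, delayed=True).gain
            cod = cost_of_delay(ctx, test)
            assert evisi == pytest.approx(cod + evdsi, rel=1e-9, abs=1e-9)

    def test_information_ordering(self, config, ctx):
        evipi = ev_perfect_information(ctx).gain
        evippi = ev_partial_perfect_information(ctx, ("mu_tox",)).gain
        tol = 1e-7 * max(abs(evipi), 1.0)
        assert evipi >= evippi - tol
        for test in config.tests:
            evisi = ev_sample_information(ctx, test, delayed=False).gain
            evdsi = ev_sample_information(ctx, test, delayed=True).gain
            assert evippi >= evisi - tol
            assert evisi >= -tol
            assert evisi >= evdsi - tol

    def test_trdm_delayed_value_nonnegative_when_prior_undecided(self, config):
        ctx = config.context("trdm")
        report = compute_report(ctx, config.tests)
        assert report.prior_verdict == "undecided"
        for m in report.tests.values():
            assert m.evdsi >= -1e-9

    def test_report_consistency(self, config, ctx):
        report = compute_report(ctx, config.tests)
        for name, m in report.tests.items():
            assert m.evisi == pytest.approx(m.cod + m.evdsi, rel=1e-9, abs=1e-9)
            test = next(t for t in config.tests if t.name == name)
            assert m.enbs == pytest.approx(m.evdsi - test.cost)
            assert m.roi == pytest.approx(m.enbs / test.cost)
        assert report.best_test in report.tests
        triples = report.decision_probs.values()
        assert all(sum(t) == pytest.approx(1.0, abs=1e-9) for t in triples)


class TestLimits:
    def test_no_uncertainty_no_value(self):
        cfg = replace(load_scenario("fatal-s1"), prior_tox_om=0.0)
        for dm in DMS:
            ctx = cfg.context(dm)
            assert ev_perfect_information(ctx).gain == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_instant_test_is_worthless(self, config):
        probe = TestSpec("null", posterior_width_om=config.prior_tox_om,
                         duration_years=0.0, cost=0.0)
        for dm in DMS:
            ctx = config.context(dm)
            assert ev_sample_information(ctx, probe, delayed=True).gain == pytest.approx(
                0.0, abs=1e-6
            )

    def test_zero_duration_removes_the_delay_penalty(self, config):
        probe = TestSpec("fast", posterior_width_om=2.0, duration_years=0.0, cost=1.0)
        for dm in DMS:
            ctx = config.context(dm)
            evisi = ev_sample_information(ctx, probe, delayed=False).gain
            evdsi = ev_sample_information(ctx, probe, delayed=True).gain
            assert evisi == evdsi
            assert cost_of_delay(ctx, probe) == 0.0

    def test_perfect_instant_test_recovers_partial_perfect_information(self, config):
        probe = TestSpec("oracle", posterior_width_om=0.0, duration_years=0.0, cost=0.0)
        for dm in DMS:
            ctx = config.context(dm)
            evdsi = ev_sample_information(ctx, probe, delayed=True).gain
            evippi = ev_partial_perfect_information(ctx, ("mu_tox",)).gain
            assert evdsi == pytest.approx(evippi, rel=1e-9, abs=1e-9)

    def test_full_subset_collapses_to_perfect_information(self, fatal_s3):
        for dm in DMS:
            ctx = fatal_s3.context(dm)
            full = ev_partial_perfect_information(ctx, ("mu_tox", "mu_exp")).gain
            assert full == pytest.approx(ev_perfect_information(ctx).gain, rel=1e-9)

    def test_empty_subset_is_worthless(self, fatal_s1):
        for dm in DMS:
            ctx = fatal_s1.context(dm)
            assert ev_partial_perfect_information(ctx, ()).gain == pytest.approx(
                0.0, abs=1e-6
            )

    def test_residual_exposure_uncertainty_caps_toxicity_information(self, fatal_s3):
        for dm in DMS:
            ctx = fatal_s3.context(dm)
            evippi = ev_partial_perfect_information(ctx, ("mu_tox",)).gain
            assert evippi < ev_perfect_information(ctx).gain


class TestMonotonicity:
    def test_cod_nondecreasing_in_duration(self, fatal_s1):
        for dm in DMS:
            ctx = fatal_s1.context(dm)
            cods = [
                cost_of_delay(
                    ctx, TestSpec("p", posterior_width_om=2.0, duration_years=d, cost=1.0)
                )
                for d in range(0, 11)
            ]
            assert all(a <= b + 1e-9 for a, b in zip(cods, cods[1:]))

    def test_evdsi_monotone_in_reduction_and_duration(self, fatal_s1):
        for dm in DMS:
            ctx = fatal_s1.context(dm)
            widths = [7.0, 5.0, 3.0, 1.0, 0.0]
            along_width = [
                ev_sample_information(
                    ctx, TestSpec("p", posterior_width_om=w, duration_years=2.0, cost=1.0)
                ).gain
                for w in widths
            ]
            assert all(a <= b + 1e-6 for a, b in zip(along_width, along_width[1:]))
            along_duration = [
                ev_sample_information(
                    ctx, TestSpec("p", posterior_width_om=2.0, duration_years=d, cost=1.0)
                ).gain
                for d in (0, 2, 5, 8, 10)
            ]
            assert all(a >= b - 1e-6 for a, b in zip(along_duration, along_duration[1:]))


class TestScenario1Signs:
    def test_slow_test_destroys_value_for_the_benefit_risk_dm(self, fatal_s1, test_b):
        ctx = fatal_s1.context("brdm")
        assert ev_sample_information(ctx, test_b, delayed=True).gain < 0
        enbs, roi = enbs_roi(ctx, test_b)
        assert enbs < 0 and roi < 0

    def test_even_perfect_information_loses_value_after_five_years(self, fatal_s1):
        ctx = fatal_s1.context("brdm")
        evdpi = ev_perfect_information(ctx, delay_years=5.0).gain
        assert evdpi < 0
        assert cod_perfect_information(ctx, 5.0) > ev_perfect_information(ctx).gain

    def test_best_test_by_roi_is_the_fast_one(self, fatal_s1):
        report = compute_report(fatal_s1.context("brdm"), fatal_s1.tests)
        assert report.best_test == "A"
        assert report.tests["A"].roi > report.tests["B"].roi


class TestOracles:
    def test_quadrature_matches_monte_carlo(self, fatal_s1, test_a):
        for dm in DMS:
            ctx = fatal_s1.context(dm)
            quad = ev_sample_information(ctx, test_a, delayed=True).ev_given
            mc, se = ev_sample_information_mc(ctx, test_a, delayed=True, n=10**5, seed=13)
            assert abs(quad - mc) < 3 * se

    def test_brdm_evippi_nested_quadrature_oracle(self, fatal_s3):
        # independent nested integration: outer Gauss-Hermite over the
        # toxicity location, inner closed-form expectation over exposure,
        # per-node grid minimisation through the public cost functions
        cfg = fatal_s3
        params, econ = cfg.risk_params, cfg.econ
        u_tox = om_to_sd(cfg.prior_tox_om)
        u_exp = om_to_sd(cfg.prior_exp_om)
        x, w = np.polynomial.hermite_e.hermegauss(64)
        w = w / w.sum()
        vals = []
        for node in x:
            mt = params.mu_tox + u_tox * node
            state = UncertaintyState({"mu_exp": (params.mu_exp, u_exp)})
            p = type(params)(mt, params.sigma_tox, params.mu_exp, params.sigma_exp)
            r0 = expected_risk(p, state, MitigationLevel(0.0))
            best = min(
                total_social_cost(
                    r0, expected_risk(p, state, MitigationLevel(float(k))),
                    MitigationLevel(float(k)), 0.0, econ,
                ).tsc
                for k in range(101)
            )
            vals.append(best)
        oracle_ev_given = float(np.sum(w * np.asarray(vals)))
        ctx = cfg.context("brdm")
        got = ev_partial_perfect_information(ctx, ("mu_tox",)).ev_given
        assert got == pytest.approx(oracle_ev_given, rel=1e-9)

    def test_trdm_closed_form_matches_quadrature_oracle(self, fatal_s1, test_a):
        # the bivariate-normal expectation must agree with adaptive
        # integration of the preposterior health cost, split at the point
        # where the regulate verdict switches
        from scipy.integrate import quad

        cfg = fatal_s1
        params, econ, policy = cfg.risk_params, cfg.econ, cfg.trdm_policy
        u0 = om_to_sd(cfg.prior_tox_om)
        post = test_a.posterior_sd
        spread = math.sqrt(u0**2 - post**2)
        d_all = sum(1.05 ** -(y - 1) for y in range(1, 21))
        first = int(test_a.duration_years + 2 + 1)
        d_imp = sum(1.05 ** -(y - 1) for y in range(first, 21))
        b = params.combined_sigma
        s_res = math.hypot(b, post)
        # posterior mean above which the 5th risk percentile clears the TRL
        switch = params.mu_exp - b * norm.ppf(policy.trl) - norm.ppf(0.95) * post

        def integrand(c, regulated):
            er = norm.cdf((params.mu_exp - c) / s_res)
            val = econ.value_rate * er * d_all
            if regulated:
                er90 = norm.cdf((params.mu_exp - 1.0 - c) / s_res)
                val -= econ.value_rate * (er - er90) * d_imp
            return val * norm.pdf(c, params.mu_tox, spread)

        lo, hi = params.mu_tox - 12 * spread, params.mu_tox + 12 * spread
        regulate_part, _ = quad(integrand, lo, switch, args=(True,), limit=200)
        stand_down_part, _ = quad(integrand, switch, hi, args=(False,), limit=200)
        oracle = regulate_part + stand_down_part
        got = ev_sample_information(cfg.context("trdm"), test_a, delayed=True).ev_given
        assert got == pytest.approx(oracle, rel=1e-8)


class TestEnbsRoi:
    def test_break_even(self, fatal_s1):
        ctx = fatal_s1.context("brdm")
        probe = TestSpec("be", posterior_width_om=4.0, duration_years=1.0, cost=0.005)
        evdsi = ev_sample_information(ctx, probe, delayed=True).gain
        matched = TestSpec("be", posterior_width_om=4.0, duration_years=1.0, cost=evdsi)
        enbs, roi = enbs_roi(ctx, matched)
        assert enbs == pytest.approx(0.0, abs=1e-9)
        assert roi == pytest.approx(0.0, abs=1e-9)

    def test_zero_cost_roi_undefined_but_enbs_returned(self, fatal_s1):
        ctx = fatal_s1.context("brdm")
        free = TestSpec("free", posterior_width_om=4.0, duration_years=1.0, cost=0.0)
        with pytest.warns(UserWarning):
            enbs, roi = enbs_roi(ctx, free)
        assert math.isnan(roi)
        assert enbs == pytest.approx(ev_sample_information(ctx, free).gain)
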