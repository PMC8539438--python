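"""Trajectories, steady-state detection and the algebraic equilibrium oracles."""

import numpy as np
import pytest

from smskinetics import (
    RateConstants,
    ValidationError,
    build_sms_network,
    equilibrium_closed_form,
    equilibrium_full_network,
    mass_action_ratio,
    simulate,
    steady_state,
)
from smskinetics.simulate import TimeCourse

from conftest import START_25


class TestClosedFormEquilibrium:
    def test_symmetric_identity_at_unit_K(self):
        eq = equilibrium_closed_form(START_25, K=1.0)
        assert eq.lipids == pytest.approx([25, 25, 25, 25], abs=1e-12)

    def test_baseline_K_quadratic_root(self):
        # x + y = 50 with (y/x)^2 = K gives x = 50/(1+sqrt(K))
        K = 0.34965034965034963
        expected_pc = 50 / (1 + np.sqrt(K))
        eq = equilibrium_closed_form(START_25, K)
        assert eq.pc == pytest.approx(expected_pc, abs=1e-10)
        assert eq.pc == pytest.approx(31.4206, abs=1e-3)
        assert eq.sm == pytest.approx(18.5794, abs=1e-3)
        # the root satisfies the mass-action relation it was solved from
        assert (eq.dag * eq.sm) / (eq.pc * eq.cer) == pytest.approx(K, rel=1e-10)

    def test_complete_conversion_limit(self):
        eq = equilibrium_closed_form((50, 50, 0, 0), K=1e12)
        assert eq.dag == pytest.approx(50, abs=1e-3)
        assert eq.pc == pytest.approx(0, abs=1e-3)

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            equilibrium_closed_form((0, 0, 0, 0), K=1.0)

    def test_products_only_start_runs_backwards(self):
        eq = equilibrium_closed_form((0, 0, 30, 30), K=1.0)
        assert eq.pc > 0 and eq.dag < 30


class TestSimulate:
    def test_zero_enzyme_trajectory_is_constant(self, baseline_rc):
        net = build_sms_network(baseline_rc, (30, 20, 10, 40), enzyme_total=0.0)
        tc = simulate(net, t_end=100.0, n_samples=50)
        assert np.allclose(tc.states, tc.states[0], atol=1e-12)

    def test_baseline_relaxes_toward_reactants(self, baseline_net, baseline_rc):
        # K < 1 favours PC and Cer over DAG and SM
        tc = simulate(baseline_net, t_end=2000.0, n_samples=100)
        final = tc.state_at(-1)
        assert final.pc > 25 and final.cer > 25
        assert final.dag < 25 and final.sm < 25
        assert mass_action_ratio(final) == pytest.approx(baseline_rc.K, abs=1e-3)

    def test_long_integration_conserved_and_nonnegative(self, baseline_net):
        tc = simulate(baseline_net, t_end=1e4, n_samples=400)
        assert np.all(tc.states >= -1e-12)
        for members, total in baseline_net.conserved_moieties:
            cols = [tc.column(m) for m in members]
            drift = np.max(np.abs(sum(cols) - total)) / max(abs(total), 1.0)
            assert drift <= 1e-9

    def test_bad_arguments_rejected(self, baseline_net):
        with pytest.raises(ValidationError):
            simulate(baseline_net, t_end=-1.0)
        with pytest.raises(ValidationError):
            simulate(baseline_net, t_end=10.0, n_samples=1)

    def test_timecourse_csv_round_trip(self, baseline_net, tmp_path):
        tc = simulate(baseline_net, t_end=10.0, n_samples=20)
        path = tmp_path / "tc.csv"
        tc.to_csv(path)
        back = TimeCourse.from_csv(path, rc=tc.rc)
        assert np.allclose(back.times, tc.times)
        assert np.allclose(back.states, tc.states)


class TestSteadyState:
    def test_baseline_reaches_published_ratio(self, baseline_net, baseline_rc):
        res = steady_state(baseline_net)
        assert res.converged and res.residual < 1e-10
        assert res.mass_action_ratio == pytest.approx(baseline_rc.K, abs=1e-3)
        # composition matches the full-network oracle exactly; it sits within
        # 0.3 % mol/mol of the lipid-only closed form because the phosphoenzyme
        # sequesters ~0.46 head groups at the default enzyme pool of 1.0
        oracle = equilibrium_full_network(baseline_net)
        assert res.state.to_array() == pytest.approx(oracle.to_array(), abs=1e-6)
        simple = equilibrium_closed_form(START_25, baseline_rc.K)
        assert res.state.lipids == pytest.approx(simple.lipids, abs=0.3)

    def test_unit_constants_keep_symmetric_start(self):
        # K = 1 pins the ratio at 1; the symmetric 25% composition is retained
        # in the trace-enzyme limit (a sizeable pool stores ~0.5 head groups)
        net = build_sms_network(RateConstants(1, 1, 1, 1), START_25,
                                enzyme_total=1e-4)
        res = steady_state(net)
        assert res.mass_action_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.state.lipids == pytest.approx([25, 25, 25, 25], abs=1e-3)

    def test_nonconvergence_reported_honestly(self, baseline_net):
        res = steady_state(baseline_net, tol=1e-300, time_cap=1.0)
        assert not res.converged
        assert res.residual > 0

    def test_random_draws_match_algebraic_oracle(self, rng):
        for _ in range(60):
            rc = RateConstants(*np.exp(rng.uniform(np.log(0.05), np.log(5), 4)))
            lipids = tuple(rng.uniform(1, 40, 4))
            enzyme = float(np.exp(rng.uniform(np.log(0.01), np.log(10))))
            net = build_sms_network(rc, lipids, enzyme)
            res = steady_state(net)
            assert res.converged
            assert res.mass_action_ratio == pytest.approx(rc.K, rel=1e-3)
            oracle = equilibrium_full_network(net)
            assert res.state.to_array() == pytest.approx(oracle.to_array(), abs=1e-4)

    def test_composition_approaches_closed_form_in_trace_enzyme_limit(self, baseline_rc):
        simple = equilibrium_closed_form(START_25, baseline_rc.K)
        deviations = []
        for enzyme in (1.0, 0.1, 0.001):
            net = build_sms_network(baseline_rc, START_25, enzyme)
            eq = equilibrium_full_network(net)
            deviations.append(np.max(np.abs(eq.lipids - simple.lipids)))
        assert deviations[0] > deviations[1] > deviations[2]
        assert deviations[-1] < 1e-3

    def test_steady_state_sm_increasing_in_k2(self, baseline_rc):
        sms = []
        for k2 in (0.5, 1.0, 2.0, 4.0):
            net = build_sms_network(baseline_rc.replace(k2=k2), START_25)
            sms.append(steady_state(net).state.sm)
        assert all(a < b for a, b in zip(sms, sms[1:]))
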