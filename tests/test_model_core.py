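"""Mean-field model: rate laws, equilibria, critical concentration,
observable helpers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssbkin import (
    ParameterSet,
    StateVector,
    apply_force_regime,
    critical_concentration,
    diffusion_length,
    dissociation_Kd,
    effective_rates,
    equilibrate,
    extension_change,
    per_nt_compaction,
    rhs,
)
from ssbkin.model_core import integrate
from dataclasses import replace


class TestParameterSet:
    def test_table1_values(self, table1):
        assert table1.k_b == pytest.approx(0.150)
        assert table1.k_off == pytest.approx(0.0171)
        assert table1.k_w == pytest.approx(1.40)
        assert (table1.n_b, table1.n_w) == (8, 17)

    @pytest.mark.parametrize("bad", [
        dict(k_b=0.0),
        dict(k_off=-1.0),
        dict(n_b=17, n_w=17),
        dict(x_b=0.1, x_w=0.05),
    ])
    def test_invariant_violations_rejected(self, bad):
        kw = dict(k_b=0.15, k_off=0.017, k_w=1.4)
        kw.update(bad)
        with pytest.raises(ValueError):
            ParameterSet(**kw)

    def test_json_round_trip(self, table1, tmp_path):
        from ssbkin import load_parameters, save_parameters
        save_parameters(table1, tmp_path / "p.json")
        assert load_parameters(tmp_path / "p.json") == table1


class TestEffectiveRates:
    def test_intrinsic_rates_at_zero_occupancy(self, table1):
        assert effective_rates(table1, 0.0) == pytest.approx((0.0171, 0.0))

    def test_fully_crowded_rates(self, table1):
        k_off_eff, k_unw_eff = effective_rates(table1, 1.0)
        assert k_off_eff == pytest.approx(0.0171 + 0.113)
        assert k_unw_eff == pytest.approx(0.095)

    def test_out_of_range_occupancy_rejected(self, table1):
        with pytest.raises(ValueError):
            effective_rates(table1, 1.5)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_occupancy(self, a, b):
        p = ParameterSet(k_b=0.15, k_off=0.017, k_w=1.4,
                         k_off_stim=0.113, k_unw_stim=0.095)
        lo, hi = sorted((a, b))
        assert effective_rates(p, hi)[0] >= effective_rates(p, lo)[0]
        assert effective_rates(p, hi)[1] >= effective_rates(p, lo)[1]


class TestRhs:
    def test_initial_fill_rate_matches_calibrated_on_rate(self, table1):
        # fractional lattice-filling rate at 1 nM equals k_b (0.150 s^-1)
        db, dw = rhs(StateVector.empty(table1), 1.0, table1)
        fill_rate = table1.n_w * (db + dw)
        assert fill_rate == pytest.approx(0.150, rel=1e-9)

    def test_nothing_happens_without_protein(self, table1):
        assert rhs(StateVector.empty(table1), 0.0, table1) == (0.0, 0.0)

    def test_negative_density_rejected(self, table1):
        with pytest.raises(ValueError):
            StateVector(-0.01, 0.0)
        with pytest.raises(ValueError):
            rhs(StateVector.empty(table1), -1.0, table1)

    def test_derivatives_vanish_at_equilibrium(self, table1):
        s = equilibrate(3.4, table1)
        db, dw = rhs(s, 3.4, table1)
        assert abs(db) < 1e-9 and abs(dw) < 1e-9


class TestEquilibrate:
    def test_states_balanced_near_critical_concentration(self, table1):
        s = equilibrate(3.4, table1)
        assert s.theta_b == pytest.approx(s.theta_w, rel=0.05)

    def test_low_concentration_fully_wrapped(self, table1):
        s = equilibrate(0.05, table1)
        assert s.theta_w > 10 * max(s.theta_b, 1e-6)
        assert extension_change(s, table1) == pytest.approx(table1.x_w, rel=0.05)

    def test_occupancies_conserve_and_stay_in_range(self, table1):
        for c in (0.05, 1.0, 3.4, 50.0):
            s = equilibrate(c, table1)
            assert s.theta_0 + s.theta_b + s.theta_w == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= s.theta_b <= 1.0 and 0.0 <= s.theta_w <= 1.0

    @pytest.mark.parametrize("c", [2.0, 3.4, 10.0, 50.0])
    def test_start_independent_above_escape_concentration(self, table1, c):
        a = equilibrate(c, table1, start="empty")
        b = equilibrate(c, table1, start="packed")
        assert abs(a.theta_b - b.theta_b) < 1e-6
        assert abs(a.theta_w - b.theta_w) < 1e-6

    def test_rinse_from_loaded_state_reaches_packed_wrap(self, table1):
        loaded = equilibrate(50.0, table1)
        s = equilibrate(0.0, table1, start=loaded)
        assert s.theta_w > 0.9
        assert s.beta == pytest.approx(0.0, abs=1e-6)

    def test_equilibrium_occupancies_monotone_in_concentration(self, table1):
        cs = [0.05, 0.5, 2.0, 3.4, 10.0, 50.0, 100.0]
        states = [equilibrate(c, table1) for c in cs]
        tb = [s.theta_b for s in states]
        tw = [s.theta_w for s in states]
        assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(tb, tb[1:]))
        assert all(w2 <= w1 + 1e-9 for w1, w2 in zip(tw, tw[1:]))


class TestCriticalConcentration:
    def test_requires_wrapping(self, table1):
        with pytest.raises(ValueError):
            critical_concentration(table1.without_wrapping())

    def test_ablating_stimulation_stabilises_wrapping(self, table1):
        # without stimulated unwrapping the wrapped state survives to higher
        # concentration, so the crossover moves up
        base = critical_concentration(table1)
        ablated = replace(table1, k_off_stim=0.0, k_unw_stim=0.0,
                          k_unw=0.01)  # small intrinsic unwrapping keeps a crossover
        assert critical_concentration(ablated) > base

    def test_faster_binding_lowers_crossover(self, table1):
        base = critical_concentration(table1)
        assert critical_concentration(replace(table1, k_b=2 * table1.k_b)) < base


class TestObservables:
    def test_compaction_of_pure_states(self, table1):
        wrapped = StateVector(0.0, 1.0 / table1.n_w)
        bound = StateVector(1.0 / table1.n_b, 0.0)
        assert extension_change(wrapped, table1) == pytest.approx(0.083)
        assert extension_change(bound, table1) == pytest.approx(0.0159)
        assert extension_change(StateVector.empty(table1), table1) == 0.0

    def test_per_protein_to_per_nt_conversions(self):
        assert per_nt_compaction(2.0, 17) == pytest.approx(0.118, abs=5e-4)
        assert per_nt_compaction(5.0, 35) == pytest.approx(0.143, abs=5e-4)
        assert per_nt_compaction(0.0, 17) == 0.0
        with pytest.raises(ValueError):
            per_nt_compaction(2.0, 0)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(1e-3, 10), st.floats(1e-3, 10), st.floats(0.1, 10))
    def test_Kd_is_scale_invariant_ratio(self, k_off, k_on, scale):
        kd = dissociation_Kd(k_off, k_on)
        assert dissociation_Kd(scale * k_off, scale * k_on) == pytest.approx(kd)

    def test_single_domain_affinity(self):
        assert dissociation_Kd(0.017, 0.18) == pytest.approx(0.094, abs=1e-3)
        assert dissociation_Kd(0.0, 0.5) == 0.0

    def test_diffusion_length_scaling(self):
        assert diffusion_length(300.0, 10.0) == pytest.approx(54.77, abs=0.01)
        assert diffusion_length(0.0, 10.0) == 0.0
        assert diffusion_length(300.0, 40.0) == pytest.approx(2 * diffusion_length(300.0, 10.0))


class TestForceRegimes:
    def test_seven_pN_widens_wrapped_footprint(self, table1):
        p7 = apply_force_regime(table1, 7.0)
        assert p7.n_w == 35
        assert p7.x_w == pytest.approx(5.0 / 35.0)

    def test_twelve_pN_keeps_calibrated_compaction(self, table1):
        assert apply_force_regime(table1, 12.0).x_w == pytest.approx(0.083)

    @pytest.mark.parametrize("force", [20.0, 60.0])
    def test_high_force_disables_wrapping_and_stimulation(self, table1, force):
        p = apply_force_regime(table1, force)
        assert not p.wrapping_enabled
        assert p.k_off_stim == 0.0 and p.k_unw_stim == 0.0
        assert p.k_unw > 0.1  # destabilised wrap unwinds quickly

    def test_uncalibrated_force_rejected(self, table1):
        with pytest.raises(KeyError):
            apply_force_regime(table1, 9.0)


class TestTrajectoryInvariants:
    def test_occupancies_bounded_along_trajectory(self, table1):
        sol = integrate(table1, 50.0, (0.0, 300.0))
        t = np.linspace(0, 300, 1500)
        beta, omega = sol.sol(t)
        theta_b = table1.n_b * beta
        theta_w = table1.n_w * omega
        assert beta.min() > -1e-9 and omega.min() > -1e-9
        assert (theta_b + theta_w).max() < 1 + 1e-9
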