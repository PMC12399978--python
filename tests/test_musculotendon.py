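import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synemg.musculotendon import (CurveConstants, MusculotendonParams,
                                  active_force_length, contractile_force,
                                  fiber_velocity, passive_force_length,
                                  pennation_cos, solve_equilibrium,
                                  tendon_force, tendon_strain)

C = CurveConstants()


class TestActiveForceLength:
    def test_peak_at_optimum(self):
        assert active_force_length(1.0) == 1.0

    def test_symmetry_about_optimum(self):
        assert active_force_length(0.8) == pytest.approx(active_force_length(1.2))

    def test_value_at_1p6(self):
        assert active_force_length(1.6, gamma=0.6) == pytest.approx(np.exp(-0.6))


class TestPassiveForceLength:
    def test_zero_at_optimum_and_below(self):
        assert passive_force_length(1.0) == 0.0
        assert passive_force_length(0.7) == 0.0  # clamped, no compression

    def test_unity_at_full_passive_strain(self):
        assert passive_force_length(1.0 + C.eps0M) == pytest.approx(1.0)

    def test_value_at_1p3(self):
        expected = (np.exp(2.5) - 1) / (np.exp(5) - 1)
        assert passive_force_length(1.3) == pytest.approx(expected, abs=1e-9)


class TestForceVelocity:
    def test_isometric_force_is_a_fl(self):
        assert contractile_force(0.7, 0.9, 0.0) == pytest.approx(0.7 * 0.9)

    def test_shortening_branch_example(self):
        # a=1, fl=1, FCE=0.5: b = 1 + 0.5/0.3, VM = 10*(0.5-1)/b = -1.875
        vm = fiber_velocity(1.0, 1.0, 0.5)
        assert vm == pytest.approx(-1.875)
        assert contractile_force(1.0, 1.0, vm) == pytest.approx(0.5)

    def test_lengthening_saturates_at_flen(self):
        f = contractile_force(1.0, 1.0, 1e9)
        assert f == pytest.approx(C.FlenM, rel=1e-6)

    def test_branch_continuity_at_isometric(self):
        below = contractile_force(0.5, 1.0, -1e-12)
        above = contractile_force(0.5, 1.0, +1e-12)
        assert abs(below - above) <= 1e-9

    def test_inverse_domain_error(self):
        with pytest.raises(ValueError, match="asymptote"):
            fiber_velocity(1.0, 1.0, 1.9)

    @settings(deadline=None, max_examples=60)
    @given(a=st.floats(0.05, 1.0), fl=st.floats(0.2, 1.0),
           frac=st.floats(0.01, 0.99))
    def test_forward_inverse_round_trip(self, a, fl, frac):
        fce = frac * a * fl * C.FlenM
        vm = fiber_velocity(a, fl, fce)
        assert contractile_force(a, fl, vm) == pytest.approx(fce, abs=1e-9)


class TestTendon:
    def test_slack_carries_no_force(self):
        assert tendon_force(1.0) == 0.0
        assert tendon_force(0.9) == 0.0

    def test_strain_at_toe_transition(self):
        assert tendon_strain(0.33) == pytest.approx(0.609 * 0.04, abs=1e-12)

    def test_strain_at_max_isometric_force(self):
        # confirms strain at F0m is the nominal tendon strain 0.04
        assert tendon_strain(1.0) == pytest.approx(0.04, abs=5e-4)

    def test_branch_continuity_at_toe(self):
        lt = 1.0 + C.epstoe
        assert tendon_force(lt - 1e-12) == pytest.approx(tendon_force(lt + 1e-12), abs=1e-9)

    def test_force_strain_round_trip(self):
        for f in (0.05, 0.2, 0.33, 0.6, 1.0):
            assert tendon_force(1.0 + tendon_strain(f)) == pytest.approx(f, rel=1e-9)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            tendon_strain(-0.1)


class TestPennation:
    P = MusculotendonParams(F0m=100, l0m=0.1, lst=0.2, alpha0=0.2)

    def test_zero_angle_gives_unity(self):
        p = MusculotendonParams(F0m=100, l0m=0.1, lst=0.2, alpha0=0.0)
        assert pennation_cos(0.05, p) == 1.0
        assert pennation_cos(0.2, p) == 1.0

    def test_angle_at_optimal_length(self):
        assert pennation_cos(0.1, self.P) == pytest.approx(np.cos(0.2))

    def test_constant_thickness_relation(self):
        lm = 1.25 * self.P.l0m
        sin_pen = np.sin(0.2) / 1.25
        assert pennation_cos(lm, self.P) == pytest.approx(np.sqrt(1 - sin_pen**2))


class TestEquilibrium:
    P = MusculotendonParams(F0m=1000.0, l0m=0.10, lst=0.20, alpha0=0.0)

    def test_slack_and_passive_free_gives_zero_force(self):
        lmt = np.full(5, self.P.lst + self.P.l0m)
        st_ = solve_equilibrium(np.zeros(5), lmt, self.P, dt=0.01)
        assert np.all(np.abs(st_.fmt) <= 1e-3)

    def test_full_activation_fixed_point_is_f0m(self):
        lmt = np.full(10, 1.04 * self.P.lst + self.P.l0m)
        st_ = solve_equilibrium(np.ones(10), lmt, self.P, dt=0.01)
        assert np.allclose(st_.fmt, self.P.F0m, rtol=1e-4)
        assert np.allclose(st_.lm_bar, 1.0, atol=1e-4)

    def test_length_bookkeeping(self):
        rng = np.random.default_rng(0)
        n = 50
        a = 0.3 + 0.3 * np.sin(np.linspace(0, 3, n)) ** 2
        lmt = self.P.lst + self.P.l0m * (1.0 + 0.1 * np.sin(np.linspace(0, 2, n)))
        st_ = solve_equilibrium(a, lmt, self.P, dt=0.01)
        assert np.allclose(lmt, st_.lt + st_.lm * st_.cos_pen, atol=1e-9)
        # force balance at every non-flagged frame
        bal = st_.ft_bar - (st_.fce_bar + st_.fpe_bar) * st_.cos_pen
        assert np.all(np.abs(bal[~st_.flagged]) <= 1e-6)

    def test_matches_rigid_tendon_oracle_for_stiff_tendon(self):
        # with tendon strain at F0m pushed to 1e-4 the tendon is nearly rigid:
        # lm = lmt - lst, velocity by backward difference, forces closed-form
        consts = CurveConstants(eps0T=1e-4)
        p = MusculotendonParams(F0m=500.0, l0m=0.10, lst=0.20, alpha0=0.0,
                                constants=consts)
        n, dt = 80, 0.012
        t = np.linspace(0, 1, n)
        a = 0.4 + 0.3 * np.sin(2 * np.pi * t) ** 2
        lmt = p.lst + p.l0m * (1.0 + 0.12 * np.sin(2 * np.pi * t + 0.4))
        st_ = solve_equilibrium(a, lmt, p, dt=dt)

        lm_r = lmt - p.lst
        vm_r = np.zeros(n)
        vm_r[1:] = np.diff(lm_r) / dt / p.l0m
        fl_r = active_force_length(lm_r / p.l0m)
        fce_r = contractile_force(a, fl_r, vm_r, consts)
        fpe_r = passive_force_length(lm_r / p.l0m)
        fmt_r = (fce_r + fpe_r) * p.F0m
        assert np.allclose(st_.fmt, fmt_r, rtol=0.01, atol=0.5)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            solve_equilibrium(np.array([1.5]), np.array([0.3]), self.P, 0.01)
        with pytest.raises(ValueError):
            solve_equilibrium(np.array([0.5]), np.array([-0.3]), self.P, 0.01)
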