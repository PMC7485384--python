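"""Hill-type muscle model: curves, dynamics, roster and force balance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import standreflex as sr
from standreflex import _engine
from standreflex.muscles import (MUSCLE_ORDER, MuscleParams, MusclePath,
                                 MuscleState, activation_dynamics,
                                 contraction_dynamics, default_muscles,
                                 joint_moments_from_muscles, load_default_csv,
                                 musculotendon_length, see_force)


@pytest.fixture(scope="module")
def sol(muscles):
    i = muscles.index("soleus")
    return muscles.params[i], muscles.paths[i]


class TestRoster:
    def test_nine_muscles_per_leg(self, muscles):
        assert len(muscles) == 9
        assert [p.name for p in muscles.params] == MUSCLE_ORDER

    def test_added_muscle_defaults(self, muscles):
        """Rectus femoris and biceps femoris SH carry their published values."""
        rf = muscles.params[muscles.index("rectus_femoris")]
        assert rf.l_opt == pytest.approx(0.081)
        assert rf.f_max == pytest.approx(1200.0)
        assert rf.l_slack == pytest.approx(0.35)
        assert rf.pennation == pytest.approx(0.5)
        bf = muscles.params[muscles.index("biceps_femoris_sh")]
        assert bf.l_opt == pytest.approx(0.12)
        assert bf.f_max == pytest.approx(1200.0)
        assert bf.l_slack == pytest.approx(0.10)
        assert bf.pennation == pytest.approx(0.7)

    def test_tibialis_anterior_strengthened(self, muscles):
        ta = muscles.params[muscles.index("tibialis_anterior")]
        assert ta.f_max == pytest.approx(4000.0)

    def test_csv_round_trip(self, muscles, tmp_path):
        path = tmp_path / "muscles.csv"
        muscles.save_csv(path)
        again = sr.MuscleSet.load_csv(path)
        assert np.allclose(again.f_max, muscles.f_max)
        assert np.allclose(again.arms, muscles.arms)

    def test_shipped_csv_matches_defaults(self, muscles):
        shipped = load_default_csv()
        assert np.allclose(shipped.f_max, muscles.f_max)
        assert np.allclose(shipped.l_ref, muscles.l_ref)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MuscleParams("x", -1.0, 0.1, 0.2, 0.5)
        with pytest.raises(ValueError):
            MuscleParams("x", 100.0, 0.1, 0.2, 1.5)
        with pytest.raises(ValueError):
            MusclePath((0.0, 0.0, 0.0), 0.3)


class TestGeometry:
    def test_reference_posture_length(self, muscles):
        for p, pa in zip(muscles.params, muscles.paths):
            l = musculotendon_length(pa, (0.0, 0.0, 0.0))
            assert l == pytest.approx(p.ce_ref * p.l_opt + p.l_slack)

    def test_plantarflexion_shortens_soleus(self, sol):
        _, path = sol
        l0 = musculotendon_length(path, (0, 0, 0.0))
        l1 = musculotendon_length(path, (0, 0, -0.2))   # plantarflexion
        assert l1 < l0

    def test_gastrocnemius_is_biarticular(self, muscles):
        path = muscles.paths[muscles.index("gastrocnemius")]
        assert set(path.spanned_joints) == {"knee", "ankle"}
        l0 = musculotendon_length(path, (0, 0, 0))
        assert musculotendon_length(path, (0, 0.2, 0)) != l0
        assert musculotendon_length(path, (0, 0, 0.2)) != l0

    def test_monotone_in_each_spanned_joint(self, muscles):
        angles = np.linspace(-0.8, 0.8, 41)
        for pa in muscles.paths:
            for j, arm in enumerate(pa.arms):
                if arm == 0.0:
                    continue
                phi = np.zeros((41, 3))
                phi[:, j] = angles
                ls = [musculotendon_length(pa, a) for a in phi]
                d = np.diff(ls)
                assert np.all(d < 0) or np.all(d > 0)


class TestSeries:
    def test_slack_gives_zero(self, sol):
        p, _ = sol
        assert see_force(p.l_slack, p) == 0.0
        assert see_force(0.5 * p.l_slack, p) == 0.0

    def test_reference_strain_gives_fmax(self, sol):
        p, _ = sol
        F = see_force(p.l_slack * (1 + p.see_ref_strain), p)
        assert F == pytest.approx(p.f_max, rel=1e-12)

    def test_quadratic_toe_region(self, sol):
        p, _ = sol
        for frac in (0.25, 0.5, 0.8):
            l = p.l_slack * (1 + frac * p.see_ref_strain)
            assert see_force(l, p) == pytest.approx(p.f_max * frac ** 2,
                                                    rel=1e-12)

    def test_strictly_increasing_beyond_slack(self, sol):
        p, _ = sol
        ls = p.l_slack * (1 + np.linspace(0.001, 0.1, 50))
        fs = [see_force(l, p) for l in ls]
        assert np.all(np.diff(fs) > 0)


class TestContraction:
    def test_isometric_equilibrium_at_optimal_length(self, sol):
        """At a=1, l_CE=l_opt, the CE holds F_max (f_l = f_v = 1)."""
        p, _ = sol
        # SEE length whose force matches pennation-projected F_max
        fsee_n = p.pennation * 1.0
        strain = np.sqrt(fsee_n) * p.see_ref_strain
        l_mtu = p.l_opt + p.l_slack * (1 + strain)
        v, clipped = contraction_dynamics(MuscleState(p.l_opt, 1.0), 1.0,
                                          l_mtu, p)
        assert not clipped
        assert v == pytest.approx(0.0, abs=1e-6)

    def test_passive_when_inactive_and_slack(self, sol):
        p, _ = sol
        st = MuscleState(0.9 * p.l_opt, 0.0)
        l_mtu = st.l_ce + 0.5 * p.l_slack   # SEE fully slack
        v, clipped = contraction_dynamics(st, 0.0, l_mtu, p)
        assert v <= 0.0  # nothing pulls the CE out

    def test_eccentric_force_exceeds_isometric(self, sol):
        """Equilibrium force during imposed stretch exceeds isometric force."""
        p, _ = sol
        a = 0.5
        # isometric equilibrium force at this activation
        st = MuscleState(p.l_opt, a)
        fiso = a * p.f_max
        # imposed lengthening: solve force balance at positive CE velocity
        f_len = p.pennation * a * p.f_max * _engine.force_velocity(0.5, 5.0, 1.5)
        assert f_len > p.pennation * fiso

    def test_force_balance_residual_small(self, muscles, rng):
        """Accepted CE velocities satisfy the balance to < 1e-6 F_max."""
        for _ in range(200):
            i = rng.integers(0, 9)
            p = muscles.params[i]
            lce = p.l_opt * rng.uniform(0.6, 1.3)
            a = rng.uniform(0.01, 1.0)
            lmtu = lce + p.l_slack * rng.uniform(0.98, 1.05)
            fsee_n = _engine.see_force_norm(lmtu - lce, p.l_slack,
                                            p.see_ref_strain)
            nu, clipped = _engine.solve_ce_velocity(
                a, lce, fsee_n, p.pennation, p.l_opt, p.fl_width,
                p.fv_curvature, p.fv_ecc, p.damping)
            if clipped:
                continue
            fl = _engine.force_length(lce, p.l_opt, p.fl_width)
            resid = p.pennation * (
                a * fl * _engine.force_velocity(nu, p.fv_curvature, p.fv_ecc)
                + _engine.pe_force_norm(lce, p.l_opt, p.fl_width)
                + p.damping * nu
                - _engine.be_force_norm(lce, p.l_opt, p.fl_width)) - fsee_n
            assert abs(resid) < 1e-6


class TestActivation:
    def test_fixed_point(self, sol):
        p, _ = sol
        assert activation_dynamics(0.4, 0.4, 0.001, p) == pytest.approx(0.4)

    def test_step_response_time_constant(self, sol):
        """A 0->1 step reaches 63% of the gap in one rise time constant."""
        p, _ = sol
        a, dt = 0.0, 0.0005
        for _ in range(int(round(p.tau_act / dt))):
            a = activation_dynamics(a, 1.0, dt, p)
        assert a == pytest.approx(1 - np.exp(-1), abs=1e-3)

    def test_input_clamped(self, sol):
        p, _ = sol
        assert activation_dynamics(0.5, 1.7, 1.0, p) <= 1.0
        assert activation_dynamics(0.5, -2.0, 1.0, p) >= 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-0.5, 1.5), min_size=1, max_size=60))
    def test_activation_stays_in_unit_interval(self, us):
        p = MuscleParams("toy", 1000.0, 0.1, 0.2, 0.7)
        a = 0.3
        for u in us:
            a = activation_dynamics(a, u, 0.01, p)
            assert 0.0 <= a <= 1.0

    def test_distinct_rise_and_fall(self, sol):
        p, _ = sol
        up = activation_dynamics(0.5, 1.0, 0.01, p) - 0.5
        down = 0.5 - activation_dynamics(0.5, 0.0, 0.01, p)
        assert up > down  # activation is faster than deactivation


class TestMoments:
    def test_zero_forces_zero_moments(self, muscles):
        assert np.allclose(joint_moments_from_muscles(muscles, np.zeros(9)),
                           0.0)

    def test_single_muscle_product(self, muscles):
        f = np.zeros(9)
        i = muscles.index("soleus")
        f[i] = 100.0
        m = joint_moments_from_muscles(muscles, f)
        assert m[2] == pytest.approx(100.0 * muscles.arms[i, 2])
        assert m[0] == m[1] == 0.0

    def test_antagonists_cancel(self, muscles):
        f = np.zeros(9)
        isol, ita = muscles.index("soleus"), muscles.index("tibialis_anterior")
        rs, rt = muscles.arms[isol, 2], muscles.arms[ita, 2]
        f[isol], f[ita] = 100.0, -100.0 * rs / rt
        assert joint_moments_from_muscles(muscles, f)[2] == pytest.approx(0.0)
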