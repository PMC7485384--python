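"""Reflex controller: dead-zone gain, delays, feedback laws, presets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import standreflex as sr
from standreflex.controller import (ARCHITECTURES, Architecture, DeadZone,
                                    DelayedChannel, ReflexParams,
                                    DEFAULT_DELAYS, controller_step,
                                    delay_steps, effective_gain,
                                    force_feedback, length_feedback,
                                    load_preset, stimulation)
from standreflex.muscles import MUSCLE_ORDER

HEEL_X, TOE_X = -0.07, 0.21


def oracle_gain(x, G, dz, heel=HEEL_X, toe=TOE_X):
    """Independent piecewise evaluation of the dead-zone gain law."""
    bh = heel + dz.x_heel
    bt = toe - dz.x_toe
    wh = dz.z_heel * dz.x_heel
    wt = dz.z_toe * dz.x_toe
    if x < bh - wh:
        return -G
    if x < bh:
        return -G * (bh - x) / wh
    if x <= bt:
        return 0.0
    if x <= bt + wt:
        return G * (x - bt) / wt
    return G


class TestDeadZone:
    def test_gain_matches_oracle_on_dense_grid(self):
        dz = DeadZone(0.06, 0.03, 0.4, 0.7)
        for G in (1.5, -0.8):
            for x in np.linspace(-0.2, 0.35, 1000):
                assert effective_gain(x, dz, G, HEEL_X, TOE_X) == \
                    pytest.approx(oracle_gain(x, G, dz), abs=1e-12)

    def test_zero_at_midpoint(self):
        dz = DeadZone(0.05, 0.05, 0.5, 0.5)
        mid = 0.5 * ((HEEL_X + 0.05) + (TOE_X - 0.05))
        assert effective_gain(mid, dz, 2.0, HEEL_X, TOE_X) == 0.0

    def test_half_gain_at_transition_midpoint(self):
        dz = DeadZone(0.05, 0.04, 0.5, 0.6)
        bt = TOE_X - dz.x_toe
        x = bt + 0.5 * dz.z_toe * dz.x_toe
        assert effective_gain(x, dz, 2.0, HEEL_X, TOE_X) == \
            pytest.approx(1.0, rel=1e-12)

    def test_continuity(self):
        dz = DeadZone(0.08, 0.02, 0.3, 0.9)
        xs = np.linspace(-0.25, 0.4, 5000)
        g = np.array([effective_gain(x, dz, 3.0, HEEL_X, TOE_X) for x in xs])
        assert np.max(np.abs(np.diff(g))) < 3.0 * (xs[1] - xs[0]) / \
            min(dz.z_heel * dz.x_heel, dz.z_toe * dz.x_toe) * 1.01

    def test_empty_zone_rejected(self):
        dz = DeadZone(0.10, 0.10, 0.5, 0.5)
        with pytest.raises(ValueError, match="empty"):
            dz.edges(0.0, 0.15)  # heel edge would pass the toe edge

    def test_parameter_bounds(self):
        with pytest.raises(ValueError):
            DeadZone(0.2, 0.05, 0.5, 0.5)
        with pytest.raises(ValueError):
            DeadZone(0.05, 0.05, 1.5, 0.5)

    @settings(derandomize=True, max_examples=200)
    @given(hst.floats(-0.3, 0.5))
    def test_magnitude_bounded_by_gain(self, x):
        dz = DeadZone(0.07, 0.04, 0.5, 0.5)
        g = effective_gain(x, dz, 2.5, HEEL_X, TOE_X)
        assert abs(g) <= 2.5 + 1e-12


class TestDelays:
    def test_default_table(self):
        expect = {"tibialis_anterior": 35, "soleus": 44, "gastrocnemius": 54,
                  "vastus": 100, "biceps_femoris_sh": 60,
                  "biceps_femoris_lh": 60, "rectus_femoris": 82,
                  "gluteals": 40, "iliopsoas": 40}
        for name, ms in expect.items():
            assert DEFAULT_DELAYS[name] == pytest.approx(ms / 1000.0)

    def test_delay_must_be_multiple_of_dt(self):
        with pytest.raises(ValueError, match="multiple"):
            delay_steps(DEFAULT_DELAYS, 0.003)
        steps = delay_steps(DEFAULT_DELAYS, 0.001)
        assert steps[MUSCLE_ORDER.index("soleus")] == 44

    def test_zero_delay_is_identity(self):
        ch = DelayedChannel(0.0, 0.001)
        for v in (1.0, 2.0, -3.0):
            ch.push(v)
            assert ch.read() == v

    def test_constant_input_passes_through(self):
        ch = DelayedChannel(0.02, 0.001, initial=5.0)
        for _ in range(100):
            ch.push(5.0)
        assert ch.read() == 5.0

    def test_unit_pulse_appears_after_exact_lag(self):
        """A pulse at step k is read back exactly 44 steps later (soleus lag)."""
        lag = 44
        ch = DelayedChannel(0.044, 0.001)
        reads = []
        for k in range(200):
            ch.push(1.0 if k == 60 else 0.0)
            reads.append(ch.read())
        assert reads[60 + lag] == 1.0
        assert sum(reads) == 1.0

    def test_initial_value_before_history_fills(self):
        ch = DelayedChannel(0.01, 0.001, initial=7.0)
        assert ch.read() == 7.0
        for _ in range(9):
            ch.push(1.0)
            assert ch.read() == 7.0   # one full delay has not elapsed
        ch.push(1.0)
        ch.push(1.0)
        assert ch.read() == 1.0

    def test_exact_lag_and_no_lookahead(self):
        """read() after k pushes equals the input from exactly 'steps' ago."""
        steps = 5
        ch = DelayedChannel(0.005, 0.001, initial=-1.0)
        seq = np.arange(30, dtype=float)
        for k, v in enumerate(seq):
            ch.push(v)
            expect = seq[k - steps] if k - steps >= 0 else -1.0
            assert ch.read() == expect


class TestFeedbackLaws:
    def test_force_feedback_linear(self):
        assert force_feedback(0.4, 0.0) == 0.0
        assert force_feedback(0.4, 1.5) == pytest.approx(0.6)
        # published force-model tibialis gain
        assert force_feedback(0.2, -1.45) == pytest.approx(-0.29)

    def test_force_feedback_rejects_negative_force(self):
        with pytest.raises(ValueError):
            force_feedback(-0.1, 1.0)

    def test_length_feedback_threshold(self):
        assert length_feedback(0.50, 0.50, 2.0) == 0.0
        assert length_feedback(0.45, 0.50, 2.0) == 0.0       # below offset
        # published length-model soleus values
        assert length_feedback(0.6, 0.50, 1.15) == pytest.approx(0.115)

    def test_length_feedback_zero_below_offset_any_gain(self):
        for g in (-3.0, -0.1, 0.5, 3.0):
            assert length_feedback(0.3, 0.9, g) == 0.0

    def test_stimulation_clamps(self):
        assert stimulation(0.26, 0.0, 0.0) == pytest.approx(0.26)
        assert stimulation(0.26, 1.2, 0.0) == 1.0
        assert stimulation(0.062, -0.5, 0.0) == 0.001


class TestControllerStep:
    def _params(self):
        return load_preset("base")

    def test_inside_dead_zone_pure_feedforward(self):
        p = self._params()
        f = np.full(9, 0.3)
        l = np.full(9, 1.0)
        mid = 0.5 * ((HEEL_X + p.dead_zone.x_heel) + (TOE_X - p.dead_zone.x_toe))
        u = controller_step(p, Architecture("base"), mid, HEEL_X, TOE_X, f, l)
        assert np.allclose(u, np.clip(p.u0, 0.001, 1.0))

    def test_length_only_ignores_force_gains(self):
        p = self._params()
        f = np.full(9, 0.5)
        l = np.full(9, 1.05)
        x = TOE_X  # far outside the zone
        u1 = controller_step(p, Architecture("length_only"), x, HEEL_X, TOE_X,
                             f, l)
        p2 = ReflexParams(p.u0, -p.g_ffb, p.g_lfb, p.l_off, p.dead_zone)
        u2 = controller_step(p2, Architecture("length_only"), x, HEEL_X, TOE_X,
                             f, l)
        assert np.allclose(u1, u2)

    def test_force_only_ignores_length_gains(self):
        p = self._params()
        f = np.full(9, 0.5)
        l = np.full(9, 1.05)
        u1 = controller_step(p, Architecture("force_only"), TOE_X, HEEL_X,
                             TOE_X, f, l)
        p2 = ReflexParams(p.u0, p.g_ffb, -p.g_lfb, p.l_off, p.dead_zone)
        u2 = controller_step(p2, Architecture("force_only"), TOE_X, HEEL_X,
                             TOE_X, f, l)
        assert np.allclose(u1, u2)

    def test_outputs_always_clamped(self, rng):
        p = self._params()
        for _ in range(50):
            f = rng.uniform(0, 1.5, 9)
            l = rng.uniform(0.3, 1.4, 9)
            x = rng.uniform(-0.3, 0.4)
            u = controller_step(p, Architecture("base"), x, HEEL_X, TOE_X,
                                f, l)
            assert np.all(u >= 0.001) and np.all(u <= 1.0)


class TestPresets:
    @pytest.mark.parametrize("name,arch", [
        ("base", "base"), ("length_feedback", "length_only"),
        ("force_feedback", "force_only"),
        ("tuned_base", "base"), ("tuned_length_feedback", "length_only"),
        ("tuned_force_feedback", "force_only")])
    def test_presets_load_and_respect_bounds(self, name, arch):
        p = load_preset(name)
        assert np.all(p.u0 >= 0.001) and np.all(p.u0 <= 1.0)
        assert np.all(np.abs(p.g_ffb) <= 3.0)
        assert np.all(np.abs(p.g_lfb) <= 3.0)
        assert np.all((p.l_off >= 0.2) & (p.l_off <= 1.1))
        assert arch in ARCHITECTURES

    def test_published_base_values(self):
        """Spot-check the published optimized base-model parameters."""
        p = load_preset("base")
        i_sol = MUSCLE_ORDER.index("soleus")
        i_ta = MUSCLE_ORDER.index("tibialis_anterior")
        assert p.g_ffb[i_sol] == pytest.approx(1.50)
        assert p.g_ffb[i_ta] == pytest.approx(-1.11)
        assert p.u0[i_sol] == pytest.approx(0.26)
        assert p.dead_zone.x_heel == pytest.approx(0.0574)
        assert p.dead_zone.z_toe == pytest.approx(0.71)

    def test_csv_round_trip(self, tmp_path):
        p = load_preset("base")
        path = tmp_path / "params.csv"
        p.save_csv(path)
        q = ReflexParams.load_csv(path)
        assert np.allclose(q.u0, p.u0)
        assert np.allclose(q.g_lfb, p.g_lfb)
        assert q.dead_zone == p.dead_zone

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            load_preset("nope")

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            ReflexParams(np.zeros(9), np.zeros(9), np.zeros(9),
                         np.full(9, 0.5), DeadZone(0.05, 0.05, 0.5, 0.5))
        with pytest.raises(ValueError):
            ReflexParams(np.full(9, 0.1), np.full(9, 4.0), np.zeros(9),
                         np.full(9, 0.5), DeadZone(0.05, 0.05, 0.5, 0.5))
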