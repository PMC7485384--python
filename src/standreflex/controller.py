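"""Delayed proprioceptive reflex controller gated by a COM dead zone.

Every muscle receives a stimulation built from three components:

* a constant feedforward input ``u0`` that maintains quiet stance,
* Golgi-tendon-organ force feedback  u_FFB = g_eff * F_SEE(t - dt)/F_max,
* muscle-spindle length feedback     u_LFB = g_eff * (l_CE(t - dt)/l_opt
  - l_off)  applied only while the delayed normalized CE length exceeds the
  offset ``l_off``,

summed and clamped to [0.001, 1].  Sensor signals are normalized (force by
F_max, length by l_opt) so that gains of order one produce stimulations of
order one; the offset bounds (0.2-1.1) live on the same normalized scale.

The effective gain g_eff is the muscle's gain scaled by a signed factor that
depends on where the whole-body COM sits inside the base of support: zero
inside the dead zone, ramping linearly to -G towards the heel edge and +G
towards the toe edge (equal and opposite by construction), saturated beyond
the transition bands.  Feedback is therefore intermittent: inside the dead
zone only the feedforward drive acts.

Time delays are per muscle (reflex-loop latencies measured between muscle
stimulus and EMG response): tibialis anterior 35 ms, soleus 44, gastrocnemius
54, vastus 100, both biceps femoris heads 60, rectus femoris 82, and 40 ms
for the hip muscles.  Delays must be integer multiples of the integration
step so delayed reads are exact.  The COM signal itself is instantaneous by
default, with an optional configurable delay (e.g. 20 or 100 ms) for
sensing-latency variants.  Left and right legs share identical parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .muscles import MUSCLE_ORDER

ARCHITECTURES = ("base", "length_only", "force_only")

#: default reflex-loop delays, seconds
DEFAULT_DELAYS = {
    "iliopsoas": 0.040,
    "gluteals": 0.040,
    "rectus_femoris": 0.082,
    "biceps_femoris_lh": 0.060,
    "biceps_femoris_sh": 0.060,
    "vastus": 0.100,
    "gastrocnemius": 0.054,
    "soleus": 0.044,
    "tibialis_anterior": 0.035,
}

U_MIN = 0.001
U_MAX = 1.0


@dataclass(frozen=True)
class DeadZone:
    """COM dead-zone geometry (distances inward from heel/toe contacts)."""

    x_heel: float          # m, dead-zone edge distance from the heel contact
    x_toe: float           # m, from the toe contact
    z_heel: float          # transition fraction on the heel side
    z_toe: float           # transition fraction on the toe side

    def __post_init__(self):
        if not (0.0 <= self.x_heel <= 0.10 and 0.0 <= self.x_toe <= 0.10):
            raise ValueError("x_heel and x_toe must lie in [0, 0.10] m")
        if not (0.0 <= self.z_heel <= 1.0 and 0.0 <= self.z_toe <= 1.0):
            raise ValueError("transition fractions must lie in [0, 1]")

    def edges(self, heel_contact_x: float, toe_contact_x: float):
        """(b_heel, b_toe, width_heel, width_toe) in the platform frame."""
        bh = heel_contact_x + self.x_heel
        bt = toe_contact_x - self.x_toe
        if bh >= bt:
            raise ValueError(
                f"dead zone is empty: heel edge {bh:.3f} >= toe edge {bt:.3f}")
        return bh, bt, self.z_heel * self.x_heel, self.z_toe * self.x_toe


@dataclass
class ReflexParams:
    """Per-muscle reflex constants plus the dead zone (the optimization vector)."""

    u0: np.ndarray         # (9,) feedforward inputs
    g_ffb: np.ndarray      # (9,) force feedback gains
    g_lfb: np.ndarray      # (9,) length feedback gains
    l_off: np.ndarray      # (9,) length offsets, units of l_opt
    dead_zone: DeadZone

    def __post_init__(self):
        for name in ("u0", "g_ffb", "g_lfb", "l_off"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (len(MUSCLE_ORDER),):
                raise ValueError(f"{name} must have 9 entries")
        if np.any(self.u0 < U_MIN) or np.any(self.u0 > U_MAX):
            raise ValueError(f"u0 must lie in [{U_MIN}, {U_MAX}]")
        if np.any(np.abs(self.g_ffb) > 3.0) or np.any(np.abs(self.g_lfb) > 3.0):
            raise ValueError("feedback gains must lie in [-3, 3]")
        if np.any(self.l_off < 0.2) or np.any(self.l_off > 1.1):
            raise ValueError("l_off must lie in [0.2, 1.1]")

    def gated(self, architecture: str) -> "ReflexParams":
        """Copy with the gains zeroed according to the architecture."""
        if architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {architecture!r}")
        g_ffb = self.g_ffb.copy()
        g_lfb = self.g_lfb.copy()
        if architecture == "length_only":
            g_ffb[:] = 0.0
        elif architecture == "force_only":
            g_lfb[:] = 0.0
        return ReflexParams(self.u0.copy(), g_ffb, g_lfb, self.l_off.copy(),
                            self.dead_zone)

    # -- CSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [[n, self.u0[i], self.g_ffb[i], self.g_lfb[i], self.l_off[i],
                 np.nan] for i, n in enumerate(MUSCLE_ORDER)]
        dz = self.dead_zone
        for key, val in [("x_heel", dz.x_heel), ("x_toe", dz.x_toe),
                         ("z_heel", dz.z_heel), ("z_toe", dz.z_toe)]:
            rows.append([key, np.nan, np.nan, np.nan, np.nan, val])
        return pd.DataFrame(rows, columns=["name", "u0", "g_ffb", "g_lfb",
                                           "l_off", "value"])

    def save_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReflexParams":
        df = df.set_index("name")
        missing = [m for m in MUSCLE_ORDER if m not in df.index]
        if missing:
            raise ValueError(f"parameter file missing muscles: {missing}")
        mus = df.loc[MUSCLE_ORDER]
        dz = DeadZone(float(df.loc["x_heel", "value"]),
                      float(df.loc["x_toe", "value"]),
                      float(df.loc["z_heel", "value"]),
                      float(df.loc["z_toe", "value"]))
        return cls(mus["u0"].to_numpy(float), mus["g_ffb"].to_numpy(float),
                   mus["g_lfb"].to_numpy(float), mus["l_off"].to_numpy(float),
                   dz)

    @classmethod
    def load_csv(cls, path) -> "ReflexParams":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class Architecture:
    """Controller variant plus optional COM sensing delay."""

    kind: str = "base"                 # base | length_only | force_only
    com_delay: float = 0.0             # s, delay on the COM trigger signal

    def __post_init__(self):
        if self.kind not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.com_delay < 0:
            raise ValueError("com_delay must be >= 0")


class DelayedChannel:
    """Fixed-step ring buffer returning exactly dt-lagged samples.

    Reads before one full delay has elapsed return the initial value.
    """

    def __init__(self, delay: float, dt: float, initial: float = 0.0):
        steps = delay / dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"delay {delay} s is not an integer multiple of dt {dt} s")
        self.steps = int(round(steps))
        self.dt = dt
        self._initial = float(initial)
        self._buf = [self._initial] * (self.steps + 1)
        self._n = 0

    def push(self, value: float):
        self._buf[self._n % len(self._buf)] = float(value)
        self._n += 1

    def read(self) -> float:
        """Value recorded ``delay`` seconds before the most recent push.

        Until one full delay of history exists, the initial value is
        returned (the sensor had that value for all t <= 0).
        """
        i = self._n - 1 - self.steps
        if i < 0:
            return self._initial
        return self._buf[i % len(self._buf)]


# ---------------------------------------------------------------------------
# control-law operations
# ---------------------------------------------------------------------------

def effective_gain(x_com: float, dead_zone: DeadZone, gain: float,
                   heel_contact_x: float, toe_contact_x: float) -> float:
    """Signed, COM-gated gain: continuous piecewise-linear in x_com.

    ``x_com`` and the contact coordinates are expressed in the platform
    frame.  Returns -gain fully beyond the heel-side band, 0 inside the dead
    zone, +gain fully beyond the toe-side band, with linear ramps of widths
    z_heel*x_heel and z_toe*x_toe in between.
    """
    bh, bt, wh, wt = dead_zone.edges(heel_contact_x, toe_contact_x)
    from ._engine import deadzone_scale
    return gain * deadzone_scale(x_com, bh, bt, wh, wt)


def force_feedback(f_hat_delayed: float, g_eff: float) -> float:
    """Stimulation from delayed normalized SEE force."""
    if f_hat_delayed < 0:
        raise ValueError("normalized force must be >= 0")
    return g_eff * f_hat_delayed


def length_feedback(l_hat_delayed: float, l_off: float, g_eff: float) -> float:
    """Stimulation from delayed normalized CE length above the offset."""
    if l_hat_delayed <= 0:
        raise ValueError("normalized length must be > 0")
    if l_hat_delayed > l_off:
        return g_eff * (l_hat_delayed - l_off)
    return 0.0


def stimulation(u0: float, u_ffb: float, u_lfb: float) -> float:
    """Total stimulation, clamped to [0.001, 1]."""
    return float(np.clip(u0 + u_ffb + u_lfb, U_MIN, U_MAX))


def controller_step(params: ReflexParams, architecture: Architecture,
                    x_com: float, heel_contact_x: float, toe_contact_x: float,
                    f_hat_delayed: np.ndarray, l_hat_delayed: np.ndarray) -> np.ndarray:
    """Stimulations for the 9 muscles of one leg (the other leg is identical).

    ``f_hat_delayed`` / ``l_hat_delayed`` are the delayed normalized sensor
    values per muscle; ``x_com`` is the (optionally delayed) COM x in the
    platform frame.
    """
    p = params.gated(architecture.kind)
    dz = p.dead_zone
    bh, bt, wh, wt = dz.edges(heel_contact_x, toe_contact_x)
    from ._engine import deadzone_scale
    s = deadzone_scale(x_com, bh, bt, wh, wt)
    out = np.empty(len(MUSCLE_ORDER))
    for m in range(len(MUSCLE_ORDER)):
        u_ffb = force_feedback(f_hat_delayed[m], s * p.g_ffb[m])
        u_lfb = length_feedback(l_hat_delayed[m], p.l_off[m], s * p.g_lfb[m])
        out[m] = stimulation(p.u0[m], u_ffb, u_lfb)
    return out


# ---------------------------------------------------------------------------
# delay table and shipped presets
# ---------------------------------------------------------------------------

def delay_steps(delays: dict, dt: float) -> np.ndarray:
    """Per-muscle delays in integration steps (exact multiples enforced)."""
    out = np.empty(len(MUSCLE_ORDER), dtype=np.int64)
    for i, name in enumerate(MUSCLE_ORDER):
        d = delays[name]
        steps = d / dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"delay of {name} ({d} s) is not a multiple of dt={dt} s")
        out[i] = int(round(steps))
    return out


def load_delays_csv(path) -> dict:
    df = pd.read_csv(path)
    return {r["muscle"]: float(r["delay_ms"]) / 1000.0
            for _, r in df.iterrows()}


def save_delays_csv(delays: dict, path):
    pd.DataFrame({"muscle": list(delays),
                  "delay_ms": [1000.0 * delays[m] for m in delays]}
                 ).to_csv(path, index=False)


_PRESET_FILES = {
    "base": "preset_base.csv",
    "length_feedback": "preset_length_feedback.csv",
    "force_feedback": "preset_force_feedback.csv",
    "tuned_base": "preset_tuned_base.csv",
    "tuned_length_feedback": "preset_tuned_length_feedback.csv",
    "tuned_force_feedback": "preset_tuned_force_feedback.csv",
}

#: preset name -> architecture kind
PRESET_ARCHITECTURE = {
    "base": "base",
    "length_feedback": "length_only",
    "force_feedback": "force_only",
    "tuned_base": "base",
    "tuned_length_feedback": "length_only",
    "tuned_force_feedback": "force_only",
}


def load_preset(name: str) -> ReflexParams:
    """Shipped controller presets.

    ``base``, ``length_feedback`` and ``force_feedback`` are the published
    optimized parameter sets; the ``tuned_*`` variants are re-optimized for
    this package's default anthropometry and are the recommended starting
    point for simulations and warm starts.
    """
    if name not in _PRESET_FILES:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESET_FILES)}")
    with resources.files("standreflex.data").joinpath(_PRESET_FILES[name]).open() as f:
        return ReflexParams.from_frame(pd.read_csv(f))
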