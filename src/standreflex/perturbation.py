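"""Random square-pulse platform displacement signals.

The platform is perturbed with a sequence of square pulses whose amplitudes
are drawn i.i.d. uniformly from {-5, -2.5, 0, 2.5, 5} cm and whose durations
from {0.25, 0.5, 0.75, 1.0, 1.25, 1.5} s.  In the default ("absolute") mode
the platform position equals the pulse amplitude for the pulse's duration;
an alternate "incremental" mode treats each amplitude as a step added to the
previous position.  Pulse edges are rate-limited (default 1 m/s) when the
signal is sampled, so the kinematically driven platform always has finite
velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMPLITUDES = np.array([-0.05, -0.025, 0.0, 0.025, 0.05])   # m
DURATIONS = np.array([0.25, 0.5, 0.75, 1.0, 1.25, 1.5])    # s
DEFAULT_RATE_LIMIT = 1.0                                   # m/s
DEFAULT_ACCEL_LIMIT = 5.0                                  # m/s^2


@dataclass
class PerturbationSignal:
    """Piecewise-constant platform position target."""

    times: np.ndarray       # (n+1,) pulse boundary times, starting at 0
    positions: np.ndarray   # (n,) target position during each pulse, m
    seed: int | None = None
    rate_limit: float = DEFAULT_RATE_LIMIT
    accel_limit: float = DEFAULT_ACCEL_LIMIT

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions) + 1:
            raise ValueError("times must have one more entry than positions")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("pulse boundary times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def position_at(self, t) -> np.ndarray | float:
        """Rate-limited platform position at time(s) t in [0, duration]."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0) or np.any(t_arr > self.duration + 1e-12):
            raise ValueError("t outside the signal's time span")
        # right-continuous piecewise-constant target
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        idx = np.clip(idx, 0, len(self.positions) - 1)
        target = self.positions[idx]
        if not np.isfinite(self.rate_limit) or self.rate_limit <= 0:
            out = target
        else:
            # ramp from the previous pulse's value at each boundary
            prev = np.empty_like(target)
            prev[...] = np.where(idx > 0, self.positions[np.maximum(idx - 1, 0)], 0.0)
            dt_in = t_arr - self.times[idx]
            ramp = prev + np.sign(target - prev) * self.rate_limit * dt_in
            out = np.where(np.abs(ramp - prev) >= np.abs(target - prev),
                           target, ramp)
        return out if np.ndim(t) else float(out[0])

    def sampled(self, dt: float, total: float | None = None):
        """(positions, velocities) on a fixed grid, velocity+acceleration
        limited.

        The kinematically driven platform must have finite velocity *and*
        acceleration; the profile is a standard trapezoidal approach to the
        piecewise-constant target (speed capped at ``rate_limit``, slew at
        ``accel_limit``, with stopping-distance anticipation so the platform
        does not overshoot the target).
        """
        total = self.duration if total is None else min(total, self.duration)
        n = int(round(total / dt))
        t = np.arange(n) * dt
        target = self.position_at_target(t)
        pos = np.empty(n)
        vel = np.empty(n)
        p = 0.0
        v = 0.0
        vmax = self.rate_limit if self.rate_limit > 0 else np.inf
        amax = self.accel_limit if self.accel_limit > 0 else np.inf
        for i in range(n):
            d = target[i] - p
            if np.isfinite(amax):
                v_des = np.sign(d) * min(vmax, np.sqrt(2.0 * amax * abs(d)))
                dv = v_des - v
                lim = amax * dt
                if dv > lim:
                    dv = lim
                elif dv < -lim:
                    dv = -lim
                v += dv
                step = v * dt
                if abs(step) > abs(d) and d * step > 0:
                    step = d
                    v = 0.0
            else:
                step = np.clip(d, -vmax * dt, vmax * dt)
                v = step / dt
            p += step
            pos[i] = p
            vel[i] = v
        return pos, vel

    def position_at_target(self, t) -> np.ndarray:
        """Un-smoothed piecewise-constant target (right-continuous)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        idx = np.clip(idx, 0, len(self.positions) - 1)
        return self.positions[idx]


def generate_signal(seed: int, total_duration: float,
                    mode: str = "absolute",
                    rate_limit: float = DEFAULT_RATE_LIMIT) -> PerturbationSignal:
    """Draw a random square-pulse signal covering ``total_duration`` seconds."""
    if total_duration <= 0:
        raise ValueError("total_duration must be > 0")
    if mode not in ("absolute", "incremental"):
        raise ValueError("mode must be 'absolute' or 'incremental'")
    rng = np.random.default_rng(seed)
    times = [0.0]
    positions = []
    level = 0.0
    while times[-1] < total_duration:
        amp = rng.choice(AMPLITUDES)
        dur = rng.choice(DURATIONS)
        if mode == "absolute":
            level = amp
        else:
            level = float(np.clip(level + amp, AMPLITUDES[0], AMPLITUDES[-1]))
        positions.append(level)
        times.append(times[-1] + dur)
    return PerturbationSignal(np.array(times), np.array(positions),
                              seed=seed, rate_limit=rate_limit)


def save_signal_csv(signal: PerturbationSignal, path, dt: float = 0.01):
    """Write the signal as a two-column time/position CSV (target values)."""
    n = int(round(signal.duration / dt))
    t = np.arange(n + 1) * dt
    t[-1] = min(t[-1], signal.duration)
    pos = signal.position_at_target(t)
    pd.DataFrame({"time_s": t, "position_m": pos}).to_csv(path, index=False)


def load_signal_csv(path, start: float = 0.0, length: float | None = None,
                    rate_limit: float = DEFAULT_RATE_LIMIT) -> PerturbationSignal:
    """Load a time/position CSV, optionally extracting a sub-signal.

    ``start``/``length`` select a window (seconds) of the recorded trace,
    e.g. the published sample offsets 53.73, 17.57, 97.20 or 44.55 s.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty signal file")
    if not {"time_s", "position_m"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,position_m")
    t = df["time_s"].to_numpy(float)
    x = df["position_m"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    if start > 0 or length is not None:
        t_end = t[-1] if length is None else start + length
        if start < t[0] - 1e-9 or t_end > t[-1] + 1e-9:
            raise ValueError("requested window outside the recorded span")
        mask = (t >= start - 1e-12) & (t <= t_end + 1e-12)
        t, x = t[mask] - start, x[mask]
    # each sample becomes a pulse lasting until the next sample
    times = np.append(t, t[-1] + (t[-1] - t[-2] if len(t) > 1 else 0.01))
    return PerturbationSignal(times - times[0], x, rate_limit=rate_limit)
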