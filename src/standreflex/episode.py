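"""One full perturbed-standing episode: protocol, scoring, trajectory output.

Protocol (simulated times):

* phase 1, 0-1 s: joint-angle PD control toward a slightly flexed nominal
  stance while the muscles settle toward their feedforward equilibrium;
* phase 2, 1-2 s: muscle control only, platform still (quiet stance);
* phase 3, from 2 s: the platform follows the perturbation signal until the
  episode reaches ``t_total`` (default 110 s).

The episode stops early if the chest point drops below 0.7 m (a fall).  The
evaluation horizon T (default 100 s) starts at perturbation onset, i.e. it
maps to simulated time [2, 2+T].  Over that horizon the episode accumulates

* effort  f(z) = (1/T) * integral of sum_i a_i(t)^2 dt  over all 18 muscles,
* the mean absolute ankle excursion in the platform frame, relative to the
  ankle position at onset.

Scoring uses three constraints: survived duration (past onset) > 100 s,
final chest height > 1.3 m, and mean ankle excursion < 0.05 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine, plant as plant_mod
from .controller import (Architecture, ReflexParams, DEFAULT_DELAYS,
                         delay_steps)
from .muscles import MuscleSet, MUSCLE_ORDER
from .perturbation import PerturbationSignal
from .plant import PlantModel, TRAJECTORY_COLUMNS

CONSTRAINT_DURATION = 100.0      # s, past perturbation onset
CONSTRAINT_CHEST = 1.3           # m at final time
CONSTRAINT_ANKLE = 0.05          # m mean absolute excursion


@dataclass
class EpisodeConfig:
    t_pd: float = 1.0            # s of joint-angle PD control
    t_quiet: float = 1.0         # s of unperturbed muscle control
    t_total: float = 110.0       # s full episode length
    horizon: float = 100.0       # s evaluation horizon from perturbation onset
    dt: float = 0.001            # s integration step
    chest_fall: float = 0.7      # m early-stop threshold
    log_rate: float = 100.0      # Hz trajectory sampling
    presettle: float = 10.0      # s of PD-held relaxation before the episode
                                 # proper, so phase 1 starts at equilibrium
    # joint PD gains (hip, knee, ankle); ankle stiffness must exceed the
    # gravitational gradient m*g*h_com (~850 N m/rad) so the PD statue does
    # not pivot over its ankles, while ankle damping stays small because the
    # foot is light and explicit damping would destabilize the fixed step
    pd_kp: tuple = (600.0, 900.0, 1500.0)   # N m/rad
    pd_kd: tuple = (30.0, 30.0, 5.0)        # N m s/rad
    # calibrated quiet-stance pose for the default model: knee rests in its
    # extension stop and the settled COM sits ~4 cm ahead of the ankles
    nominal_pose: tuple = (0.0033, -0.0053, -0.0062)  # hip, knee, ankle (rad)

    def __post_init__(self):
        if self.t_pd + self.t_quiet >= self.t_total:
            raise ValueError("t_pd + t_quiet must be < t_total")
        if self.horizon > self.t_total - self.t_pd:
            raise ValueError("evaluation horizon does not fit in the episode")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class EpisodeResult:
    survived: float              # s past perturbation onset (capped at horizon end)
    survived_sim_time: float     # s of simulated time reached
    fell: bool
    effort: float                # f(z)
    mean_ankle_excursion: float  # m
    final_chest_height: float    # m
    trajectory: pd.DataFrame
    activations: np.ndarray      # (n_log, 9) leg-averaged
    config: EpisodeConfig
    n_velocity_clips: int = 0
    failed: bool = False         # integration blow-up

    @property
    def feasible(self) -> bool:
        ok, _ = constraint_values(self)
        return ok

    def save_trajectory_csv(self, path):
        self.trajectory.to_csv(path, index=False)


def effort(activations: np.ndarray, times: np.ndarray,
           horizon: float | None = None) -> float:
    """Time-averaged summed squared activation, trapezoid quadrature.

    ``activations`` is (n, n_muscles); the average runs over [t0, t0+horizon]
    of the supplied time base.
    """
    a = np.asarray(activations, dtype=float)
    t = np.asarray(times, dtype=float)
    if horizon is not None:
        mask = t <= t[0] + horizon + 1e-12
        a, t = a[mask], t[mask]
    if len(t) < 2:
        return 0.0
    ssq = np.sum(a * a, axis=1)
    return float(np.trapezoid(ssq, t) / (t[-1] - t[0]))


def constraint_values(result: EpisodeResult):
    """(all_ok, dict of value/limit/ok per constraint)."""
    vals = {
        "duration": {"value": result.survived, "limit": CONSTRAINT_DURATION,
                     "ok": result.survived > CONSTRAINT_DURATION},
        "chest_height": {"value": result.final_chest_height,
                         "limit": CONSTRAINT_CHEST,
                         "ok": result.final_chest_height > CONSTRAINT_CHEST},
        "ankle_excursion": {"value": result.mean_ankle_excursion,
                            "limit": CONSTRAINT_ANKLE,
                            "ok": result.mean_ankle_excursion < CONSTRAINT_ANKLE},
    }
    return all(v["ok"] for v in vals.values()), vals


def run_episode(model: PlantModel, muscles: MuscleSet, params: ReflexParams,
                architecture: Architecture, signal: PerturbationSignal | None,
                config: EpisodeConfig | None = None,
                delays: dict | None = None) -> EpisodeResult:
    """Simulate one episode and score it.

    ``signal`` may be None for a fully quiet (zero-perturbation) episode.
    """
    cfg = config or EpisodeConfig()
    dt = cfg.dt
    n_steps = int(round(cfg.t_total / dt))
    n_pd = int(round(cfg.t_pd / dt))
    n_quiet = int(round(cfg.t_quiet / dt))
    n_horizon = int(round(cfg.horizon / dt))
    log_every = max(1, int(round(1.0 / (cfg.log_rate * dt))))

    dly = delay_steps(delays or DEFAULT_DELAYS, dt)
    com_dly = int(round(architecture.com_delay / dt))
    if abs(architecture.com_delay / dt - com_dly) > 1e-9:
        raise ValueError("com_delay must be an integer multiple of dt")

    p = params.gated(architecture.kind)
    dz = p.dead_zone

    # platform trajectory on the integration grid (zero before onset)
    plat_pos = np.zeros(n_steps)
    plat_vel = np.zeros(n_steps)
    onset = n_pd + n_quiet
    if signal is not None:
        need = (n_steps - onset) * dt
        if signal.duration < need - 1e-9:
            raise ValueError(
                f"signal ({signal.duration} s) shorter than the perturbation "
                f"phase ({need} s)")
        pos, vel = signal.sampled(dt, total=need)
        plat_pos[onset:onset + len(pos)] = pos
        plat_vel[onset:onset + len(vel)] = vel

    # preload the contact springs with the body weight so the episode does
    # not start with a drop-and-rock transient
    preload = model.total_mass * plant_mod.GRAVITY / (4 * model.contact.stiffness)
    state0 = plant_mod.upright_state(model, cfg.nominal_pose, settle=preload)
    q_ref = state0.q.copy()
    lce0 = np.vstack([muscles.initial_states(cfg.nominal_pose)] * 2)
    act0 = np.vstack([np.clip(p.u0, 0.001, 1.0)] * 2)
    kp6 = np.array(cfg.pd_kp * 2, dtype=float)
    kd6 = np.array(cfg.pd_kd * 2, dtype=float)

    q0, qd0 = state0.q, state0.qdot
    if cfg.presettle > 0:
        n_pre = int(round(cfg.presettle / dt))
        pre = _engine.run_episode_core(
            q0, qd0, lce0, act0,
            *model.engine_args(), model.total_mass,
            *muscles.engine_args(),
            p.u0, p.g_ffb, p.g_lfb, p.l_off, dly,
            dz.x_heel, dz.x_toe, dz.z_heel, dz.z_toe, com_dly,
            dt, n_pre, n_pre, 1, 1, kp6, kd6, q_ref,
            np.zeros(n_pre), np.zeros(n_pre), cfg.chest_fall, n_pre)
        q0, qd0, lce0, act0 = pre[-4], pre[-3], pre[-2], pre[-1]

    out = _engine.run_episode_core(
        q0, qd0, lce0, act0,
        *model.engine_args(), model.total_mass,
        *muscles.engine_args(),
        p.u0, p.g_ffb, p.g_lfb, p.l_off, dly,
        dz.x_heel, dz.x_toe, dz.z_heel, dz.z_toe, com_dly,
        dt, n_steps, n_pd, n_quiet, n_horizon, kp6, kd6, q_ref,
        plat_pos, plat_vel, cfg.chest_fall, log_every)

    (t, ang, mom, com, chest, ankx, grfy, act_log, platx, trunk,
     survived_sim, fell, effort_sum, exc_sum, final_chest, nclip,
     edges_ok, q, qd, lce, act) = out
    if edges_ok != 1:
        raise ValueError("dead zone is empty for this stance geometry")

    onset_t = cfg.t_pd + cfg.t_quiet
    lived = max(0.0, survived_sim - onset_t)
    # normalize accumulated integrals by the horizon actually defined
    eff = effort_sum / cfg.horizon
    exc = exc_sum / cfg.horizon

    traj = pd.DataFrame({
        "time": t,
        "trunk_x": trunk[:, 0], "trunk_y": trunk[:, 1],
        "trunk_pitch": np.degrees(trunk[:, 2]),
        "hip": np.degrees(ang[:, 0]),
        "knee": np.degrees(ang[:, 1]),
        "ankle": np.degrees(ang[:, 2]),
        "com_x": com[:, 0], "com_y": com[:, 1],
        "chest_y": chest, "ankle_x": ankx, "grf_y": grfy,
    })[TRAJECTORY_COLUMNS]
    traj["hip_moment"] = mom[:, 0]
    traj["knee_moment"] = mom[:, 1]
    traj["ankle_moment"] = mom[:, 2]
    traj["platform_x"] = platx

    return EpisodeResult(
        survived=lived,
        survived_sim_time=survived_sim,
        fell=bool(fell == 1),
        effort=eff,
        mean_ankle_excursion=exc,
        final_chest_height=final_chest,
        trajectory=traj,
        activations=act_log,
        config=cfg,
        n_velocity_clips=int(nclip),
        failed=bool(fell == 2),
    )


def sim_table(result: EpisodeResult, from_onset: bool = True) -> pd.DataFrame:
    """Episode trajectory in the evaluation CSV dialect.

    Columns time_s, hip_deg, knee_deg, ankle_deg, hip_Nm, knee_Nm, ankle_Nm;
    time restarts at zero at perturbation onset when ``from_onset``.
    """
    tr = result.trajectory
    t = tr["time"].to_numpy()
    if from_onset:
        t0 = result.config.t_pd + result.config.t_quiet
        mask = t >= t0 - 1e-9
    else:
        t0 = 0.0
        mask = np.ones(len(t), dtype=bool)
    return pd.DataFrame({
        "time_s": t[mask] - t0,
        "hip_deg": tr["hip"].to_numpy()[mask],
        "knee_deg": tr["knee"].to_numpy()[mask],
        "ankle_deg": tr["ankle"].to_numpy()[mask],
        "hip_Nm": tr["hip_moment"].to_numpy()[mask],
        "knee_Nm": tr["knee_moment"].to_numpy()[mask],
        "ankle_Nm": tr["ankle_moment"].to_numpy()[mask],
    })
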