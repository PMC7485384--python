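"""Four-element Hill-type muscles (9 per leg) and their joint geometry.

Each muscle has a contractile element (CE) with activation, force-length and
force-velocity dependence, a series elastic element (SEE, the tendon) with a
quadratic toe region, a parallel elastic element with damping, and a buffer
element that props the CE up at very short lengths.  Forces are transmitted
to the skeleton through constant moment arms: the musculotendon length is

    l_MTU = l_ref - sum_j r_j * (phi_j - phi_ref_j)

with r_j the signed moment arm at joint j (flexion/dorsiflexion-positive
convention) and the reference posture the upright stance (phi_ref = 0), at
which the CE sits at its optimal length and the SEE at slack.  Muscle joint
moments are F_SEE * r_j.

The roster covers all mono- and bi-articular muscles of the leg: iliopsoas,
gluteals, rectus femoris, biceps femoris long and short head, vastus,
gastrocnemius, soleus and tibialis anterior.  The curve shapes follow the
reflex-controlled walking literature; attachment geometry is a documented
default table and every number can be overridden through the muscle CSV.
The tibialis anterior maximum isometric force is raised to 4000 N so the
dorsiflexor can withstand platform perturbations (its activation stays low,
so realized forces remain physiological).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import _engine

MUSCLE_ORDER = [
    "iliopsoas", "gluteals", "rectus_femoris", "biceps_femoris_lh",
    "biceps_femoris_sh", "vastus", "gastrocnemius", "soleus",
    "tibialis_anterior",
]
JOINT_NAMES = ["hip", "knee", "ankle"]

CSV_COLUMNS = ["name", "f_max", "l_opt", "l_slack", "pennation", "v_max",
               "see_ref_strain", "tau_act", "tau_deact", "fl_width",
               "fv_curvature", "fv_ecc", "damping", "ce_ref",
               "arm_hip", "arm_knee", "arm_ankle"]


@dataclass(frozen=True)
class MuscleParams:
    """Constants of one muscle (lengths m, forces N, times s)."""

    name: str
    f_max: float
    l_opt: float
    l_slack: float
    pennation: float          # scalar projection factor, not an angle
    v_max: float = 12.0       # maximum shortening velocity, l_opt/s
    see_ref_strain: float = 0.04
    tau_act: float = 0.01
    tau_deact: float = 0.04
    fl_width: float = 0.56
    fv_curvature: float = 5.0
    fv_ecc: float = 1.5       # eccentric force plateau / F_max
    damping: float = 0.1      # normalized CE damping
    ce_ref: float = 0.8       # CE length / l_opt in the upright reference:
                              # stance sits on the ascending force-length
                              # limb, whose slope (through the taut tendon)
                              # supplies tonic postural joint stiffness

    def __post_init__(self):
        if self.f_max <= 0 or self.l_opt <= 0:
            raise ValueError(f"{self.name}: f_max and l_opt must be > 0")
        if self.l_slack < 0:
            raise ValueError(f"{self.name}: l_slack must be >= 0")
        if not 0 < self.pennation <= 1:
            raise ValueError(f"{self.name}: pennation must be in (0, 1]")


@dataclass(frozen=True)
class MusclePath:
    """Joint routing: signed constant moment arms and resting MTU length."""

    arms: tuple            # (hip, knee, ankle) moment arms, m; 0 = not spanned
    l_ref: float           # MTU length in the upright reference posture

    def __post_init__(self):
        if not any(a != 0.0 for a in self.arms):
            raise ValueError("muscle must span at least one joint")
        if not all(np.isfinite(a) for a in self.arms):
            raise ValueError("moment arms must be finite")

    @property
    def spanned_joints(self) -> list[str]:
        return [JOINT_NAMES[j] for j, a in enumerate(self.arms) if a != 0.0]


@dataclass
class MuscleState:
    l_ce: float
    activation: float

    def __post_init__(self):
        if self.l_ce <= 0 or not 0 <= self.activation <= 1:
            raise ValueError("require l_ce > 0 and activation in [0, 1]")


# default roster: (f_max, l_opt, l_slack, pennation, v_max, arms)
# Rectus femoris and biceps femoris short head carry their published
# defaults (l_opt 8.1/12 cm, F_max 1200 N, l_slack 35/10 cm, pennation
# 0.5/0.7); tibialis anterior F_max is raised to 4000 N.
_DEFAULT_TABLE = {
    # iliopsoas/gluteals lump all uni-articular hip flexors/extensors, so
    # they carry group-level maximal forces (the trunk they steer weighs
    # ~54 kg and hip strategy needs realistic hip torque reserves)
    "iliopsoas":          (2500.0, 0.11, 0.10, 0.5, 12.0, (0.08, 0.0, 0.0)),
    "gluteals":           (3000.0, 0.11, 0.13, 0.5, 12.0, (-0.08, 0.0, 0.0)),
    "rectus_femoris":     (1200.0, 0.081, 0.35, 0.5, 12.0, (0.05, -0.05, 0.0)),
    "biceps_femoris_lh":  (3000.0, 0.10, 0.31, 0.7, 12.0, (-0.08, 0.05, 0.0)),
    "biceps_femoris_sh":  (1200.0, 0.12, 0.10, 0.7, 12.0, (0.0, 0.04, 0.0)),
    "vastus":             (6000.0, 0.08, 0.23, 0.6, 12.0, (0.0, -0.06, 0.0)),
    "gastrocnemius":      (1500.0, 0.05, 0.40, 0.7, 12.0, (0.0, 0.05, -0.05)),
    "soleus":             (4000.0, 0.04, 0.26, 0.5, 6.0, (0.0, 0.0, -0.05)),
    "tibialis_anterior":  (4000.0, 0.06, 0.24, 0.7, 12.0, (0.0, 0.0, 0.04)),
}


class MuscleSet:
    """Ordered collection of 9 muscles with flattened engine arrays."""

    def __init__(self, params: list[MuscleParams], paths: list[MusclePath]):
        if len(params) != len(paths):
            raise ValueError("params and paths must align")
        if [p.name for p in params] != MUSCLE_ORDER:
            raise ValueError(f"muscle roster must be exactly {MUSCLE_ORDER}")
        self.params = params
        self.paths = paths
        n = len(params)
        self.f_max = np.array([p.f_max for p in params])
        self.l_opt = np.array([p.l_opt for p in params])
        self.l_slack = np.array([p.l_slack for p in params])
        self.pennation = np.array([p.pennation for p in params])
        self.v_max = np.array([p.v_max for p in params])
        self.l_ref = np.array([pa.l_ref for pa in paths])
        self.arms = np.array([pa.arms for pa in paths], dtype=float)
        self.tau_act = np.array([p.tau_act for p in params])
        self.tau_deact = np.array([p.tau_deact for p in params])
        self.fl_width = np.array([p.fl_width for p in params])
        self.fv_curvature = np.array([p.fv_curvature for p in params])
        self.fv_ecc = np.array([p.fv_ecc for p in params])
        self.see_ref_strain = np.array([p.see_ref_strain for p in params])
        self.damping = np.array([p.damping for p in params])
        self.n = n

    def __len__(self):
        return self.n

    def index(self, name: str) -> int:
        return MUSCLE_ORDER.index(name)

    def engine_args(self):
        return (self.f_max, self.l_opt, self.l_slack, self.pennation,
                self.v_max, self.l_ref, self.arms, self.tau_act,
                self.tau_deact, self.fl_width, self.fv_curvature,
                self.fv_ecc, self.see_ref_strain, self.damping)

    def initial_states(self, joint_angles=(0.0, 0.0, 0.0)) -> np.ndarray:
        """CE lengths putting the SEE at slack in the given posture."""
        phi = np.asarray(joint_angles, dtype=float)
        lce = np.empty(self.n)
        for m in range(self.n):
            lmtu = _engine.mtu_length(self.l_ref[m], self.arms[m], phi)
            lce[m] = np.clip(lmtu - self.l_slack[m], 0.5 * self.l_opt[m],
                             1.5 * self.l_opt[m])
        return lce

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, pa in zip(self.params, self.paths):
            rows.append([p.name, p.f_max, p.l_opt, p.l_slack, p.pennation,
                         p.v_max, p.see_ref_strain, p.tau_act, p.tau_deact,
                         p.fl_width, p.fv_curvature, p.fv_ecc, p.damping,
                         p.ce_ref, *pa.arms])
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def save_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MuscleSet":
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"muscle table missing columns: {sorted(missing)}")
        params, paths = [], []
        df = df.set_index("name").loc[MUSCLE_ORDER].reset_index()
        for _, r in df.iterrows():
            params.append(MuscleParams(
                r["name"], r["f_max"], r["l_opt"], r["l_slack"],
                r["pennation"], r["v_max"], r["see_ref_strain"],
                r["tau_act"], r["tau_deact"], r["fl_width"],
                r["fv_curvature"], r["fv_ecc"], r["damping"], r["ce_ref"]))
            arms = (r["arm_hip"], r["arm_knee"], r["arm_ankle"])
            paths.append(MusclePath(tuple(float(a) for a in arms),
                                    r["ce_ref"] * r["l_opt"] + r["l_slack"]))
        return cls(params, paths)

    @classmethod
    def load_csv(cls, path) -> "MuscleSet":
        return cls.from_frame(pd.read_csv(path))


def default_muscles() -> MuscleSet:
    """The shipped muscle table (see module docstring)."""
    params, paths = [], []
    for name in MUSCLE_ORDER:
        f_max, l_opt, l_slack, pen, v_max, arms = _DEFAULT_TABLE[name]
        p = MuscleParams(name, f_max, l_opt, l_slack, pen, v_max)
        params.append(p)
        paths.append(MusclePath(arms, p.ce_ref * l_opt + l_slack))
    return MuscleSet(params, paths)


def load_default_csv() -> MuscleSet:
    """Muscle set from the CSV shipped inside the package."""
    with resources.files("standreflex.data").joinpath("muscles.csv").open() as f:
        return MuscleSet.from_frame(pd.read_csv(f))


# ---------------------------------------------------------------------------
# single-muscle operations (thin wrappers over the engine kernels)
# ---------------------------------------------------------------------------

def musculotendon_length(path: MusclePath, joint_angles) -> float:
    """MTU length at the given (hip, knee, ankle) angles, rad."""
    phi = np.asarray(joint_angles, dtype=float)
    if np.any(np.abs(phi) > np.pi):
        raise ValueError("joint angles must lie within +/- pi")
    return _engine.mtu_length(path.l_ref, np.asarray(path.arms, float), phi)


def see_force(l_see: float, params: MuscleParams) -> float:
    """Series elastic force (N); zero at or below slack length."""
    if l_see < 0:
        raise ValueError("l_see must be >= 0")
    return params.f_max * _engine.see_force_norm(l_see, params.l_slack,
                                                 params.see_ref_strain)


def contraction_dynamics(state: MuscleState, activation: float,
                         l_mtu: float, params: MuscleParams):
    """CE velocity (m/s) solving the four-element force balance.

    Returns (dl_ce/dt, clipped): ``clipped`` is True when no root exists
    inside the velocity bounds and the velocity was clamped.
    """
    fsee_n = _engine.see_force_norm(l_mtu - state.l_ce, params.l_slack,
                                    params.see_ref_strain)
    nu, clipped = _engine.solve_ce_velocity(
        activation, state.l_ce, fsee_n, params.pennation, params.l_opt,
        params.fl_width, params.fv_curvature, params.fv_ecc, params.damping)
    return nu * params.v_max * params.l_opt, bool(clipped)


def activation_dynamics(a: float, u: float, dt: float,
                        params: MuscleParams) -> float:
    """First-order excitation-contraction coupling, exact exponential step."""
    u = min(max(u, 0.0), 1.0)
    tau = params.tau_act if u >= a else params.tau_deact
    return a + (u - a) * (1.0 - np.exp(-dt / tau))


def joint_moments_from_muscles(muscles: MuscleSet, forces: np.ndarray) -> np.ndarray:
    """Per-joint (hip, knee, ankle) moments from SEE forces, one leg."""
    forces = np.asarray(forces, dtype=float)
    return muscles.arms.T @ forces
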