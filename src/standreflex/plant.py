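"""Sagittal-plane rigid-body model of a human standing on a movable platform.

The body is a seven-segment chain (trunk including head and arms, two thighs,
two shanks, two feet) connected by revolute hip, knee and ankle joints, with
the trunk as a floating base.  The nine generalized coordinates are trunk x,
trunk y (at the hip joint), trunk pitch (forward lean positive), and the six
joint angles (left hip/knee/ankle, right hip/knee/ankle; flexion and
dorsiflexion positive, zero in upright stance).  Left/right controls are
mirrored, so effectively six degrees of freedom describe the motion.

Each foot touches the platform at a heel and a toe point through a unilateral
spring-damper normal force with regularized Coulomb friction.  The platform
is driven kinematically: its recorded/generated trajectory is imposed, and
its 1000 kg mass is kept as metadata only, since a body of ~80 kg cannot
perturb it appreciably.

Default anthropometry is an 80 kg, 1.80 m adult with standard literature
mass/length fractions; everything is overridable through the config mapping
accepted by :func:`build_plant`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine

GRAVITY = 9.81
PLATFORM_MASS = 1000.0  # kg, metadata (platform motion is prescribed)

TRAJECTORY_COLUMNS = ["time", "trunk_x", "trunk_y", "trunk_pitch", "hip",
                      "knee", "ankle", "com_x", "com_y", "chest_y",
                      "ankle_x", "grf_y"]


@dataclass(frozen=True)
class SegmentParams:
    """Inertial and geometric parameters of one rigid segment."""

    name: str
    mass: float          # kg
    length: float        # m
    com_offset: float    # m from the proximal joint along the segment
    inertia: float       # kg m^2 about the segment COM

    def __post_init__(self):
        for f in ("mass", "length", "inertia"):
            v = getattr(self, f)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"segment {self.name!r}: {f} must be > 0, got {v}")
        if not 0.0 <= self.com_offset <= self.length:
            raise ValueError(
                f"segment {self.name!r}: com_offset {self.com_offset} outside "
                f"[0, {self.length}]")


@dataclass(frozen=True)
class ContactParams:
    """Foot-platform contact law parameters."""

    stiffness: float = 30000.0   # N/m per contact point (normal & tangential)
    damping: float = 300.0       # N s/m per contact point
    friction: float = 1.0        # Coulomb coefficient

    def __post_init__(self):
        if self.stiffness <= 0 or self.damping <= 0 or self.friction <= 0:
            raise ValueError("contact stiffness, damping and friction must be > 0")


@dataclass(frozen=True)
class JointStops:
    """Soft joint-range stops (hip, knee, ankle), engaged beyond the range.

    The knee's lower bound sits at full extension so the leg can rest near
    its lock in stance without hyperextending.
    """

    lower: tuple = (-0.6, 0.0, -0.8)    # rad
    upper: tuple = (2.0, 2.2, 0.6)      # rad
    stiffness: float = 2000.0           # N m/rad
    damping: float = 10.0               # N m s/rad


@dataclass(frozen=True)
class PlatformState:
    x: float = 0.0
    xdot: float = 0.0
    mass: float = PLATFORM_MASS


@dataclass
class PlantState:
    """Generalized coordinates/velocities plus simulation time."""

    q: np.ndarray          # (9,)
    qdot: np.ndarray       # (9,)
    t: float = 0.0

    def copy(self) -> "PlantState":
        return PlantState(self.q.copy(), self.qdot.copy(), self.t)


#: default anthropometry config (fractions of total mass / height)
DEFAULT_CONFIG = {
    "total_mass": 80.0,          # kg
    "height": 1.80,              # m
    # mass fractions (trunk includes head and arms; sums to 1 with 2 legs)
    "trunk_mass_frac": 0.678,
    "thigh_mass_frac": 0.100,
    "shank_mass_frac": 0.0465,
    "foot_mass_frac": 0.0145,
    # length fractions of height
    "trunk_len_frac": 0.470,     # hip to top of head
    "thigh_len_frac": 0.245,
    "shank_len_frac": 0.246,
    "foot_len_frac": 0.152,
    "ankle_height_frac": 0.039,
    # COM position fractions along segment from proximal end
    "trunk_com_frac": 0.45,
    "thigh_com_frac": 0.433,
    "shank_com_frac": 0.433,
    # radius of gyration fractions of segment length (about COM)
    "trunk_gyr_frac": 0.30,
    "thigh_gyr_frac": 0.323,
    "shank_gyr_frac": 0.302,
    "foot_gyr_frac": 0.475,
    # foot geometry: ankle sits above the foot axis, heel behind, toe ahead
    "heel_back_frac": 0.25,      # of foot length, behind the ankle
    "ankle_back": 0.05,          # m, ankle joint behind the shank axis, so the
                                 # standing plumb line passes anterior to it
    "chest_frac": 0.85,          # chest point along the trunk from the hip
}


def _segments_from_config(cfg: dict) -> dict[str, SegmentParams]:
    M = cfg["total_mass"]
    H = cfg["height"]
    lt = cfg["trunk_len_frac"] * H
    lth = cfg["thigh_len_frac"] * H
    lsh = cfg["shank_len_frac"] * H
    lft = cfg["foot_len_frac"] * H

    def seg(name, mfrac, length, com_frac, gyr_frac):
        m = mfrac * M
        return SegmentParams(name, m, length, com_frac * length,
                             m * (gyr_frac * length) ** 2)

    return {
        "trunk": seg("trunk", cfg["trunk_mass_frac"], lt,
                     cfg["trunk_com_frac"], cfg["trunk_gyr_frac"]),
        "thigh": seg("thigh", cfg["thigh_mass_frac"], lth,
                     cfg["thigh_com_frac"], cfg["thigh_gyr_frac"]),
        "shank": seg("shank", cfg["shank_mass_frac"], lsh,
                     cfg["shank_com_frac"], cfg["shank_gyr_frac"]),
        "foot": seg("foot", cfg["foot_mass_frac"], lft,
                    0.5, cfg["foot_gyr_frac"]),
    }


@dataclass
class PlantModel:
    """Built model: segment table plus the flattened arrays the engine uses."""

    segments: dict[str, SegmentParams]
    contact: ContactParams
    config: dict
    stops: JointStops = field(default_factory=JointStops)
    platform_mass: float = PLATFORM_MASS
    # engine arrays, filled by build_plant
    A: np.ndarray = field(default=None, repr=False)
    m7: np.ndarray = field(default=None, repr=False)
    I7: np.ndarray = field(default=None, repr=False)
    ptn: np.ndarray = field(default=None, repr=False)
    pta: np.ndarray = field(default=None, repr=False)
    ptv: np.ndarray = field(default=None, repr=False)

    @property
    def total_mass(self) -> float:
        s = self.segments
        return s["trunk"].mass + 2 * (s["thigh"].mass + s["shank"].mass
                                      + s["foot"].mass)

    @property
    def n_segments(self) -> int:
        return 7

    @property
    def n_joints(self) -> int:
        return 6

    @property
    def n_contact_points(self) -> int:
        return 4

    @property
    def hip_height(self) -> float:
        cfg = self.config
        return (cfg["ankle_height_frac"] * cfg["height"]
                + self.segments["shank"].length + self.segments["thigh"].length)

    def engine_args(self):
        c = self.contact
        s = self.stops
        return (self.A, self.m7, self.I7, self.ptn, self.pta, self.ptv,
                c.stiffness, c.damping, c.friction, GRAVITY,
                np.asarray(s.lower, dtype=float),
                np.asarray(s.upper, dtype=float), s.stiffness, s.damping)


def build_plant(config: dict | None = None,
                contact: ContactParams | None = None) -> PlantModel:
    """Construct the 7-segment model from an anthropometry config.

    ``config`` may override any :data:`DEFAULT_CONFIG` key.  Unknown keys are
    rejected so typos in parameter files surface immediately.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown anthropometry keys: {sorted(unknown)}")
        cfg.update(config)
    segs = _segments_from_config(cfg)
    model = PlantModel(segments=segs, contact=contact or ContactParams(),
                       config=cfg)

    # alpha = A q : absolute CCW segment orientations
    # order: trunk, thighL, shankL, footL, thighR, shankR, footR
    A = np.zeros((7, 9))
    A[:, 2] = -1.0  # trunk pitch is forward-positive; CCW alpha = -pitch
    for leg, (jh, jk, ja) in enumerate([(3, 4, 5), (6, 7, 8)]):
        base = 1 + 3 * leg
        A[base + 0, jh] = 1.0                       # thigh
        A[base + 1, jh] = 1.0
        A[base + 1, jk] = -1.0                      # shank
        A[base + 2, jh] = 1.0
        A[base + 2, jk] = -1.0
        A[base + 2, ja] = 1.0                       # foot

    lt = segs["trunk"].length
    lth = segs["thigh"].length
    lsh = segs["shank"].length
    lft = segs["foot"].length
    h_ank = cfg["ankle_height_frac"] * cfg["height"]
    d_heel = cfg["heel_back_frac"] * lft
    d_toe = lft - d_heel
    c_ft = 0.5 * lft - d_heel   # foot COM, forward of the ankle
    b_ank = cfg["ankle_back"]   # ankle joint behind the shank axis

    # chain tables: point = (q0,q1) + sum of local vectors rotated by alphas
    ptn = np.zeros(_engine.N_PTS, dtype=np.int64)
    pta = np.zeros((_engine.N_PTS, 3), dtype=np.int64)
    ptv = np.zeros((_engine.N_PTS, 3, 2))

    def set_chain(i, chain):
        ptn[i] = len(chain)
        for k, (ai, vec) in enumerate(chain):
            pta[i, k] = ai
            ptv[i, k] = vec

    TR, THL, SHL, FTL, THR, SHR, FTR = range(7)
    ct = segs["trunk"].com_offset
    cth = segs["thigh"].com_offset
    csh = segs["shank"].com_offset
    # segment COMs (points 0..6, same order as alphas)
    set_chain(0, [(TR, (0.0, ct))])
    for leg, (TH, SH, FT) in enumerate([(THL, SHL, FTL), (THR, SHR, FTR)]):
        o = 3 * leg
        set_chain(1 + o, [(TH, (0.0, -cth))])
        set_chain(2 + o, [(TH, (0.0, -lth)), (SH, (0.0, -csh))])
        set_chain(3 + o, [(TH, (0.0, -lth)), (SH, (-b_ank, -lsh)),
                          (FT, (c_ft, -0.5 * h_ank))])
    # contact points
    set_chain(_engine.PT_HEEL_L, [(THL, (0.0, -lth)), (SHL, (-b_ank, -lsh)),
                                  (FTL, (-d_heel, -h_ank))])
    set_chain(_engine.PT_TOE_L, [(THL, (0.0, -lth)), (SHL, (-b_ank, -lsh)),
                                 (FTL, (d_toe, -h_ank))])
    set_chain(_engine.PT_HEEL_R, [(THR, (0.0, -lth)), (SHR, (-b_ank, -lsh)),
                                  (FTR, (-d_heel, -h_ank))])
    set_chain(_engine.PT_TOE_R, [(THR, (0.0, -lth)), (SHR, (-b_ank, -lsh)),
                                 (FTR, (d_toe, -h_ank))])
    # ankles and chest
    set_chain(_engine.PT_ANKLE_L, [(THL, (0.0, -lth)), (SHL, (-b_ank, -lsh))])
    set_chain(_engine.PT_ANKLE_R, [(THR, (0.0, -lth)), (SHR, (-b_ank, -lsh))])
    set_chain(_engine.PT_CHEST, [(TR, (0.0, cfg["chest_frac"] * lt))])

    model.A = A
    model.m7 = np.array([segs["trunk"].mass,
                         segs["thigh"].mass, segs["shank"].mass,
                         segs["foot"].mass,
                         segs["thigh"].mass, segs["shank"].mass,
                         segs["foot"].mass])
    model.I7 = np.array([segs["trunk"].inertia,
                         segs["thigh"].inertia, segs["shank"].inertia,
                         segs["foot"].inertia,
                         segs["thigh"].inertia, segs["shank"].inertia,
                         segs["foot"].inertia])
    model.ptn = ptn
    model.pta = pta
    model.ptv = ptv
    return model


def upright_state(model: PlantModel, joint_angles=(0.0, 0.0, 0.0),
                  settle: float = 0.0) -> PlantState:
    """Standing state with both legs at (hip, knee, ankle) and feet on ground.

    ``settle`` lowers the hip slightly so contact springs carry the weight.
    """
    h, k, a = joint_angles
    q = np.zeros(9)
    q[3:6] = (h, k, a)
    q[6:9] = (h, k, a)
    # put the heel/toe points on the surface: solve hip height for contact
    q[1] = model.hip_height
    pts = kin_points(model, PlantState(q, np.zeros(9)))
    ymin = min(pts[_engine.PT_HEEL_L, 1], pts[_engine.PT_TOE_L, 1])
    q[1] -= ymin + settle
    # center the feet at x=0 in the world
    ax = pts[_engine.PT_ANKLE_L, 0]
    q[0] -= ax
    return PlantState(q, np.zeros(9), 0.0)


def kin_points(model: PlantModel, state: PlantState) -> np.ndarray:
    """All model points of interest (COMs, heel/toe contacts, ankles, chest)."""
    _, _, pts, _, _, _ = _engine.plant_kin(state.q, state.qdot, model.A,
                                           model.ptn, model.pta, model.ptv)
    return pts


def forward_dynamics(model: PlantModel, state: PlantState,
                     joint_moments: np.ndarray,
                     platform: PlatformState | None = None) -> np.ndarray:
    """Generalized accelerations under gravity, contact and joint moments.

    ``joint_moments`` has six entries (left hip/knee/ankle, right
    hip/knee/ankle), flexion/dorsiflexion positive.
    """
    if not np.all(np.isfinite(state.q)) or not np.all(np.isfinite(state.qdot)):
        raise ValueError("state contains non-finite values")
    tau = np.asarray(joint_moments, dtype=float)
    if tau.shape != (6,):
        raise ValueError("joint_moments must have 6 entries")
    plat = platform or PlatformState()
    qdd, _, _ = _engine.plant_dynamics(state.q, state.qdot, tau,
                                       plat.x, plat.xdot,
                                       *model.engine_args())
    if not np.all(np.isfinite(qdd)):
        raise ArithmeticError("singular or ill-conditioned mass matrix")
    return qdd


def integrate_step(model: PlantModel, state: PlantState,
                   joint_moments: np.ndarray, dt: float,
                   platform: PlatformState | None = None) -> PlantState:
    """Advance one fixed step with the semi-implicit Euler scheme."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    qdd = forward_dynamics(model, state, joint_moments, platform)
    if not np.all(np.isfinite(qdd)):
        raise ArithmeticError("non-finite derivatives; simulation aborted")
    qdot = state.qdot + dt * qdd
    q = state.q + dt * qdot
    return PlantState(q, qdot, state.t + dt)


def com_position(model: PlantModel, state: PlantState) -> tuple[float, float]:
    """Whole-body COM (x, y): mass-weighted mean of segment COMs."""
    pts = kin_points(model, state)
    return _engine.com_from_pts(pts, model.m7, model.total_mass)


def contact_forces(model: PlantModel, state: PlantState,
                   platform: PlatformState | None = None) -> np.ndarray:
    """Per-point (tangential, normal) contact forces, N.

    Rows: left heel, left toe, right heel, right toe.  Normal forces are
    unilateral (>= 0) and tangential magnitudes respect the friction cone.
    """
    plat = platform or PlatformState()
    _, grf, _ = _engine.plant_dynamics(state.q, state.qdot, np.zeros(6),
                                       plat.x, plat.xdot,
                                       *model.engine_args())
    return grf


def chest_height(model: PlantModel, state: PlantState) -> float:
    """Height of the chest point on the trunk segment (m)."""
    return kin_points(model, state)[_engine.PT_CHEST, 1]


def ankle_x(model: PlantModel, state: PlantState,
            platform: PlatformState | None = None,
            reference: float = 0.0) -> float:
    """Mean ankle x in the platform frame, relative to ``reference``.

    ``reference`` is the same quantity at perturbation onset, so with no
    motion the result is identically zero.
    """
    plat = platform or PlatformState()
    pts = kin_points(model, state)
    ax = 0.5 * (pts[_engine.PT_ANKLE_L, 0] + pts[_engine.PT_ANKLE_R, 0])
    return ax - plat.x - reference


def mechanical_energy(model: PlantModel, state: PlantState) -> float:
    """Total kinetic + gravitational potential energy (no contact stored energy)."""
    return _engine.mech_energy(state.q, state.qdot, model.A, model.m7,
                               model.I7, model.ptn, model.pta, model.ptv,
                               GRAVITY)


def mirror_state(state: PlantState) -> PlantState:
    """Swap left and right leg coordinates."""
    q = state.q.copy()
    qd = state.qdot.copy()
    q[3:6], q[6:9] = state.q[6:9].copy(), state.q[3:6].copy()
    qd[3:6], qd[6:9] = state.qdot[6:9].copy(), state.qdot[3:6].copy()
    return PlantState(q, qd, state.t)
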