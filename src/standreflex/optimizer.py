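"""Lexicographic particle swarm optimization of the reflex controller.

The decision vector z stacks, per architecture:

* base:        u0 (9), G_FFB (9), G_LFB (9), l_off (9), dead zone (4) -> 40
* length_only: u0 (9),            G_LFB (9), l_off (9), dead zone (4) -> 31
* force_only:  u0 (9), G_FFB (9),                       dead zone (4) -> 22

Bounds: u0 in [0.001, 1], gains in [-3, 3], l_off in [0.2, 1.1], dead-zone
edge distances in [0, 0.10] m, transition fractions in [0, 1].

Candidates are scored lexicographically: tier 1 is the summed normalized
constraint violation (duration shortfall / 100 s, chest shortfall / 1.3 m,
ankle excursion excess / 0.05 m); tier 2 is the effort objective.  Any
feasible candidate (tier 1 == 0) beats any infeasible one; ties fall back to
candidate index so comparisons are a deterministic total order.

The swarm is a standard global-best PSO with inertia/cognitive/social
coefficients, velocity clamping, and reflection at the bounds; fixed seeds
make runs reproducible, and optional warm starts inject a known-good
parameter vector as one initial particle (its personal best then protects
the final answer from ever being worse than the warm start).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .controller import Architecture, DeadZone, ReflexParams, ARCHITECTURES
from .episode import (CONSTRAINT_ANKLE, CONSTRAINT_CHEST, CONSTRAINT_DURATION,
                      EpisodeConfig, run_episode)
from .muscles import MUSCLE_ORDER

N_MUS = len(MUSCLE_ORDER)


@dataclass(frozen=True)
class LexicographicScore:
    violation: float       # tier 1: total normalized constraint violation
    effort: float          # tier 2: objective among feasible candidates

    @property
    def feasible(self) -> bool:
        return self.violation <= 0.0

    def key(self):
        # feasible candidates compare on effort with violation pinned at 0
        v = self.violation if self.violation > 0 else 0.0
        return (v, self.effort)


def lexicographic_compare(a: LexicographicScore, b: LexicographicScore) -> int:
    """-1 if a is better, +1 if b is better, 0 on exact tie."""
    ka, kb = a.key(), b.key()
    if ka < kb:
        return -1
    if ka > kb:
        return 1
    return 0


WORST_SCORE = LexicographicScore(np.inf, np.inf)


def make_bounds(architecture: str):
    """(lower, upper) arrays for the architecture's decision vector."""
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    lo, hi = [], []
    lo += [0.001] * N_MUS
    hi += [1.0] * N_MUS
    if architecture in ("base", "force_only"):
        lo += [-3.0] * N_MUS
        hi += [3.0] * N_MUS
    if architecture in ("base", "length_only"):
        lo += [-3.0] * N_MUS
        hi += [3.0] * N_MUS
        lo += [0.2] * N_MUS
        hi += [1.1] * N_MUS
    lo += [0.0, 0.0, 0.0, 0.0]       # x_heel, x_toe, z_heel, z_toe
    hi += [0.10, 0.10, 1.0, 1.0]
    return np.array(lo), np.array(hi)


def vector_to_params(z: np.ndarray, architecture: str) -> ReflexParams:
    """Unpack a decision vector into ReflexParams (absent blocks zeroed)."""
    z = np.asarray(z, dtype=float)
    lo, hi = make_bounds(architecture)
    if z.shape != lo.shape:
        raise ValueError(f"expected {lo.shape[0]} parameters for "
                         f"{architecture}, got {z.shape[0]}")
    i = 0
    u0 = z[i:i + N_MUS]; i += N_MUS
    if architecture in ("base", "force_only"):
        g_ffb = z[i:i + N_MUS]; i += N_MUS
    else:
        g_ffb = np.zeros(N_MUS)
    if architecture in ("base", "length_only"):
        g_lfb = z[i:i + N_MUS]; i += N_MUS
        l_off = z[i:i + N_MUS]; i += N_MUS
    else:
        g_lfb = np.zeros(N_MUS)
        l_off = np.full(N_MUS, 1.1)
    dz = DeadZone(*z[i:i + 4])
    return ReflexParams(u0.copy(), g_ffb.copy(), g_lfb.copy(), l_off.copy(), dz)


def params_to_vector(params: ReflexParams, architecture: str) -> np.ndarray:
    blocks = [params.u0]
    if architecture in ("base", "force_only"):
        blocks.append(params.g_ffb)
    if architecture in ("base", "length_only"):
        blocks.append(params.g_lfb)
        blocks.append(params.l_off)
    dz = params.dead_zone
    blocks.append(np.array([dz.x_heel, dz.x_toe, dz.z_heel, dz.z_toe]))
    return np.concatenate(blocks)


def episode_score(result) -> LexicographicScore:
    """Score one episode lexicographically (normalized violations)."""
    v = 0.0
    v += max(0.0, CONSTRAINT_DURATION - result.survived) / CONSTRAINT_DURATION
    v += max(0.0, CONSTRAINT_CHEST - result.final_chest_height) / CONSTRAINT_CHEST
    v += max(0.0, result.mean_ankle_excursion - CONSTRAINT_ANKLE) / CONSTRAINT_ANKLE
    if result.failed:
        v += 10.0
    return LexicographicScore(v, result.effort)


def make_episode_evaluator(model, muscles, architecture: Architecture,
                           signal, config: EpisodeConfig | None = None,
                           delays: dict | None = None):
    """evaluate(z) -> LexicographicScore via one full episode (single shooting)."""

    def evaluate(z):
        try:
            params = vector_to_params(z, architecture.kind)
            result = run_episode(model, muscles, params, architecture,
                                 signal, config, delays)
        except Exception:
            return WORST_SCORE
        return episode_score(result)

    return evaluate


@dataclass
class SwarmConfig:
    n_particles: int = 24
    n_iterations: int = 60
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    v_clamp: float = 0.20         # fraction of each bound range
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("population must have at least 2 particles")
        if min(self.cognitive, self.social, self.inertia) <= 0:
            raise ValueError("PSO coefficients must be > 0")


@dataclass
class SwarmResult:
    best_z: np.ndarray
    best_score: LexicographicScore
    history: pd.DataFrame         # iteration, best violation, best effort
    n_evals: int


def _reflect(z, v, lo, hi):
    """Reflect position (and flip velocity) at the box bounds."""
    for _ in range(4):
        below = z < lo
        above = z > hi
        if not (below.any() or above.any()):
            break
        z = np.where(below, 2 * lo - z, z)
        z = np.where(above, 2 * hi - z, z)
        v = np.where(below | above, -v, v)
    return np.clip(z, lo, hi), v


def pso_optimize(evaluate, bounds, swarm: SwarmConfig | None = None,
                 warm_start: np.ndarray | None = None,
                 callback=None) -> SwarmResult:
    """Global-best PSO with lexicographic comparison.

    ``evaluate`` maps a decision vector to a LexicographicScore; crashes are
    the evaluator's concern (score them as maximally infeasible).
    """
    cfg = swarm or SwarmConfig()
    lo, hi = bounds
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    ndim = len(lo)
    rng = np.random.default_rng(cfg.seed)
    rang = hi - lo
    vmax = cfg.v_clamp * rang

    pos = lo + rng.random((cfg.n_particles, ndim)) * rang
    if warm_start is not None:
        ws = np.atleast_2d(np.asarray(warm_start, float))
        if ws.shape[1] != ndim:
            raise ValueError("warm start has the wrong dimension")
        k = min(len(ws), cfg.n_particles)
        pos[:k] = np.clip(ws[:k], lo, hi)
    vel = (rng.random((cfg.n_particles, ndim)) - 0.5) * vmax

    pbest = pos.copy()
    pbest_score = [WORST_SCORE] * cfg.n_particles
    gbest = pos[0].copy()
    gbest_score = WORST_SCORE
    n_evals = 0
    rows = []

    for it in range(cfg.n_iterations):
        for i in range(cfg.n_particles):
            score = evaluate(pos[i])
            n_evals += 1
            if lexicographic_compare(score, pbest_score[i]) < 0:
                pbest_score[i] = score
                pbest[i] = pos[i].copy()
            # strict improvement only: ties keep the earlier candidate
            if lexicographic_compare(score, gbest_score) < 0:
                gbest_score = score
                gbest = pos[i].copy()
        rows.append((it, gbest_score.violation, gbest_score.effort))
        if callback is not None:
            callback(it, gbest, gbest_score)
        r1 = rng.random((cfg.n_particles, ndim))
        r2 = rng.random((cfg.n_particles, ndim))
        vel = (cfg.inertia * vel
               + cfg.cognitive * r1 * (pbest - pos)
               + cfg.social * r2 * (gbest[None, :] - pos))
        vel = np.clip(vel, -vmax, vmax)
        pos = pos + vel
        for i in range(cfg.n_particles):
            pos[i], vel[i] = _reflect(pos[i], vel[i], lo, hi)

    history = pd.DataFrame(rows, columns=["iteration", "best_violation",
                                          "best_effort"])
    return SwarmResult(gbest, gbest_score, history, n_evals)


def delay_sweep(delay_tables: list, model, muscles, architecture: Architecture,
                signal, swarm: SwarmConfig | None = None,
                config: EpisodeConfig | None = None,
                warm_start: np.ndarray | None = None) -> pd.DataFrame:
    """One optimization per delay table; collated best scores.

    Each entry of ``delay_tables`` is a full muscle->delay (s) mapping, e.g.
    the default table with all delays shifted, or a COM-delay variant driven
    through ``architecture.com_delay``.
    """
    rows = []
    bounds = make_bounds(architecture.kind)
    for i, delays in enumerate(delay_tables):
        evaluate = make_episode_evaluator(model, muscles, architecture,
                                          signal, config, delays)
        res = pso_optimize(evaluate, bounds, swarm, warm_start=warm_start)
        rows.append({"setting": i,
                     "delays": ";".join(f"{m}={delays[m]:.3f}"
                                        for m in MUSCLE_ORDER),
                     "best_violation": res.best_score.violation,
                     "best_effort": res.best_score.effort})
    return pd.DataFrame(rows, columns=["setting", "delays", "best_violation",
                                       "best_effort"])
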