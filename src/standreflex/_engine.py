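"""Numba-compiled numerical core.

Everything that runs inside the 1 kHz simulation loop lives here: planar
rigid-body kinematics/dynamics of the 7-segment chain, the four-element
Hill-type muscle equations, the dead-zone reflex controller, and the episode
integrator.  The public modules (`plant`, `muscles`, `controller`, `episode`)
wrap these kernels with validated, documented interfaces; the math itself has
a single home so the fast path and the inspectable path cannot diverge.

Conventions
-----------
* x forward (toe direction), y up; gravity acts along -y.
* Generalized coordinates ``q`` (9): trunk x, trunk y (the hip joint is the
  floating-base reference point), trunk pitch (forward lean positive), then
  left hip, knee, ankle and right hip, knee, ankle joint angles.
* Joint angles are zero in upright stance; hip flexion, knee flexion and
  ankle dorsiflexion are positive.
* Internally each segment carries an absolute CCW orientation ``alpha``
  which is a fixed linear map of ``q`` (matrix ``A``, 7 x 9).
"""

import numpy as np
from numba import config, njit

# Reproducibility across machines: compile for a generic CPU instead of the
# host's microarchitecture.  The 110-s episodes are chaotic, so instruction
# -selection differences (FMA contraction, vector width) would otherwise make
# episode outcomes host-dependent at the margin.
config.CPU_NAME = "generic"
config.CPU_FEATURES = ""

# indices into the point table produced by plant_kin
PT_COM0 = 0           # 0..6: segment COMs (trunk, thighL, shankL, footL, thighR, shankR, footR)
PT_HEEL_L = 7
PT_TOE_L = 8
PT_HEEL_R = 9
PT_TOE_R = 10
PT_ANKLE_L = 11
PT_ANKLE_R = 12
PT_CHEST = 13
N_PTS = 14
N_Q = 9
N_MUS = 9  # per leg


# ---------------------------------------------------------------------------
# rigid-body kinematics / dynamics
# ---------------------------------------------------------------------------

@njit(cache=False)
def plant_kin(q, qd, A, ptn, pta, ptv):
    """Positions, Jacobians, bias accelerations and velocities of all points.

    Returns (alphas, alphadots, pts, J, bias, vel); J/bias/vel are only
    filled for points 0..10 (segment COMs and contact points).
    """
    alphas = np.zeros(7)
    ad = np.zeros(7)
    for i in range(7):
        s = 0.0
        sd = 0.0
        for j in range(2, N_Q):
            w = A[i, j]
            if w != 0.0:
                s += w * q[j]
                sd += w * qd[j]
        alphas[i] = s
        ad[i] = sd

    pts = np.zeros((N_PTS, 2))
    J = np.zeros((11, 2, N_Q))
    bias = np.zeros((11, 2))
    vel = np.zeros((11, 2))
    for i in range(N_PTS):
        px = q[0]
        py = q[1]
        if i < 11:
            J[i, 0, 0] = 1.0
            J[i, 1, 1] = 1.0
            vel[i, 0] = qd[0]
            vel[i, 1] = qd[1]
        for k in range(ptn[i]):
            ai = pta[i, k]
            ca = np.cos(alphas[ai])
            sa = np.sin(alphas[ai])
            vx0 = ptv[i, k, 0]
            vy0 = ptv[i, k, 1]
            rx = ca * vx0 - sa * vy0
            ry = sa * vx0 + ca * vy0
            px += rx
            py += ry
            if i < 11:
                adk = ad[ai]
                vel[i, 0] += -ry * adk
                vel[i, 1] += rx * adk
                bias[i, 0] += -rx * adk * adk
                bias[i, 1] += -ry * adk * adk
                for j in range(2, N_Q):
                    w = A[ai, j]
                    if w != 0.0:
                        J[i, 0, j] += -ry * w
                        J[i, 1, j] += rx * w
        pts[i, 0] = px
        pts[i, 1] = py
    return alphas, ad, pts, J, bias, vel


@njit(cache=False)
def contact_forces_anchored(pts, vel, plat_x, plat_v, anchors, active,
                            kc, cc, mu):
    """Per-point contact forces with stick-slip friction, (4, 2) = (ft, fn).

    Normal: unilateral spring-damper (clipped at 0).  Tangential: a spring
    anchored where the point first touched (expressed in the platform frame,
    so platform motion drags a sticking foot along), clipped at the Coulomb
    limit mu*fn; while sliding the anchor is re-seated at the limit.
    ``anchors``/``active`` persist across steps and are updated in place.
    """
    grf = np.zeros((4, 2))
    for c in range(4):
        i = PT_HEEL_L + c
        py = pts[i, 1]
        if py < 0.0:
            fn = kc * (-py) - cc * vel[i, 1]
            if fn < 0.0:
                fn = 0.0
            relx = pts[i, 0] - plat_x
            if active[c] == 0:
                anchors[c] = relx
                active[c] = 1
            ft = -kc * (relx - anchors[c]) - cc * (vel[i, 0] - plat_v)
            flim = mu * fn
            if ft > flim:
                ft = flim
                anchors[c] = relx + ft / kc
            elif ft < -flim:
                ft = -flim
                anchors[c] = relx + ft / kc
            grf[c, 0] = ft
            grf[c, 1] = fn
        else:
            active[c] = 0
    return grf


@njit(cache=False)
def joint_stop_torques(q, qd, jlo, jhi, ks, cs, tau_out):
    """Soft joint-range stops (spring-damper beyond [jlo, jhi] per joint)."""
    for j in range(6):
        jj = j % 3
        x = q[3 + j]
        if x > jhi[jj]:
            tau_out[j] = -ks * (x - jhi[jj]) - cs * qd[3 + j]
        elif x < jlo[jj]:
            tau_out[j] = -ks * (x - jlo[jj]) - cs * qd[3 + j]
        else:
            tau_out[j] = 0.0


@njit(cache=False)
def plant_solve(q, qd, tau, grf, A, m7, I7, pts, J, bias, vel, grav):
    """Assemble M(q) qdd = Q and solve; contact forces are supplied."""
    M = np.zeros((N_Q, N_Q))
    Q = np.zeros(N_Q)
    for s in range(7):
        ms = m7[s]
        Is = I7[s]
        for a in range(N_Q):
            Ja0 = J[s, 0, a]
            Ja1 = J[s, 1, a]
            Aa = A[s, a]
            for b in range(a, N_Q):
                M[a, b] += ms * (Ja0 * J[s, 0, b] + Ja1 * J[s, 1, b]) \
                    + Is * Aa * A[s, b]
            Q[a] += Ja1 * (-ms * grav) \
                - ms * (Ja0 * bias[s, 0] + Ja1 * bias[s, 1])
    for a in range(1, N_Q):
        for b in range(a):
            M[a, b] = M[b, a]

    for c in range(4):
        i = PT_HEEL_L + c
        if grf[c, 1] > 0.0:
            for a in range(N_Q):
                Q[a] += J[i, 0, a] * grf[c, 0] + J[i, 1, a] * grf[c, 1]
    for j in range(6):
        Q[3 + j] += tau[j]
    qdd = solve_spd(M, Q)
    return qdd


@njit(cache=False)
def solve_spd(M, b):
    """Cholesky solve for the symmetric positive-definite mass matrix.

    Hand-rolled so the arithmetic is plain scalar code: no BLAS/LAPACK
    kernel dispatch, hence bit-identical results on any machine.
    """
    n = M.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = M[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    s = 1e-12  # should never happen for this topology
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    y = np.zeros(n)
    for i in range(n):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    x = np.zeros(n)
    for i in range(n - 1, -1, -1):
        s = y[i]
        for k in range(i + 1, n):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=False)
def plant_dynamics(q, qd, tau, plat_x, plat_v, A, m7, I7, ptn, pta, ptv,
                   kc, cc, mu, grav, jlo, jhi, ks, cs):
    """One-call generalized accelerations (public API and tests).

    Stateless: tangential anchors are seated at the instantaneous point
    positions, so friction acts as pure damping on the slip velocity here;
    the episode loop carries persistent anchors instead.
    """
    alphas, ad, pts, J, bias, vel = plant_kin(q, qd, A, ptn, pta, ptv)
    anchors = np.zeros(4)
    active = np.zeros(4, dtype=np.int64)
    grf = contact_forces_anchored(pts, vel, plat_x, plat_v, anchors, active,
                                  kc, cc, mu)
    tau_tot = tau.copy()
    stop = np.zeros(6)
    joint_stop_torques(q, qd, jlo, jhi, ks, cs, stop)
    for j in range(6):
        tau_tot[j] += stop[j]
    qdd = plant_solve(q, qd, tau_tot, grf, A, m7, I7, pts, J, bias, vel, grav)
    return qdd, grf, pts


@njit(cache=False)
def com_from_pts(pts, m7, mtot):
    cx = 0.0
    cy = 0.0
    for s in range(7):
        cx += m7[s] * pts[s, 0]
        cy += m7[s] * pts[s, 1]
    return cx / mtot, cy / mtot


@njit(cache=False)
def mech_energy(q, qd, A, m7, I7, ptn, pta, ptv, grav):
    """Kinetic + gravitational potential energy of the chain (no contact)."""
    alphas, ad, pts, J, bias, vel = plant_kin(q, qd, A, ptn, pta, ptv)
    E = 0.0
    for s in range(7):
        E += 0.5 * m7[s] * (vel[s, 0] ** 2 + vel[s, 1] ** 2)
        E += 0.5 * I7[s] * ad[s] ** 2
        E += m7[s] * grav * pts[s, 1]
    return E


# ---------------------------------------------------------------------------
# Hill-type muscle model
# ---------------------------------------------------------------------------

_FL_C = np.log(0.05)


@njit(cache=False)
def force_length(lce, lopt, w):
    """Bell-shaped active force-length factor; 0.05 at lopt*(1 +/- w)."""
    x = np.abs((lce - lopt) / (lopt * w))
    return np.exp(_FL_C * x * x * x)


@njit(cache=False)
def force_velocity(nu, K, N):
    """Hill force-velocity factor vs normalized CE velocity nu = v/v_max.

    Shortening (nu<0) follows the Hill hyperbola down to 0 at nu=-1;
    lengthening saturates at N (eccentric force enhancement).
    """
    if nu <= -1.0:
        return 0.0
    if nu <= 0.0:
        return (1.0 + nu) / (1.0 - K * nu)
    return N - (N - 1.0) * (1.0 + nu) / (1.0 + 7.56 * K * nu)


@njit(cache=False)
def _force_velocity_deriv(nu, K, N):
    if nu <= -1.0:
        return 0.0
    if nu <= 0.0:
        d = 1.0 - K * nu
        return (1.0 + K) / (d * d)
    d = 1.0 + 7.56 * K * nu
    return (N - 1.0) * (7.56 * K - 1.0) / (d * d)


@njit(cache=False)
def see_force_norm(lsee, lslack, eps_ref):
    """Series elastic force / F_max: quadratic in strain, slack below l_slack."""
    if lsee <= lslack or lslack <= 0.0:
        return 0.0
    e = (lsee - lslack) / (lslack * eps_ref)
    return e * e


@njit(cache=False)
def pe_force_norm(lce, lopt, w):
    """Parallel elastic force / F_max, engages beyond optimal length."""
    if lce <= lopt:
        return 0.0
    x = (lce - lopt) / (lopt * w)
    return x * x


@njit(cache=False)
def be_force_norm(lce, lopt, w):
    """Buffer element force / F_max, props the CE up below lopt*(1-w)."""
    lmin = lopt * (1.0 - w)
    if lce >= lmin:
        return 0.0
    x = (lmin - lce) / (lopt * w * 0.5)
    return x * x


@njit(cache=False)
def solve_ce_velocity(a, lce, fsee_n, penn, lopt, w, K, N, dmp):
    """Normalized CE velocity from the four-element force balance.

    Solves  penn*(a*fl*fv(nu) + fpe + dmp*nu - fbe) = fsee_n  for nu in
    [-1, 1] by safeguarded Newton iteration (the residual is monotone in nu).
    Returns (nu, clipped) where clipped=1 means no root inside the velocity
    bounds and the value was clamped.
    """
    fl = force_length(lce, lopt, w)
    base = pe_force_norm(lce, lopt, w) - be_force_norm(lce, lopt, w)
    afl = a * fl
    lo = -1.0
    hi = 1.0
    rlo = penn * (afl * force_velocity(lo, K, N) + base + dmp * lo) - fsee_n
    if rlo >= 0.0:
        return -1.0, 1
    rhi = penn * (afl * force_velocity(hi, K, N) + base + dmp * hi) - fsee_n
    if rhi <= 0.0:
        return 1.0, 1
    nu = 0.0
    for _ in range(80):
        r = penn * (afl * force_velocity(nu, K, N) + base + dmp * nu) - fsee_n
        if np.abs(r) < 1e-10:
            break
        if r > 0.0:
            hi = nu
        else:
            lo = nu
        dr = penn * (afl * _force_velocity_deriv(nu, K, N) + dmp)
        if dr > 0.0:
            nun = nu - r / dr
        else:
            nun = 0.5 * (lo + hi)
        if nun <= lo or nun >= hi:
            nun = 0.5 * (lo + hi)
        nu = nun
    return nu, 0


@njit(cache=False)
def mtu_length(lref, arm, phi):
    """Musculotendon length: reference length minus moment-arm-weighted angles."""
    return lref - arm[0] * phi[0] - arm[1] * phi[1] - arm[2] * phi[2]


@njit(cache=False)
def muscles_step(phi, lce, act, stim, dt,
                 fmax, lopt, lslack, penn, vmax, lref, arm,
                 tact, tdeact, flw, fvK, fvN, see_eps, dmp,
                 moments, fsee_out, lce_out):
    """Advance one leg's 9 muscles by one step.

    Writes joint moments (hip, knee, ankle; flexion/dorsiflexion positive),
    the normalized SEE forces and CE lengths *at the current time* (sensor
    values), then integrates activation and CE length in place.
    Returns the number of velocity-bound clips.
    """
    nclip = 0
    moments[0] = 0.0
    moments[1] = 0.0
    moments[2] = 0.0
    for m in range(N_MUS):
        lmtu = mtu_length(lref[m], arm[m], phi)
        lsee = lmtu - lce[m]
        fn = see_force_norm(lsee, lslack[m], see_eps[m])
        fsee_out[m] = fn
        lce_out[m] = lce[m] / lopt[m]
        F = fn * fmax[m]
        moments[0] += F * arm[m, 0]
        moments[1] += F * arm[m, 1]
        moments[2] += F * arm[m, 2]
        # first-order excitation-contraction coupling (exact exponential step)
        u = stim[m]
        if u < 0.0:
            u = 0.0
        elif u > 1.0:
            u = 1.0
        tau = tact[m] if u >= act[m] else tdeact[m]
        act[m] += (u - act[m]) * (1.0 - np.exp(-dt / tau))
        nu, clipped = solve_ce_velocity(act[m], lce[m], fn, penn[m],
                                        lopt[m], flw[m], fvK[m], fvN[m],
                                        dmp[m])
        nclip += clipped
        lce[m] += dt * nu * vmax[m] * lopt[m]
        if lce[m] < 0.2 * lopt[m]:
            lce[m] = 0.2 * lopt[m]
    return nclip


# ---------------------------------------------------------------------------
# reflex controller
# ---------------------------------------------------------------------------

@njit(cache=False)
def deadzone_scale(xc, bh, bt, wh, wt):
    """Signed gain factor in [-1, 1] vs COM x (platform frame).

    0 inside [bh, bt]; linear ramp to -1 over width wh below bh and to +1
    over width wt above bt; saturated beyond.  Continuous everywhere.
    """
    if xc > bt:
        if wt <= 0.0:
            return 1.0
        s = (xc - bt) / wt
        return s if s < 1.0 else 1.0
    if xc < bh:
        if wh <= 0.0:
            return -1.0
        s = (xc - bh) / wh
        return s if s > -1.0 else -1.0
    return 0.0


@njit(cache=False)
def reflex_stimulation(u0, gffb, glfb, loff, s, fhat, lhat, stim_out):
    """Per-muscle stimulation u = clamp(u0 + s*G_FFB*Fhat + length term)."""
    for m in range(N_MUS):
        u = u0[m] + s * gffb[m] * fhat[m]
        if lhat[m] > loff[m]:
            u += s * glfb[m] * (lhat[m] - loff[m])
        if u < 0.001:
            u = 0.001
        elif u > 1.0:
            u = 1.0
        stim_out[m] = u


# ---------------------------------------------------------------------------
# episode loop
# ---------------------------------------------------------------------------

@njit(cache=False)
def run_episode_core(
        q0, qd0, lce0, act0,
        # plant
        A, m7, I7, ptn, pta, ptv, kc, cc, mu, grav, jlo, jhi, ks, cs, mtot,
        # muscles
        fmax, lopt, lslack, penn, vmax, lref, arm,
        tact, tdeact, flw, fvK, fvN, see_eps, dmp,
        # controller
        u0, gffb, glfb, loff, dly, xheel, xtoe, zheel, ztoe, com_dly,
        # protocol
        dt, n_steps, n_pd, n_quiet, n_horizon, pd_kp, pd_kd, q_ref,
        plat_pos, plat_vel, chest_fall, log_every):
    """Integrate one full episode; returns logs and scalar outcomes.

    Phases: [0, n_pd) joint-angle PD control (muscles active underneath),
    [n_pd, n_pd+n_quiet) muscle-only quiet stance, then platform motion.
    Early stop when the chest point drops below ``chest_fall``.
    """
    q = q0.copy()
    qd = qd0.copy()
    lce = lce0.copy()   # (2, 9)
    act = act0.copy()

    fhist = np.zeros((n_steps, 2, N_MUS))
    lhist = np.zeros((n_steps, 2, N_MUS))
    comhist = np.zeros(n_steps)

    # initial sensor values, used until real history reaches the delay depth
    init_f = np.zeros((2, N_MUS))
    init_l = np.zeros((2, N_MUS))
    phi = np.zeros(3)
    for leg in range(2):
        for j in range(3):
            phi[j] = q[3 + 3 * leg + j]
        for m in range(N_MUS):
            lmtu = mtu_length(lref[m], arm[m], phi)
            init_f[leg, m] = see_force_norm(lmtu - lce[leg, m], lslack[m],
                                            see_eps[m])
            init_l[leg, m] = lce[leg, m] / lopt[m]

    nlog = n_steps // log_every + 1
    log_t = np.zeros(nlog)
    log_ang = np.zeros((nlog, 3))
    log_mom = np.zeros((nlog, 3))
    log_com = np.zeros((nlog, 2))
    log_chest = np.zeros(nlog)
    log_ankx = np.zeros(nlog)
    log_grfy = np.zeros(nlog)
    log_act = np.zeros((nlog, N_MUS))
    log_plat = np.zeros(nlog)
    log_trunk = np.zeros((nlog, 3))
    n_logged = 0

    effort_sum = 0.0
    exc_sum = 0.0
    onset = n_pd + n_quiet
    bh = 0.0
    bt = 0.0
    wh = 0.0
    wt = 0.0
    ax_ref = 0.0
    edges_ok = 1
    nclip = 0
    survived = 0.0
    fell = 0

    stim = np.zeros((2, N_MUS))
    momL = np.zeros(3)
    momR = np.zeros(3)
    fseeL = np.zeros(N_MUS)
    fseeR = np.zeros(N_MUS)
    lceL = np.zeros(N_MUS)
    lceR = np.zeros(N_MUS)
    tau = np.zeros(6)
    stop = np.zeros(6)
    final_chest = 0.0
    anchors = np.zeros(4)
    cactive = np.zeros(4, dtype=np.int64)

    for n in range(n_steps):
        t = n * dt
        plat_x = plat_pos[n]
        plat_v = plat_vel[n]

        alphas, ad, pts, J, bias, vel = plant_kin(q, qd, A, ptn, pta, ptv)
        cx, cy = com_from_pts(pts, m7, mtot)
        comhist[n] = cx - plat_x
        chest_y = pts[PT_CHEST, 1]
        final_chest = chest_y

        if n == n_pd:
            # freeze dead-zone geometry at the start of muscle-only stance
            heel_x = 0.5 * (pts[PT_HEEL_L, 0] + pts[PT_HEEL_R, 0]) - plat_x
            toe_x = 0.5 * (pts[PT_TOE_L, 0] + pts[PT_TOE_R, 0]) - plat_x
            bh = heel_x + xheel
            bt = toe_x - xtoe
            wh = zheel * xheel
            wt = ztoe * xtoe
            if bh >= bt:
                edges_ok = 0
        if n == onset:
            ax_ref = 0.5 * (pts[PT_ANKLE_L, 0] + pts[PT_ANKLE_R, 0]) - plat_x

        # --- controller ---
        if n >= n_pd and edges_ok == 1:
            ic = n - com_dly
            if ic < n_pd:
                ic = n_pd
            s = deadzone_scale(comhist[ic], bh, bt, wh, wt)
        else:
            s = 0.0
        for leg in range(2):
            for m in range(N_MUS):
                i = n - dly[m]
                if i < 0:
                    fhat = init_f[leg, m]
                    lhat = init_l[leg, m]
                else:
                    fhat = fhist[i, leg, m]
                    lhat = lhist[i, leg, m]
                u = u0[m] + s * gffb[m] * fhat
                if lhat > loff[m]:
                    u += s * glfb[m] * (lhat - loff[m])
                if u < 0.001:
                    u = 0.001
                elif u > 1.0:
                    u = 1.0
                stim[leg, m] = u

        # --- muscles ---
        for j in range(3):
            phi[j] = q[3 + j]
        nclip += muscles_step(phi, lce[0], act[0], stim[0], dt,
                              fmax, lopt, lslack, penn, vmax, lref, arm,
                              tact, tdeact, flw, fvK, fvN, see_eps, dmp,
                              momL, fseeL, lceL)
        for j in range(3):
            phi[j] = q[6 + j]
        nclip += muscles_step(phi, lce[1], act[1], stim[1], dt,
                              fmax, lopt, lslack, penn, vmax, lref, arm,
                              tact, tdeact, flw, fvK, fvN, see_eps, dmp,
                              momR, fseeR, lceR)
        for m in range(N_MUS):
            fhist[n, 0, m] = fseeL[m]
            fhist[n, 1, m] = fseeR[m]
            lhist[n, 0, m] = lceL[m]
            lhist[n, 1, m] = lceR[m]

        for j in range(3):
            tau[j] = momL[j]
            tau[3 + j] = momR[j]
        joint_stop_torques(q, qd, jlo, jhi, ks, cs, stop)
        for j in range(6):
            tau[j] += stop[j]
        if n < n_pd:
            for j in range(6):
                tau[j] += pd_kp[j] * (q_ref[3 + j] - q[3 + j]) \
                    - pd_kd[j] * qd[3 + j]

        grf = contact_forces_anchored(pts, vel, plat_x, plat_v, anchors,
                                      cactive, kc, cc, mu)
        qdd = plant_solve(q, qd, tau, grf, A, m7, I7, pts, J, bias,
                          vel, grav)

        ankle_rel = 0.5 * (pts[PT_ANKLE_L, 0] + pts[PT_ANKLE_R, 0]) \
            - plat_x - ax_ref

        if n % log_every == 0:
            log_t[n_logged] = t
            for j in range(3):
                log_ang[n_logged, j] = 0.5 * (q[3 + j] + q[6 + j])
                log_mom[n_logged, j] = 0.5 * (momL[j] + momR[j])
            log_com[n_logged, 0] = cx
            log_com[n_logged, 1] = cy
            log_chest[n_logged] = chest_y
            log_ankx[n_logged] = ankle_rel if n >= onset else 0.0
            log_grfy[n_logged] = grf[0, 1] + grf[1, 1] + grf[2, 1] + grf[3, 1]
            for m in range(N_MUS):
                log_act[n_logged, m] = 0.5 * (act[0, m] + act[1, m])
            log_plat[n_logged] = plat_x
            log_trunk[n_logged, 0] = q[0]
            log_trunk[n_logged, 1] = q[1]
            log_trunk[n_logged, 2] = q[2]
            n_logged += 1

        if onset <= n < onset + n_horizon:
            ssq = 0.0
            for leg in range(2):
                for m in range(N_MUS):
                    ssq += act[leg, m] * act[leg, m]
            effort_sum += ssq * dt
            a_exc = ankle_rel if ankle_rel >= 0.0 else -ankle_rel
            exc_sum += a_exc * dt

        # --- integrate (semi-implicit Euler) ---
        bad = 0
        for a in range(N_Q):
            if not np.isfinite(qdd[a]):
                bad = 1
        if bad == 1:
            fell = 2
            survived = t
            break
        for a in range(N_Q):
            qd[a] += dt * qdd[a]
            q[a] += dt * qd[a]
        survived = t + dt

        if chest_y < chest_fall:
            fell = 1
            break

    return (log_t[:n_logged], log_ang[:n_logged], log_mom[:n_logged],
            log_com[:n_logged], log_chest[:n_logged], log_ankx[:n_logged],
            log_grfy[:n_logged], log_act[:n_logged], log_plat[:n_logged],
            log_trunk[:n_logged],
            survived, fell, effort_sum, exc_sum, final_chest, nclip,
            edges_ok, q, qd, lce, act)
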