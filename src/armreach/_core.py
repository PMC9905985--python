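"""Compiled numerical kernels for the reaching simulator.

Everything here is numba-compiled and operates on plain float64 arrays so
that the 1 kHz predictive control loop (which re-integrates the arm model
inside every control period) stays affordable.  The public modules
(:mod:`armreach.arm`, :mod:`armreach.muscle`, :mod:`armreach.simulate`, ...)
are thin wrappers around these kernels; there is a single source of truth
for the equations of motion and the muscle model.

Parameter packing
-----------------
The model parameters travel as a tuple ``P``::

    P = (arm, A, fmax, l0, rmom, qinit, jidx, passive, misc)

``arm``     (6, 3): rows = segment lengths L, masses m, inertias I (about
            each segment's centre of mass), COM offsets c, joint lower
            limits, joint upper limits.
``A``       (3, 3): constant inertia coupling matrix of the planar chain in
            absolute segment angles (see :func:`mass_bias`).
``fmax``    (6,)  maximum isometric forces, N.
``l0``      (6,)  optimal muscle lengths, m.
``rmom``    (6,)  signed constant moment arms, m (flexor +, extensor −).
``qinit``   (3,)  reference joint angles at which every muscle sits at its
            optimal length (the initial posture).
``jidx``    (6,)  joint index each muscle spans.
``passive`` (3,)  passive-curve triple (s_p, r_p, l_p).
``misc``    (9,)  [k_lim, c_lim, tau_act, v_max, gamma_fl,
                   ecc_gain, ecc_shape, conc_shape, fa_floor]

State vector (24,): q (3), qdot (3), then for each of the six muscles the
three states of the activation chain (a1, a2, a3); activation a == a3.
"""

import numpy as np
from numba import njit

# misc[] layout indices
K_LIM, C_LIM, TAU_ACT, V_MAX, GAMMA_FL, ECC_GAIN, ECC_SHAPE, CONC_SHAPE, FA_FLOOR = range(9)

NQ = 3
NMUS = 6
NSTATE = 2 * NQ + 3 * NMUS


@njit(cache=True)
def fk(q, L):
    """Endpoint of the 3-link chain (shoulder at the origin)."""
    th = 0.0
    x = 0.0
    y = 0.0
    for j in range(NQ):
        th += q[j]
        x += L[j] * np.cos(th)
        y += L[j] * np.sin(th)
    return x, y


@njit(cache=True)
def jacobian(q, L):
    """2x3 endpoint Jacobian (analytic)."""
    J = np.zeros((2, NQ))
    th = np.zeros(NQ)
    t = 0.0
    for j in range(NQ):
        t += q[j]
        th[j] = t
    for j in range(NQ):
        sx = 0.0
        sy = 0.0
        for k in range(j, NQ):
            sx += -L[k] * np.sin(th[k])
            sy += L[k] * np.cos(th[k])
        J[0, j] = sx
        J[1, j] = sy
    return J


@njit(cache=True)
def mass_bias(q, qd, arm, A):
    """Joint-space mass matrix M(q) and Coriolis/centrifugal vector h(q, qd).

    Derived from the Lagrangian of the planar chain in absolute segment
    angles theta_i = sum_{j<=i} q_j, where the kinetic energy couples
    segments through the constant matrix
    ``A[j,l] = sum_k m_k beta_kj beta_kl`` with ``beta_kj = L_j`` for j < k,
    ``c_k`` for j == k, 0 otherwise.  In those coordinates

        tau_theta = (A o cos(dth) + diag(I)) thetadd + (A o sin(dth)) thd^2

    and the joint-space form follows from theta = T q with T lower
    triangular of ones: M_q = T' M_theta T, h_q = T' h_theta.
    """
    I = arm[2]
    th = np.zeros(NQ)
    t = 0.0
    for j in range(NQ):
        t += q[j]
        th[j] = t
    thd = np.zeros(NQ)
    t = 0.0
    for j in range(NQ):
        t += qd[j]
        thd[j] = t
    Mth = np.zeros((NQ, NQ))
    hth = np.zeros(NQ)
    for j in range(NQ):
        for l in range(NQ):
            d = th[j] - th[l]
            Mth[j, l] = A[j, l] * np.cos(d)
            hth[j] += A[j, l] * np.sin(d) * thd[l] * thd[l]
        Mth[j, j] += I[j]
    # M_q = T' Mth T ; h_q = T' hth  with T[i,j] = 1 for j <= i
    Mq = np.zeros((NQ, NQ))
    hq = np.zeros(NQ)
    for a in range(NQ):
        for b in range(NQ):
            s = 0.0
            for i in range(a, NQ):
                for j in range(b, NQ):
                    s += Mth[i, j]
            Mq[a, b] = s
        s = 0.0
        for i in range(a, NQ):
            s += hth[i]
        hq[a] = s
    return Mq, hq


@njit(cache=True)
def inverse_dynamics(q, qd, qdd, arm, A):
    Mq, hq = mass_bias(q, qd, arm, A)
    return Mq @ qdd + hq


@njit(cache=True)
def limit_torque(q, qd, arm, misc):
    """One-sided penalty + damping engaged only beyond a joint limit."""
    qmin = arm[4]
    qmax = arm[5]
    tau = np.zeros(NQ)
    for j in range(NQ):
        if q[j] > qmax[j]:
            tau[j] = -misc[K_LIM] * (q[j] - qmax[j]) - misc[C_LIM] * qd[j]
        elif q[j] < qmin[j]:
            tau[j] = -misc[K_LIM] * (q[j] - qmin[j]) - misc[C_LIM] * qd[j]
    return tau


@njit(cache=True)
def passive_force(lbar, sp, rp, lp):
    if lbar > lp:
        return sp * (np.exp(rp * (lbar - lp)) - 1.0)
    return 0.0


@njit(cache=True)
def force_length(lbar, gamma):
    d = lbar - 1.0
    return np.exp(-d * d / gamma)


@njit(cache=True)
def force_velocity(lbardot, misc):
    """Normalized force-velocity factor; argument is d(l/l0)/dt in 1/s."""
    v = lbardot / misc[V_MAX]
    if v >= 0.0:  # lengthening
        return 1.0 + misc[ECC_GAIN] * v / (v + misc[ECC_SHAPE])
    s = -v  # shortening, fraction of v_max
    if s >= 1.0:
        return 0.0
    return (1.0 - s) / (1.0 + s / misc[CONC_SHAPE])


@njit(cache=True)
def muscle_kinematics(q, qd, l0, rmom, qinit, jidx):
    """Normalized lengths and their rates for all six muscles."""
    lbar = np.zeros(NMUS)
    lbardot = np.zeros(NMUS)
    for i in range(NMUS):
        j = jidx[i]
        rho = rmom[i] / l0[i]
        lbar[i] = 1.0 - rho * (q[j] - qinit[j])
        lbardot[i] = -rho * qd[j]
    return lbar, lbardot


@njit(cache=True)
def muscle_forces(q, qd, act, fmax, l0, rmom, qinit, jidx, passive, misc):
    """Total force (N) of each muscle at activations ``act``."""
    lbar, lbardot = muscle_kinematics(q, qd, l0, rmom, qinit, jidx)
    f = np.zeros(NMUS)
    for i in range(NMUS):
        fa = force_length(lbar[i], misc[GAMMA_FL]) * force_velocity(lbardot[i], misc)
        fp = passive_force(lbar[i], passive[0], passive[1], passive[2])
        a = min(max(act[i], 0.0), 1.0)
        f[i] = fmax[i] * (fa * a + fp)
        if f[i] < 0.0:
            f[i] = 0.0
    return f


@njit(cache=True)
def rhs(x, u, P):
    """Time derivative of the full 24-state (arm + activation chains)."""
    arm, A, fmax, l0, rmom, qinit, jidx, passive, misc = P
    q = x[0:NQ]
    qd = x[NQ:2 * NQ]
    act = np.zeros(NMUS)
    for i in range(NMUS):
        act[i] = x[2 * NQ + 3 * i + 2]
    f = muscle_forces(q, qd, act, fmax, l0, rmom, qinit, jidx, passive, misc)
    tau = limit_torque(q, qd, arm, misc)
    for i in range(NMUS):
        tau[jidx[i]] += f[i] * rmom[i]
    Mq, hq = mass_bias(q, qd, arm, A)
    qdd = np.linalg.solve(Mq, tau - hq)
    dx = np.zeros(NSTATE)
    for j in range(NQ):
        dx[j] = qd[j]
        dx[NQ + j] = qdd[j]
    inv_tau = 1.0 / misc[TAU_ACT]
    for i in range(NMUS):
        b = 2 * NQ + 3 * i
        ui = min(max(u[i], 0.0), 1.0)
        dx[b] = (ui - x[b]) * inv_tau
        dx[b + 1] = (x[b] - x[b + 1]) * inv_tau
        dx[b + 2] = (x[b + 1] - x[b + 2]) * inv_tau
    return dx


@njit(cache=True, fastmath=False)
def _rhs_into(x, u, arm, A, fmax, l0, rmom, qinit, jidx, passive, misc, dx):
    """Fused, allocation-free evaluation of :func:`rhs` (identical maths).

    Everything is scalarized for the fixed sizes (3 joints, 6 muscles);
    the 3x3 mass-matrix solve uses Cramer's rule (M is well-conditioned
    for positive inertias).  A consistency test asserts agreement with
    the reference :func:`rhs` to machine precision.
    """
    q0 = x[0]
    q1 = x[1]
    q2 = x[2]
    qd0 = x[3]
    qd1 = x[4]
    qd2 = x[5]
    th0 = q0
    th1 = q0 + q1
    th2 = q0 + q1 + q2
    td0 = qd0
    td1 = qd0 + qd1
    td2 = qd0 + qd1 + qd2

    # absolute-angle mass matrix and velocity-product terms
    c01 = np.cos(th0 - th1)
    c02 = np.cos(th0 - th2)
    c12 = np.cos(th1 - th2)
    s01 = np.sin(th0 - th1)
    s02 = np.sin(th0 - th2)
    s12 = np.sin(th1 - th2)
    I0 = arm[2, 0]
    I1 = arm[2, 1]
    I2 = arm[2, 2]
    m00 = A[0, 0] + I0
    m11 = A[1, 1] + I1
    m22 = A[2, 2] + I2
    m01 = A[0, 1] * c01
    m02 = A[0, 2] * c02
    m12 = A[1, 2] * c12
    h0 = A[0, 1] * s01 * td1 * td1 + A[0, 2] * s02 * td2 * td2
    h1 = -A[0, 1] * s01 * td0 * td0 + A[1, 2] * s12 * td2 * td2
    h2 = -A[0, 2] * s02 * td0 * td0 - A[1, 2] * s12 * td1 * td1

    # joint-space form via theta = T q (T lower-triangular of ones)
    Mq00 = m00 + m11 + m22 + 2.0 * (m01 + m02 + m12)
    Mq01 = m11 + m22 + m01 + m02 + 2.0 * m12
    Mq02 = m22 + m02 + m12
    Mq11 = m11 + m22 + 2.0 * m12
    Mq12 = m22 + m12
    Mq22 = m22
    b0 = h0 + h1 + h2
    b1 = h1 + h2
    b2 = h2

    # muscle torques and activation-chain derivatives
    tau0 = 0.0
    tau1 = 0.0
    tau2 = 0.0
    sp = passive[0]
    rp = passive[1]
    lp = passive[2]
    inv_tau = 1.0 / misc[TAU_ACT]
    gamma = misc[GAMMA_FL]
    for i in range(NMUS):
        j = jidx[i]
        if j == 0:
            qj = q0
            qdj = qd0
        elif j == 1:
            qj = q1
            qdj = qd1
        else:
            qj = q2
            qdj = qd2
        rho = rmom[i] / l0[i]
        lbar = 1.0 - rho * (qj - qinit[j])
        lbardot = -rho * qdj
        d = lbar - 1.0
        fl = np.exp(-d * d / gamma)
        v = lbardot / misc[V_MAX]
        if v >= 0.0:
            fv = 1.0 + misc[ECC_GAIN] * v / (v + misc[ECC_SHAPE])
        else:
            s = -v
            if s >= 1.0:
                fv = 0.0
            else:
                fv = (1.0 - s) / (1.0 + s / misc[CONC_SHAPE])
        fp = 0.0
        if lbar > lp:
            fp = sp * (np.exp(rp * (lbar - lp)) - 1.0)
        a = x[2 * NQ + 3 * i + 2]
        if a < 0.0:
            a = 0.0
        elif a > 1.0:
            a = 1.0
        f = fmax[i] * (fl * fv * a + fp)
        if f < 0.0:
            f = 0.0
        t = f * rmom[i]
        if j == 0:
            tau0 += t
        elif j == 1:
            tau1 += t
        else:
            tau2 += t
        base = 2 * NQ + 3 * i
        ui = u[i]
        if ui < 0.0:
            ui = 0.0
        elif ui > 1.0:
            ui = 1.0
        dx[base] = (ui - x[base]) * inv_tau
        dx[base + 1] = (x[base] - x[base + 1]) * inv_tau
        dx[base + 2] = (x[base + 1] - x[base + 2]) * inv_tau

    # one-sided joint-limit penalties
    k_lim = misc[K_LIM]
    c_lim = misc[C_LIM]
    if q0 > arm[5, 0]:
        tau0 += -k_lim * (q0 - arm[5, 0]) - c_lim * qd0
    elif q0 < arm[4, 0]:
        tau0 += -k_lim * (q0 - arm[4, 0]) - c_lim * qd0
    if q1 > arm[5, 1]:
        tau1 += -k_lim * (q1 - arm[5, 1]) - c_lim * qd1
    elif q1 < arm[4, 1]:
        tau1 += -k_lim * (q1 - arm[4, 1]) - c_lim * qd1
    if q2 > arm[5, 2]:
        tau2 += -k_lim * (q2 - arm[5, 2]) - c_lim * qd2
    elif q2 < arm[4, 2]:
        tau2 += -k_lim * (q2 - arm[4, 2]) - c_lim * qd2

    r0 = tau0 - b0
    r1 = tau1 - b1
    r2 = tau2 - b2
    # Cramer's rule on the symmetric 3x3 system
    det = (Mq00 * (Mq11 * Mq22 - Mq12 * Mq12)
           - Mq01 * (Mq01 * Mq22 - Mq12 * Mq02)
           + Mq02 * (Mq01 * Mq12 - Mq11 * Mq02))
    qdd0 = (r0 * (Mq11 * Mq22 - Mq12 * Mq12)
            - Mq01 * (r1 * Mq22 - Mq12 * r2)
            + Mq02 * (r1 * Mq12 - Mq11 * r2)) / det
    qdd1 = (Mq00 * (r1 * Mq22 - r2 * Mq12)
            - r0 * (Mq01 * Mq22 - Mq12 * Mq02)
            + Mq02 * (Mq01 * r2 - r1 * Mq02)) / det
    qdd2 = (Mq00 * (Mq11 * r2 - Mq12 * r1)
            - Mq01 * (Mq01 * r2 - r1 * Mq02)
            + r0 * (Mq01 * Mq12 - Mq11 * Mq02)) / det
    dx[0] = qd0
    dx[1] = qd1
    dx[2] = qd2
    dx[3] = qdd0
    dx[4] = qdd1
    dx[5] = qdd2


@njit(cache=True)
def rk4(x, u, h, n, P):
    """n classical Runge-Kutta steps of size h with zero-order-hold u."""
    arm, A, fmax, l0, rmom, qinit, jidx, passive, misc = P
    y = x.copy()
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    tmp = np.empty(NSTATE)
    for _ in range(n):
        _rhs_into(y, u, arm, A, fmax, l0, rmom, qinit, jidx, passive, misc, k1)
        for s in range(NSTATE):
            tmp[s] = y[s] + 0.5 * h * k1[s]
        _rhs_into(tmp, u, arm, A, fmax, l0, rmom, qinit, jidx, passive, misc, k2)
        for s in range(NSTATE):
            tmp[s] = y[s] + 0.5 * h * k2[s]
        _rhs_into(tmp, u, arm, A, fmax, l0, rmom, qinit, jidx, passive, misc, k3)
        for s in range(NSTATE):
            tmp[s] = y[s] + h * k3[s]
        _rhs_into(tmp, u, arm, A, fmax, l0, rmom, qinit, jidx, passive, misc, k4)
        for s in range(NSTATE):
            y[s] = y[s] + (h / 6.0) * (k1[s] + 2.0 * k2[s] + 2.0 * k3[s] + k4[s])
    return y


@njit(cache=True)
def excitations_from_torques(x, tau_des, c_lag, P):
    """Invert desired joint torques to muscle excitations (no co-excitation).

    Per joint: subtract the torque already produced passively at the
    (predicted) state, pick the agonist whose moment arm matches the sign of
    the remaining active torque, convert to a required activation through
    the active force scaling at the current operating point, and apply a
    first-order lead to compensate the activation lag.  The antagonist is
    never excited at the same step.
    """
    arm, A, fmax, l0, rmom, qinit, jidx, passive, misc = P
    q = x[0:NQ]
    qd = x[NQ:2 * NQ]
    lbar, lbardot = muscle_kinematics(q, qd, l0, rmom, qinit, jidx)
    u = np.zeros(NMUS)
    for j in range(NQ):
        fi = 2 * j       # flexor index
        ei = 2 * j + 1   # extensor index
        tau_p = 0.0
        for i in (fi, ei):
            tau_p += fmax[i] * passive_force(lbar[i], passive[0], passive[1], passive[2]) * rmom[i]
        tau_a = tau_des[j] - tau_p
        if tau_a >= 0.0:
            ag = fi
        else:
            ag = ei
        F = tau_a / rmom[ag]  # ≥ 0 by the sign choice
        fa = force_length(lbar[ag], misc[GAMMA_FL]) * force_velocity(lbardot[ag], misc)
        if fa < misc[FA_FLOOR]:
            fa = misc[FA_FLOOR]
        a_req = F / (fmax[ag] * fa)
        if a_req < 0.0:
            a_req = 0.0
        elif a_req > 1.0:
            a_req = 1.0
        a_cur = x[2 * NQ + 3 * ag + 2]
        uu = a_req + c_lag * (a_req - a_cur)
        if uu < 0.0:
            uu = 0.0
        elif uu > 1.0:
            uu = 1.0
        u[ag] = uu
    return u


@njit(cache=True)
def ik_reference(path_x, path_v, w_goal, q0, q_goal, L, qmin, qmax, dt, k_fb,
                 lam, k_null):
    """Joint-space reference from a planned endpoint path.

    Damped-least-squares differential inverse kinematics with endpoint
    feedback, integrated at the control rate.  The one-DOF redundancy of
    the 3-link planar arm is resolved by minimum joint velocity plus a
    nullspace bias (gain ``k_null``, ramped along the path by ``w_goal``)
    toward ``q_goal`` — a feasible
    configuration reaching the target, precomputed by the caller — which
    steers the reference onto the correct configuration branch instead of
    letting clamped-greedy IK get trapped at a joint limit.  The
    reference is clamped to the limits.
    """
    n = path_x.shape[0]
    qr = np.zeros((n, NQ))
    q = q0.copy()
    lam2 = lam * lam
    qdn = np.zeros(NQ)
    jv = np.zeros(NQ)
    for k in range(n):
        qr[k] = q
        if k == n - 1:
            break
        px, py = fk(q, L)
        vx = path_v[k, 0] + k_fb * (path_x[k, 0] - px)
        vy = path_v[k, 1] + k_fb * (path_x[k, 1] - py)
        J = jacobian(q, L)
        # qd = J+ v + (I - J+ J) qd_null with damped pseudoinverse
        # (2x2 solve, explicit)
        a11 = lam2
        a12 = 0.0
        a22 = lam2
        for j in range(NQ):
            a11 += J[0, j] * J[0, j]
            a12 += J[0, j] * J[1, j]
            a22 += J[1, j] * J[1, j]
        det = a11 * a22 - a12 * a12
        w1 = (a22 * vx - a12 * vy) / det
        w2 = (-a12 * vx + a11 * vy) / det
        # nullspace velocity toward the goal configuration, ramped with
        # path progress so early motion stays minimum-velocity
        kw = k_null * w_goal[k]
        for j in range(NQ):
            qdn[j] = kw * (q_goal[j] - q[j])
        # project: qd_null - J+ (J qd_null)
        bx = 0.0
        by = 0.0
        for j in range(NQ):
            bx += J[0, j] * qdn[j]
            by += J[1, j] * qdn[j]
        n1 = (a22 * bx - a12 * by) / det
        n2 = (-a12 * bx + a11 * by) / det
        for j in range(NQ):
            jv[j] = J[0, j] * (w1 - n1) + J[1, j] * (w2 - n2) + qdn[j]
            q[j] = q[j] + dt * jv[j]
            if q[j] < qmin[j]:
                q[j] = qmin[j]
            elif q[j] > qmax[j]:
                q[j] = qmax[j]
    return qr


@njit(cache=True)
def reach(x0, qr, qdr, qddr, kp, kd, n_pred, dt, n_sub, P):
    """Closed-loop simulation of one reach.

    qr/qdr/qddr: reference joint trajectory sampled at the control rate over
    the whole horizon (held at the final sample beyond the plan).  Returns
    time series sampled at the control rate: q, qd, endpoint, activations,
    excitations, normalized lengths, total forces.
    """
    arm, A, fmax, l0, rmom, qinit, jidx, passive, misc = P
    L = arm[0]
    n = qr.shape[0]
    tau_act = misc[TAU_ACT]
    t_pred = n_pred * dt
    if t_pred < dt:
        t_pred = dt
    c_lag = 3.0 * tau_act / t_pred - 1.0
    if c_lag < 0.0:
        c_lag = 0.0
    h = dt / n_sub

    Q = np.zeros((n, NQ))
    QD = np.zeros((n, NQ))
    EP = np.zeros((n, 2))
    ACT = np.zeros((n, NMUS))
    EXC = np.zeros((n, NMUS))
    LBAR = np.zeros((n, NMUS))
    FTOT = np.zeros((n, NMUS))

    x = x0.copy()
    u = np.zeros(NMUS)
    ok = True
    for k in range(n):
        q = x[0:NQ]
        qd = x[NQ:2 * NQ]
        Q[k] = q
        QD[k] = qd
        ex, ey = fk(q, L)
        EP[k, 0] = ex
        EP[k, 1] = ey
        act = np.zeros(NMUS)
        for i in range(NMUS):
            act[i] = x[2 * NQ + 3 * i + 2]
        ACT[k] = act
        lb, _ = muscle_kinematics(q, qd, l0, rmom, qinit, jidx)
        LBAR[k] = lb
        FTOT[k] = muscle_forces(q, qd, act, fmax, l0, rmom, qinit, jidx, passive, misc)
        if k == n - 1:
            break
        if not ok:
            EXC[k] = u
            continue
        # predict the state over the prediction horizon holding current u
        xp = x
        if n_pred > 0:
            xp = rk4(x, u, dt, n_pred, P)
        idx = k + n_pred
        if idx > n - 1:
            idx = n - 1
        tau_ff = inverse_dynamics(qr[idx], qdr[idx], qddr[idx], arm, A)
        tau_des = np.zeros(NQ)
        for j in range(NQ):
            tau_des[j] = tau_ff[j] + kp[j] * (qr[idx, j] - xp[j]) + kd[j] * (qdr[idx, j] - xp[NQ + j])
        u = excitations_from_torques(xp, tau_des, c_lag, P)
        EXC[k] = u
        x = rk4(x, u, h, n_sub, P)
        bad = False
        for s in range(NSTATE):
            if not np.isfinite(x[s]):
                bad = True
        if bad:
            ok = False
            x = np.zeros(NSTATE)
            x[0:NQ] = Q[k]
            x[NQ:2 * NQ] = 0.0
    return Q, QD, EP, ACT, EXC, LBAR, FTOT, ok
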