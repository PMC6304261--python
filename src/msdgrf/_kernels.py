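"""Compiled numerical kernels.

The waveform-fitting objectives call the fixed-step RK4 integrator tens of
thousands of times per trial, so the integrator and both objectives are
compiled with numba.  The public API in :mod:`msdgrf.model` and
:mod:`msdgrf.fitting` wraps these kernels; nothing here validates input.

State layout: (p1, p2, v1, v2); parameter layout:
(p1, p2, v1, v2, omega1_sq, omega2_sq, lam, zeta).
"""

import numpy as np
from numba import njit

# Integration is declared diverged once any state magnitude passes this
# bound (metres / m s^-1 scales here are < 10 for any physical stance).
DIVERGENCE_LIMIT = 1e6

# Objective value returned for diverged / unphysical parameter probes;
# far above any physical RMSE in g or N/kg so line searches back away.
PENALTY = 1e6

G_PER_MS2 = 9.81  # 1 g, for unit conversion of accelerations


@njit(cache=True)
def rk4_path(p1_0, p2_0, v1_0, v2_0, w1, w2, lam, zeta, g, dt, n_steps):
    """Classic fixed-step RK4 for the two-mass model.

    Returns (p1, p2, v1, v2, n_valid) where each array has n_steps + 1
    entries and n_valid is the number of finite states actually produced
    (n_steps + 1 on success; entries beyond n_valid are unspecified).
    """
    n = n_steps + 1
    P1 = np.empty(n)
    P2 = np.empty(n)
    V1 = np.empty(n)
    V2 = np.empty(n)
    P1[0] = p1_0
    P2[0] = p2_0
    V1[0] = v1_0
    V2[0] = v2_0
    tz = 2.0 * zeta * np.sqrt(w2)  # 2*zeta*omega2: damping per unit velocity
    p1 = p1_0
    p2 = p2_0
    v1 = v1_0
    v2 = v2_0
    for i in range(n_steps):
        # stage 1
        a1_1 = -w1 * (p1 - p2) + g
        a2_1 = -w2 * p2 + w1 * lam * (p1 - p2) - tz * v2 + g
        # stage 2 (half step using stage-1 slopes)
        hp1 = p1 + 0.5 * dt * v1
        hp2 = p2 + 0.5 * dt * v2
        hv1 = v1 + 0.5 * dt * a1_1
        hv2 = v2 + 0.5 * dt * a2_1
        a1_2 = -w1 * (hp1 - hp2) + g
        a2_2 = -w2 * hp2 + w1 * lam * (hp1 - hp2) - tz * hv2 + g
        # stage 3
        qp1 = p1 + 0.5 * dt * hv1
        qp2 = p2 + 0.5 * dt * hv2
        qv1 = v1 + 0.5 * dt * a1_2
        qv2 = v2 + 0.5 * dt * a2_2
        a1_3 = -w1 * (qp1 - qp2) + g
        a2_3 = -w2 * qp2 + w1 * lam * (qp1 - qp2) - tz * qv2 + g
        # stage 4 (full step)
        fp1 = p1 + dt * qv1
        fp2 = p2 + dt * qv2
        fv1 = v1 + dt * a1_3
        fv2 = v2 + dt * a2_3
        a1_4 = -w1 * (fp1 - fp2) + g
        a2_4 = -w2 * fp2 + w1 * lam * (fp1 - fp2) - tz * fv2 + g

        p1 = p1 + dt / 6.0 * (v1 + 2.0 * hv1 + 2.0 * qv1 + fv1)
        p2 = p2 + dt / 6.0 * (v2 + 2.0 * hv2 + 2.0 * qv2 + fv2)
        v1 = v1 + dt / 6.0 * (a1_1 + 2.0 * a1_2 + 2.0 * a1_3 + a1_4)
        v2 = v2 + dt / 6.0 * (a2_1 + 2.0 * a2_2 + 2.0 * a2_3 + a2_4)
        if (
            not (np.isfinite(p1) and np.isfinite(p2) and np.isfinite(v1) and np.isfinite(v2))
            or abs(p1) > DIVERGENCE_LIMIT
            or abs(p2) > DIVERGENCE_LIMIT
        ):
            return P1, P2, V1, V2, i + 1
        P1[i + 1] = p1
        P2[i + 1] = p2
        V1[i + 1] = v1
        V2[i + 1] = v2
    return P1, P2, V1, V2, n


@njit(cache=True)
def _params_invalid(x, M):
    return (
        x[4] < 0.0  # omega1_sq (zero allowed: absent upper spring)
        or x[5] <= 0.0  # omega2_sq
        or x[6] <= 0.0  # lam
        or x[7] < 0.0  # zeta
        or M <= 0.0
    )


@njit(cache=True)
def acc_objective(x, M, g, dt, n_steps, t_target, target):
    """RMSE (g) between the model upper-mass proper acceleration and a
    measured trunk-accelerometer stance segment sampled at t_target."""
    if _params_invalid(x, M):
        return PENALTY
    P1, P2, V1, V2, n_valid = rk4_path(
        x[0], x[1], x[2], x[3], x[4], x[5], x[6], x[7], g, dt, n_steps
    )
    if n_valid < n_steps + 1:
        return PENALTY
    w1 = x[4]
    acc = -(w1 / G_PER_MS2) * (P1 - P2)  # (a1 - g)/|g|: proper acceleration in g
    t_model = np.arange(n_steps + 1) * dt
    model_at_target = np.interp(t_target, t_model, acc)
    s = 0.0
    for i in range(t_target.size):
        d = model_at_target[i] - target[i]
        s += d * d
    return np.sqrt(s / t_target.size)


@njit(cache=True)
def grf_objective(x, M, g, dt, n_steps, t_target, target):
    """RMSE (N/kg) between the model GRF and a measured, body-mass
    normalised GRF stance segment sampled at t_target."""
    if _params_invalid(x, M):
        return PENALTY
    P1, P2, V1, V2, n_valid = rk4_path(
        x[0], x[1], x[2], x[3], x[4], x[5], x[6], x[7], g, dt, n_steps
    )
    if n_valid < n_steps + 1:
        return PENALTY
    w2 = x[5]
    lam = x[6]
    zeta = x[7]
    om2 = np.sqrt(w2)
    # per-kg spring and damper coefficients: k2/M and c/M
    k2_per_m = w2 / (1.0 + lam)
    c_per_m = 2.0 * zeta * om2 / (1.0 + lam)
    grf = -(k2_per_m * P2 + c_per_m * V2)
    t_model = np.arange(n_steps + 1) * dt
    model_at_target = np.interp(t_target, t_model, grf)
    s = 0.0
    for i in range(t_target.size):
        d = model_at_target[i] - target[i]
        s += d * d
    return np.sqrt(s / t_target.size)


@njit(cache=True)
def acc_objective_batch(X, M, g, dt, n_steps, t_target, target):
    """acc_objective for each row of X (m, 8); returns an m-vector."""
    out = np.empty(X.shape[0])
    for j in range(X.shape[0]):
        out[j] = acc_objective(X[j], M, g, dt, n_steps, t_target, target)
    return out


@njit(cache=True)
def grf_objective_batch(X, M, g, dt, n_steps, t_target, target):
    """grf_objective for each row of X (m, 8); returns an m-vector."""
    out = np.empty(X.shape[0])
    for j in range(X.shape[0]):
        out[j] = grf_objective(X[j], M, g, dt, n_steps, t_target, target)
    return out
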