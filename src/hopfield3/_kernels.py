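"""Compiled inner loops: fixed-step RK4 and Benettin tangent evolution.

Everything here works on plain float64 arrays so the loops can be jitted
with numba when it is available; without numba the same functions run as
ordinary Python (slow but correct), keeping the package importable anywhere.

A trajectory is flagged divergent as soon as any component leaves
[-DIVERGENCE_BOUND, DIVERGENCE_BOUND]; the kernels return the step index of
the blow-up (or -1) instead of raising, and the wrappers in
:mod:`hopfield3.integrate` turn that into an exception.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every simulation test
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


#: States beyond this magnitude are treated as numerical divergence.  The
#: tanh couplings bound every attractor of the network well inside |x| < 20,
#: so this only triggers on genuinely escaping orbits.
DIVERGENCE_BOUND = 1.0e6


@njit(cache=True)
def _deriv3(x, w, beta, i1, out):
    a0 = np.tanh(beta[0] * x[0])
    a1 = np.tanh(beta[1] * x[1])
    a2 = np.tanh(beta[2] * x[2])
    out[0] = -x[0] + w[0, 0] * a0 + w[0, 1] * a1 + w[0, 2] * a2 + i1
    out[1] = -x[1] + w[1, 0] * a0 + w[1, 1] * a1 + w[1, 2] * a2
    out[2] = -x[2] + w[2, 0] * a0 + w[2, 1] * a1 + w[2, 2] * a2


@njit(cache=True)
def rk4_trajectory(x0, w, beta, i1, dt, n_steps):
    """Integrate the 3D network for ``n_steps`` RK4 steps.

    Returns ``(states, bad_step)`` where states has shape
    ``(n_steps + 1, 3)`` (row 0 is ``x0``) and ``bad_step`` is the first
    step index at which the state left the divergence bound, or -1.
    """
    out = np.empty((n_steps + 1, 3))
    out[0] = x0
    x = x0.copy()
    k1 = np.empty(3)
    k2 = np.empty(3)
    k3 = np.empty(3)
    k4 = np.empty(3)
    tmp = np.empty(3)
    for n in range(n_steps):
        _deriv3(x, w, beta, i1, k1)
        for i in range(3):
            tmp[i] = x[i] + 0.5 * dt * k1[i]
        _deriv3(tmp, w, beta, i1, k2)
        for i in range(3):
            tmp[i] = x[i] + 0.5 * dt * k2[i]
        _deriv3(tmp, w, beta, i1, k3)
        for i in range(3):
            tmp[i] = x[i] + dt * k3[i]
        _deriv3(tmp, w, beta, i1, k4)
        for i in range(3):
            x[i] = x[i] + (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        out[n + 1] = x
        for i in range(3):
            if not (-DIVERGENCE_BOUND < x[i] < DIVERGENCE_BOUND):
                return out, n + 1
    return out, -1


@njit(cache=True)
def _deriv4(x, w, beta, i1, phi, eps, gamma, out):
    a0 = np.tanh(beta[0] * x[0])
    a1 = np.tanh(beta[1] * x[1])
    a2 = np.tanh(beta[2] * x[2])
    out[0] = -x[0] + w[0, 0] * a0 + w[0, 1] * a1 + w[0, 2] * a2 + i1
    out[1] = -x[1] + w[1, 0] * a0 + w[1, 1] * a1 + w[1, 2] * a2 + phi * x[3]
    out[2] = -x[2] + w[2, 0] * a0 + w[2, 1] * a1 + w[2, 2] * a2
    out[3] = -eps * x[3] - phi * (x[1] - gamma)


@njit(cache=True)
def rk4_trajectory_aug(x0, w, beta, i1, phi, eps, gamma, dt, n_steps):
    """RK4 integration of the 4D linear-augmentation system."""
    out = np.empty((n_steps + 1, 4))
    out[0] = x0
    x = x0.copy()
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    tmp = np.empty(4)
    for n in range(n_steps):
        _deriv4(x, w, beta, i1, phi, eps, gamma, k1)
        for i in range(4):
            tmp[i] = x[i] + 0.5 * dt * k1[i]
        _deriv4(tmp, w, beta, i1, phi, eps, gamma, k2)
        for i in range(4):
            tmp[i] = x[i] + 0.5 * dt * k2[i]
        _deriv4(tmp, w, beta, i1, phi, eps, gamma, k3)
        for i in range(4):
            tmp[i] = x[i] + dt * k3[i]
        _deriv4(tmp, w, beta, i1, phi, eps, gamma, k4)
        for i in range(4):
            x[i] = x[i] + (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        out[n + 1] = x
        for i in range(4):
            if not (-DIVERGENCE_BOUND < x[i] < DIVERGENCE_BOUND):
                return out, n + 1
    return out, -1


@njit(cache=True)
def _jac3(x, w, beta, out):
    # analytic Jacobian: -I + w * diag(beta * sech^2(beta * x))
    for j in range(3):
        s = 1.0 - np.tanh(beta[j] * x[j]) ** 2
        col = beta[j] * s
        for i in range(3):
            out[i, j] = w[i, j] * col
    for i in range(3):
        out[i, i] -= 1.0


@njit(cache=True)
def _rhs_var(x, q, w, beta, i1, dx, dq, jac):
    _deriv3(x, w, beta, i1, dx)
    _jac3(x, w, beta, jac)
    for i in range(3):
        for j in range(3):
            acc = 0.0
            for k in range(3):
                acc += jac[i, k] * q[k, j]
            dq[i, j] = acc


@njit(cache=True)
def benettin_spectrum(x0, w, beta, i1, dt, n_steps, renorm_every):
    """Benettin/QR Lyapunov spectrum of the 3D flow.

    Co-integrates the state and a 3x3 tangent frame with RK4 (the tangent
    dynamics use the analytic Jacobian of the flow), re-orthonormalizing the
    frame by QR every ``renorm_every`` steps and accumulating log|R_ii|.

    Returns ``(log_sums, history, n_renorms, bad_step)``; ``history`` holds
    the running exponent estimates (one row per renormalization), and
    exponents are ``log_sums / (n_renorms * renorm_every * dt)``.
    """
    x = x0.copy()
    q = np.eye(3)
    log_sums = np.zeros(3)
    n_renorms = n_steps // renorm_every
    history = np.empty((n_renorms, 3))
    dx = np.empty(3)
    dq = np.empty((3, 3))
    jac = np.empty((3, 3))
    k1x = np.empty(3)
    k1q = np.empty((3, 3))
    k2x = np.empty(3)
    k2q = np.empty((3, 3))
    k3x = np.empty(3)
    k3q = np.empty((3, 3))
    k4x = np.empty(3)
    k4q = np.empty((3, 3))
    tx = np.empty(3)
    tq = np.empty((3, 3))
    step = 0
    for r in range(n_renorms):
        for _ in range(renorm_every):
            _rhs_var(x, q, w, beta, i1, k1x, k1q, jac)
            tx[:] = x + 0.5 * dt * k1x
            tq[:] = q + 0.5 * dt * k1q
            _rhs_var(tx, tq, w, beta, i1, k2x, k2q, jac)
            tx[:] = x + 0.5 * dt * k2x
            tq[:] = q + 0.5 * dt * k2q
            _rhs_var(tx, tq, w, beta, i1, k3x, k3q, jac)
            tx[:] = x + dt * k3x
            tq[:] = q + dt * k3q
            _rhs_var(tx, tq, w, beta, i1, k4x, k4q, jac)
            x += (dt / 6.0) * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
            q += (dt / 6.0) * (k1q + 2.0 * k2q + 2.0 * k3q + k4q)
            step += 1
            for i in range(3):
                if not (-DIVERGENCE_BOUND < x[i] < DIVERGENCE_BOUND):
                    return log_sums, history[:r], r, step
        qq, rr = np.linalg.qr(q)
        for i in range(3):
            d = rr[i, i]
            if d < 0.0:
                for j in range(3):
                    qq[j, i] = -qq[j, i]
                d = -d
            log_sums[i] += np.log(d)
        q = qq.copy()
        t_elapsed = (r + 1) * renorm_every * dt
        for i in range(3):
            history[r, i] = log_sums[i] / t_elapsed
    return log_sums, history, n_renorms, -1
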