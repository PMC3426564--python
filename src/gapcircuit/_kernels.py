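"""Compiled integration kernels for the circuit equations.

The right-hand side mirrors :mod:`gapcircuit.model` exactly (the tests assert
agreement); the kernels exist because parameter fitting evaluates on the
order of 10^5 trajectories, which rules out interpreter-level stepping.

Two steppers are provided over the same RHS:

* an adaptive Dormand-Prince 5(4) pair (``dp45_segment``) used for
  reference simulations (default rtol 1e-6 / atol 1e-8), and
* a fixed-step classical RK4 (``rk4_segment``) used inside the optimizer's
  objective, where per-evaluation cost dominates.

Both integrate a single rule segment [t0, t1] and are driven from Python so
that rule switches (interphase/mitosis), the division event and the output
times are hit exactly, never stepped over.
"""

import numpy as np
from numba import njit

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784,
                11 / 84, 0.0])
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200,
                187 / 2100, 1 / 40])


@njit(cache=True)
def _external_at(t, ext_t, ext_y, out):
    """Piecewise-linear time interpolation of anchored external inputs,
    clamped outside the anchor range.  ext_y: (n_e, n_t, n); out: (n_e, n)."""
    ne, nt, n = ext_y.shape
    if t <= ext_t[0]:
        for e in range(ne):
            for i in range(n):
                out[e, i] = ext_y[e, 0, i]
        return
    if t >= ext_t[nt - 1]:
        for e in range(ne):
            for i in range(n):
                out[e, i] = ext_y[e, nt - 1, i]
        return
    k = np.searchsorted(ext_t, t)
    w = (t - ext_t[k - 1]) / (ext_t[k] - ext_t[k - 1])
    for e in range(ne):
        for i in range(n):
            out[e, i] = (1.0 - w) * ext_y[e, k - 1, i] + w * ext_y[e, k, i]


@njit(cache=True)
def _rhs(t, v, Talpha, E, h, R, D, lam, active, synthesis,
         ext_t, ext_y, y_buf, out):
    """dv/dt for one rule; v, out: (n_g, n).  Inactive (null) gene rows are
    held at zero."""
    ng, n = v.shape
    ne = E.shape[1]
    if synthesis:
        _external_at(t, ext_t, ext_y, y_buf)
    for a in range(ng):
        if not active[a]:
            for i in range(n):
                out[a, i] = 0.0
            continue
        for i in range(n):
            dv = -lam[a] * v[a, i]
            if i > 0:
                dv += D[a] * (v[a, i - 1] - v[a, i])
            if i < n - 1:
                dv += D[a] * (v[a, i + 1] - v[a, i])
            if synthesis:
                u = h[a]
                for b in range(ng):
                    u += Talpha[a, b] * v[b, i]
                for e in range(ne):
                    u += E[a, e] * y_buf[e, i]
                dv += R[a] * 0.5 * (u / np.sqrt(1.0 + u * u) + 1.0)
            out[a, i] = dv
    return out


@njit(cache=True)
def rk4_segment(v, t0, t1, dt, Talpha, E, h, R, D, lam, active, synthesis,
                ext_t, ext_y):
    """Classical RK4 with fixed nominal step dt, adjusted to land exactly on
    t1.  Returns the state at t1 (v is not modified)."""
    ng, n = v.shape
    ne = E.shape[1]
    nsteps = max(1, int(np.ceil((t1 - t0) / dt - 1e-12)))
    hstep = (t1 - t0) / nsteps
    y_buf = np.empty((ne, n))
    k1 = np.empty((ng, n))
    k2 = np.empty((ng, n))
    k3 = np.empty((ng, n))
    k4 = np.empty((ng, n))
    w = v.copy()
    for s in range(nsteps):
        t = t0 + s * hstep
        _rhs(t, w, Talpha, E, h, R, D, lam, active, synthesis,
             ext_t, ext_y, y_buf, k1)
        _rhs(t + 0.5 * hstep, w + 0.5 * hstep * k1, Talpha, E, h, R, D, lam,
             active, synthesis, ext_t, ext_y, y_buf, k2)
        _rhs(t + 0.5 * hstep, w + 0.5 * hstep * k2, Talpha, E, h, R, D, lam,
             active, synthesis, ext_t, ext_y, y_buf, k3)
        _rhs(t + hstep, w + hstep * k3, Talpha, E, h, R, D, lam,
             active, synthesis, ext_t, ext_y, y_buf, k4)
        w += (hstep / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return w


@njit(cache=True)
def dp45_segment(v, t0, t1, Talpha, E, h, R, D, lam, active, synthesis,
                 ext_t, ext_y, rtol, atol):
    """Adaptive Dormand-Prince 5(4) over [t0, t1].

    Step size is controlled by the embedded 4th-order error estimate with a
    standard 0.9 * err^(-1/5) factor, clamped to [0.2, 5] per step, and is
    always shortened to end exactly at t1.  Returns the state at t1.
    """
    ng, n = v.shape
    ne = E.shape[1]
    y_buf = np.empty((ne, n))
    K = np.empty((7, ng, n))
    w = v.copy()
    t = t0
    span = t1 - t0
    if span <= 0.0:
        return w
    hstep = min(0.25, span)
    nfail = 0
    while t < t1 - 1e-12:
        if t + hstep > t1:
            hstep = t1 - t
        for s in range(7):
            ws = w.copy()
            for j in range(s):
                if _A[s, j] != 0.0:
                    ws += (hstep * _A[s, j]) * K[j]
            _rhs(t + _C[s] * hstep, ws, Talpha, E, h, R, D, lam, active,
                 synthesis, ext_t, ext_y, y_buf, K[s])
        w5 = w.copy()
        w4 = w.copy()
        for s in range(7):
            if _B5[s] != 0.0:
                w5 += (hstep * _B5[s]) * K[s]
            if _B4[s] != 0.0:
                w4 += (hstep * _B4[s]) * K[s]
        # weighted RMS error norm
        err = 0.0
        for a in range(ng):
            for i in range(n):
                sc = atol + rtol * max(abs(w[a, i]), abs(w5[a, i]))
                d = (w5[a, i] - w4[a, i]) / sc
                err += d * d
        err = np.sqrt(err / (ng * n))
        if err <= 1.0:
            t += hstep
            w = w5
            nfail = 0
            fac = 5.0 if err == 0.0 else min(5.0, 0.9 * err ** -0.2)
            hstep *= fac
        else:
            nfail += 1
            hstep *= max(0.2, 0.9 * err ** -0.2)
            if nfail > 50:
                # persistent rejection: signal failure with NaN state
                w[:] = np.nan
                return w
    return w
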