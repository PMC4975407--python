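"""Compiled fixed-step RK4 kernels for long simulations.

The network right-hand side is a ten-to-hundred-dimensional smooth system;
a fixed-step classical Runge-Kutta scheme at ``dt`` a few hundredths of the
fastest oscillation period integrates it to well below measurement
precision, and compiling the step loop removes the per-step Python
overhead that dominates adaptive solvers on systems this small.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rk4_trajectory", "rk4_ramp", "rk4_tangent_block"]


@njit(cache=True)
def _act(V, half_nu, half_lam, V_T, out):
    for j in range(V.shape[0]):
        x = half_lam[j] * (V[j] - V_T[j])
        out[j] = half_nu[j] * (1.0 + x / np.sqrt(1.0 + x * x))


@njit(cache=True)
def _act_deriv(V, half_nu, half_lam, V_T, out):
    for j in range(V.shape[0]):
        x = half_lam[j] * (V[j] - V_T[j])
        out[j] = half_nu[j] * half_lam[j] * (1.0 + x * x) ** -1.5


@njit(cache=True)
def _rhs(V, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv, a, out):
    _act(V, half_nu, half_lam, V_T, a)
    n = V.shape[0]
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += W[i, j] * a[j]
        out[i] = -V[i] * tau_inv[i] + M_inv * s + I_ext[i]


@njit(cache=True)
def rk4_trajectory(V0, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv,
                   dt, n_steps, sample_every):
    """Integrate under static input; returns samples of shape (m+1, N)."""
    n = V0.shape[0]
    m = n_steps // sample_every
    out = np.empty((m + 1, n))
    V = V0.copy()
    out[0] = V
    a = np.empty(n)
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    tmp = np.empty(n)
    s = 0
    for step in range(n_steps):
        _rhs(V, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv, a, k1)
        for i in range(n):
            tmp[i] = V[i] + 0.5 * dt * k1[i]
        _rhs(tmp, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv, a, k2)
        for i in range(n):
            tmp[i] = V[i] + 0.5 * dt * k2[i]
        _rhs(tmp, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv, a, k3)
        for i in range(n):
            tmp[i] = V[i] + dt * k3[i]
        _rhs(tmp, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv, a, k4)
        for i in range(n):
            V[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if (step + 1) % sample_every == 0:
            s += 1
            out[s] = V
    return out[:s + 1]


@njit(cache=True)
def rk4_ramp(V0, W, tau_inv, I_base, mask_E, I_start, slope,
             half_nu, half_lam, V_T, M_inv, dt, n_steps, sample_every):
    """Integrate while the excitatory current ramps linearly in time."""
    n = V0.shape[0]
    m = n_steps // sample_every
    out = np.empty((m + 1, n))
    V = V0.copy()
    out[0] = V
    a = np.empty(n)
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    tmp = np.empty(n)
    I_ext = np.empty(n)
    s = 0
    for step in range(n_steps):
        t = step * dt
        for stage in range(4):
            if stage == 0:
                ts = t
                for i in range(n):
                    tmp[i] = V[i]
            elif stage == 1:
                ts = t + 0.5 * dt
                for i in range(n):
                    tmp[i] = V[i] + 0.5 * dt * k1[i]
            elif stage == 2:
                ts = t + 0.5 * dt
                for i in range(n):
                    tmp[i] = V[i] + 0.5 * dt * k2[i]
            else:
                ts = t + dt
                for i in range(n):
                    tmp[i] = V[i] + dt * k3[i]
            I_E = I_start + slope * ts
            for i in range(n):
                I_ext[i] = I_base[i] + I_E * mask_E[i]
            if stage == 0:
                _rhs(tmp, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv, a, k1)
            elif stage == 1:
                _rhs(tmp, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv, a, k2)
            elif stage == 2:
                _rhs(tmp, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv, a, k3)
            else:
                _rhs(tmp, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv, a, k4)
        for i in range(n):
            V[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if (step + 1) % sample_every == 0:
            s += 1
            out[s] = V
    return out[:s + 1]


@njit(cache=True)
def _rhs_tangent(V, Q, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv,
                 a, ad, dV, dQ):
    n = V.shape[0]
    k = Q.shape[1]
    _act(V, half_nu, half_lam, V_T, a)
    _act_deriv(V, half_nu, half_lam, V_T, ad)
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += W[i, j] * a[j]
        dV[i] = -V[i] * tau_inv[i] + M_inv * s + I_ext[i]
    # J = -diag(tau_inv) + M_inv * W * diag(ad)
    for i in range(n):
        for c in range(k):
            s = -tau_inv[i] * Q[i, c]
            for j in range(n):
                s += M_inv * W[i, j] * ad[j] * Q[j, c]
            dQ[i, c] = s


@njit(cache=True)
def rk4_tangent_block(V, Q, W, tau_inv, I_ext, half_nu, half_lam, V_T,
                      M_inv, dt, n_steps):
    """Advance state and k tangent vectors jointly over n_steps RK4 steps."""
    n = V.shape[0]
    k = Q.shape[1]
    a = np.empty(n); ad = np.empty(n)
    kV1 = np.empty(n); kV2 = np.empty(n); kV3 = np.empty(n); kV4 = np.empty(n)
    kQ1 = np.empty((n, k)); kQ2 = np.empty((n, k))
    kQ3 = np.empty((n, k)); kQ4 = np.empty((n, k))
    tV = np.empty(n); tQ = np.empty((n, k))
    for step in range(n_steps):
        _rhs_tangent(V, Q, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv,
                     a, ad, kV1, kQ1)
        for i in range(n):
            tV[i] = V[i] + 0.5 * dt * kV1[i]
            for c in range(k):
                tQ[i, c] = Q[i, c] + 0.5 * dt * kQ1[i, c]
        _rhs_tangent(tV, tQ, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv,
                     a, ad, kV2, kQ2)
        for i in range(n):
            tV[i] = V[i] + 0.5 * dt * kV2[i]
            for c in range(k):
                tQ[i, c] = Q[i, c] + 0.5 * dt * kQ2[i, c]
        _rhs_tangent(tV, tQ, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv,
                     a, ad, kV3, kQ3)
        for i in range(n):
            tV[i] = V[i] + dt * kV3[i]
            for c in range(k):
                tQ[i, c] = Q[i, c] + dt * kQ3[i, c]
        _rhs_tangent(tV, tQ, W, tau_inv, I_ext, half_nu, half_lam, V_T, M_inv,
                     a, ad, kV4, kQ4)
        for i in range(n):
            V[i] += dt / 6.0 * (kV1[i] + 2.0 * kV2[i] + 2.0 * kV3[i] + kV4[i])
            for c in range(k):
                Q[i, c] += dt / 6.0 * (kQ1[i, c] + 2.0 * kQ2[i, c]
                                       + 2.0 * kQ3[i, c] + kQ4[i, c])
    return V, Q
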