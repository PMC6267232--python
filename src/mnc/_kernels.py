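"""Numerical hot loops: all-pairs PLI and the coupled-oscillator integrator.

Both kernels are compiled with numba when it is importable and fall back to
equivalent (slower) numpy implementations otherwise.  The fallbacks are the
behavioural reference; the compiled versions must agree with them exactly up
to floating-point evaluation order.
"""

from __future__ import annotations

import numpy as np

_TWO_PI = 2.0 * np.pi


def _pli_all_py(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLI from an N x T phase matrix (numpy reference)."""
    n, t = phases.shape
    out = np.zeros((n, n))
    for i in range(n):
        d = phases[i] - phases[i + 1 :]
        d = d - _TWO_PI * np.floor((d + np.pi) / _TWO_PI)  # [-pi, pi)
        s = np.sign(d)
        s[d == -np.pi] = 0.0  # -pi is the wrapped image of +pi: sign 0
        v = np.abs(s.mean(axis=1))
        out[i, i + 1 :] = v
        out[i + 1 :, i] = v
    return out


def _kuramoto_py(
    omega: np.ndarray,
    in_rsn: np.ndarray,
    kappa: float,
    background: float,
    lag: float,
    theta0: np.ndarray,
    noise: np.ndarray,
) -> np.ndarray:
    """Integrate theta_i(t+1) = theta_i(t) + omega_i + coupling + noise.

    coupling_i = sum_j K_ij sin(theta_j - theta_i - lag) with K_ij = kappa
    inside the flagged RSN and ``background`` elsewhere (K_ii = 0), computed
    in O(N) per step via the complex order parameter of each block.
    Returns the (steps x N) phase trajectory (unwrapped).
    """
    steps, n = noise.shape
    dk = kappa - background
    theta = theta0.copy()
    out = np.empty((steps, n))
    for t in range(steps):
        c = np.cos(theta)
        s = np.sin(theta)
        sum_c, sum_s = c.sum(), s.sum()
        rsn_c = (c * in_rsn).sum()
        rsn_s = (s * in_rsn).sum()
        ac = background * (sum_c - c) + dk * in_rsn * (rsn_c - c)
        as_ = background * (sum_s - s) + dk * in_rsn * (rsn_s - s)
        alpha = theta + lag
        coupling = as_ * np.cos(alpha) - ac * np.sin(alpha)
        theta = theta + omega + coupling + noise[t]
        out[t] = theta
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    @njit(cache=True)
    def _pli_all_nb(phases):
        n, t = phases.shape
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                acc = 0.0
                for k in range(t):
                    d = phases[i, k] - phases[j, k]
                    d = d - _TWO_PI * np.floor((d + np.pi) / _TWO_PI)
                    if -np.pi < d < 0.0:
                        acc -= 1.0
                    elif 0.0 < d:
                        acc += 1.0
                    # d == -pi (image of +pi) and d == 0 contribute 0
                v = abs(acc) / t
                out[i, j] = v
                out[j, i] = v
        return out

    @njit(cache=True)
    def _kuramoto_nb(omega, in_rsn, kappa, background, lag, theta0, noise):
        steps, n = noise.shape
        dk = kappa - background
        theta = theta0.copy()
        out = np.empty((steps, n))
        c = np.empty(n)
        s = np.empty(n)
        for t in range(steps):
            sum_c = 0.0
            sum_s = 0.0
            rsn_c = 0.0
            rsn_s = 0.0
            for i in range(n):
                c[i] = np.cos(theta[i])
                s[i] = np.sin(theta[i])
                sum_c += c[i]
                sum_s += s[i]
                if in_rsn[i] > 0.0:
                    rsn_c += c[i]
                    rsn_s += s[i]
            for i in range(n):
                ac = background * (sum_c - c[i])
                as_ = background * (sum_s - s[i])
                if in_rsn[i] > 0.0:
                    ac += dk * (rsn_c - c[i])
                    as_ += dk * (rsn_s - s[i])
                alpha = theta[i] + lag
                coupling = as_ * np.cos(alpha) - ac * np.sin(alpha)
                out[t, i] = theta[i] + omega[i] + coupling + noise[t, i]
            for i in range(n):
                theta[i] = out[t, i]
        return out

    pli_all = _pli_all_nb
    kuramoto = _kuramoto_nb
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    pli_all = _pli_all_py
    kuramoto = _kuramoto_py
    HAVE_NUMBA = False
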