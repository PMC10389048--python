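"""Numba-compiled fixed-step RK4 kernel for the reduced glucose balance.

The reduced form dG/dt = a - vm2*G/(A*G + B) (see
:func:`beefit.model.reduced_rate_constants`) is regular at G=0 whenever
B > 0, so a fixed-step classical RK4 scheme is adequate; the state is
clamped at zero after each step. The kernel is the engine behind the fast
SSE objective used by the optimizers, where millions of one-state solves
are needed per benchmark.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _rhs(g, a, vm2, A, B):
    if g < 0.0:
        g = 0.0
    if B > 0.0:
        vhk = vm2 * g / (A * g + B)
    else:
        vhk = vm2 / A
    r = a - vhk
    if g == 0.0 and r < 0.0:
        r = 0.0
    return r


@njit(cache=False)
def rk4_trajectory(a, vm2, A, B, glci0, times, dt_max):
    """Integrate the reduced balance on ``times`` with internal step <= dt_max."""
    n = times.size
    out = np.empty(n)
    g = glci0
    out[0] = g
    for i in range(n - 1):
        span = times[i + 1] - times[i]
        m = int(np.ceil(span / dt_max))
        if m < 1:
            m = 1
        dt = span / m
        for _ in range(m):
            k1 = _rhs(g, a, vm2, A, B)
            k2 = _rhs(g + 0.5 * dt * k1, a, vm2, A, B)
            k3 = _rhs(g + 0.5 * dt * k2, a, vm2, A, B)
            k4 = _rhs(g + dt * k3, a, vm2, A, B)
            g = g + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
            if g < 0.0:
                g = 0.0
        out[i + 1] = g
    return out


@njit(cache=False)
def sse_rk4(x, g6p, atp, glci0, times, y_exp, dt_max):
    """Sum of squared errors between the RK4 trajectory at parameter vector
    ``x`` (canonical order) and the experimental values ``y_exp``.

    Volume cancels from the concentration balance, so it does not appear.
    """
    a = x[0] - x[1] * g6p
    vm2 = x[2]
    A = 1.0 + x[4] / atp
    B = x[3] + x[5] * x[4] / atp
    n = times.size
    g = glci0
    acc = (g - y_exp[0]) ** 2
    for i in range(n - 1):
        span = times[i + 1] - times[i]
        m = int(np.ceil(span / dt_max))
        if m < 1:
            m = 1
        dt = span / m
        for _ in range(m):
            k1 = _rhs(g, a, vm2, A, B)
            k2 = _rhs(g + 0.5 * dt * k1, a, vm2, A, B)
            k3 = _rhs(g + 0.5 * dt * k2, a, vm2, A, B)
            k4 = _rhs(g + dt * k3, a, vm2, A, B)
            g = g + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
            if g < 0.0:
                g = 0.0
        acc += (g - y_exp[i + 1]) ** 2
    return acc
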