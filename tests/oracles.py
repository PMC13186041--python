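"""Independent numerical oracles used only by the test suite.

Deliberately primitive: a fixed-step classical RK4 integrator for the
five-state network (no adaptivity, no event machinery) and an exhaustive
sign-change scan for fixed points of the generic switch.  They share no
code path with the package's solvers beyond the right-hand-side algebra.
"""

from __future__ import annotations

import numpy as np

from sporegerm.kinetics import KineticParameters, PulseProtocol


def _deriv(y: np.ndarray, S: float, p: KineticParameters) -> np.ndarray:
    Ri, Ra, Cc, Cca, Co = y
    act = p.k1 * S * Ri - p.k_minus1 * Ra
    ch = p.k2 * Ra * Cc
    op = p.k3 * Cca
    hill = 0.0
    if Co > 0:
        cn = Co**p.n
        hill = p.k4 * cn / (cn + p.theta**p.n)
    cl = p.k5 * Co
    return np.array([-act, act, -ch - hill + cl, ch - op, op + hill - cl])


def rk4_integrate(
    ri0: float,
    params: KineticParameters,
    protocol: PulseProtocol,
    dt: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 over the full protocol, restarted at pulse boundaries."""
    bounds = protocol.boundaries()
    y = np.array([ri0, 0.0, params.c_total, 0.0, 0.0])
    ts = [0.0]
    ys = [y.copy()]
    for left, right in zip(bounds[:-1], bounds[1:]):
        S = protocol.concentration(left)
        nsteps = int(round((right - left) / dt))
        for i in range(nsteps):
            k1 = _deriv(y, S, params)
            k2 = _deriv(y + dt / 2 * k1, S, params)
            k3 = _deriv(y + dt / 2 * k2, S, params)
            k4 = _deriv(y + dt * k3, S, params)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            ts.append(left + (i + 1) * dt)
            ys.append(y.copy())
    return np.array(ts), np.array(ys)


def first_crossing(ts: np.ndarray, values: np.ndarray, level: float) -> float | None:
    """First time `values >= level`, linearly interpolated between samples."""
    above = values >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0 or values[i] == level:
        return float(ts[i])
    return float(
        ts[i - 1] + (level - values[i - 1]) * (ts[i] - ts[i - 1]) / (values[i] - values[i - 1])
    )


def brute_force_switch_roots(P, ks, kd, n, theta, dx=1e-3, upper=None):
    """Sign-change scan of P + ks*x^n/(x^n+theta^n) - kd*x on a uniform grid."""
    if upper is None:
        upper = (P + ks) / kd + 1.0
    xs = np.arange(0.0, upper + dx, dx)
    xn = np.power(xs, n)
    fs = P + ks * xn / (xn + theta**n) - kd * xs
    roots = []
    for i in range(len(xs) - 1):
        if fs[i] == 0.0:
            roots.append(xs[i])
        elif fs[i] * fs[i + 1] < 0:
            # secant estimate inside the bracket
            roots.append(xs[i] - fs[i] * dx / (fs[i + 1] - fs[i]))
    if fs[-1] == 0.0:
        roots.append(xs[-1])
    return np.array(roots)
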