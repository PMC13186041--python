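"""Closed-form reductions of the kinetic network and geometric estimates.

Three groups of results, each usable on its own and each serving as an
independent oracle for the numerical core:

1. The receptor subsystem decouples from the channels and, under constant
   germinant, relaxes exponentially to a steady state:

       Ra(t) = R0 * occ * (1 - exp(-(k_minus1 + k1*S) * t)),
       occ   = k1*S / (k_minus1 + k1*S),   t_GR = 1 / (k1*S + k_minus1).

2. With the cooperative term switched off (k4 = 0) and fast opening
   (k3 -> inf), the channel subsystem collapses to a single linear ODE
   whose solution is

       Co(t) = (k2*Ra/beta) * c_total * (1 - exp(-beta*t)),
       beta  = k5 + k2*Ra,

   valid for t >> t_GR when Ra has reached its steady state.  The slow
   decay constant beta is what lets sub-threshold open channels persist
   between pulses — the channel-side memory.

3. The generic autocatalytic switch dX/dt = P + ks*X^n/(X^n+theta^n) - kd*X
   whose fixed-point structure (one or two stable states) underlies the
   all-or-none opening of the channel population, and the inner-membrane
   geometry that bounds how many channels a germinosome can contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BistableSwitchParams",
    "FixedPoint",
    "SwitchAnalysis",
    "ReducedModelParams",
    "GeometrySpec",
    "steady_state_occupancy",
    "gr_timescale",
    "ra_closed_form",
    "co_reduced_closed_form",
    "switch_fixed_points",
    "im_geometry",
]


@dataclass(frozen=True)
class BistableSwitchParams:
    """Parameters of the generic autocatalytic off-on switch."""

    P: float  # basal production rate
    ks: float  # maximum autocatalytic production rate
    kd: float  # linear decay rate
    n: float  # Hill coefficient
    theta: float  # half-saturation

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")
        if self.P < 0 or self.ks < 0:
            raise ValueError("P and ks must be >= 0")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")

    def net_rate(self, x: float | np.ndarray) -> float | np.ndarray:
        xn = np.power(x, self.n)
        return self.P + self.ks * xn / (xn + self.theta**self.n) - self.kd * x


@dataclass(frozen=True)
class FixedPoint:
    x: float
    stable: bool


@dataclass(frozen=True)
class SwitchAnalysis:
    fixed_points: tuple[FixedPoint, ...]
    bistable: bool


@dataclass(frozen=True)
class ReducedModelParams:
    """Derived constants of the closed-form receptor/channel reductions."""

    R0: float
    Ra_bar: float
    t_GR: float
    beta: float

    def __post_init__(self) -> None:
        if not 0 <= self.Ra_bar <= self.R0:
            raise ValueError("Ra_bar must lie in [0, R0]")
        if self.t_GR <= 0 or self.beta <= 0:
            raise ValueError("t_GR and beta must be > 0")


@dataclass(frozen=True)
class GeometrySpec:
    """Inner-membrane and germinosome areas (nm, nm^2) and channel density."""

    l: float
    s: float
    A_im: float
    area_per_channel: float
    A_ger: float
    capacity: int


def steady_state_occupancy(k1: float, S: float, k_minus1: float) -> float:
    """Steady-state fraction of GRs in the active state: k1*S/(k_minus1+k1*S)."""
    if k1 < 0 or S < 0 or k_minus1 < 0:
        raise ValueError("rates and concentration must be >= 0")
    denom = k_minus1 + k1 * S
    if denom == 0:
        raise ZeroDivisionError("occupancy undefined when k1*S and k_minus1 are both 0")
    return k1 * S / denom


def gr_timescale(k1: float, S: float, k_minus1: float) -> float:
    """Characteristic relaxation time of the receptor pool: 1/(k1*S + k_minus1)."""
    denom = k1 * S + k_minus1
    if denom <= 0:
        raise ZeroDivisionError("t_GR undefined when k1*S + k_minus1 = 0")
    return 1.0 / denom


def ra_closed_form(t: float | np.ndarray, R0: float, k1: float, S: float, k_minus1: float):
    """Active-GR count under constant germinant: exponential rise to R0*occ."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    occ = steady_state_occupancy(k1, S, k_minus1)
    rate = k_minus1 + k1 * S
    out = R0 * occ * (1.0 - np.exp(-rate * t))
    return float(out) if out.ndim == 0 else out


def co_reduced_closed_form(
    t: float | np.ndarray, Ra: float, k2: float, k5: float, c_total: float
):
    """Open-channel count in the k4 = 0, fast-k3 limit: rise to k2*Ra*c_total/beta.

    ``Ra`` is the (steady-state) active-GR count; beta = k5 + k2*Ra is the
    effective decay constant of the open pool.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    beta = k5 + k2 * Ra
    if beta <= 0:
        raise ValueError(f"beta = k5 + k2*Ra must be > 0, got {beta}")
    out = (k2 * Ra / beta) * c_total * (1.0 - np.exp(-beta * t))
    return float(out) if out.ndim == 0 else out


def switch_fixed_points(
    params: BistableSwitchParams,
    *,
    grid_points: int = 20000,
) -> SwitchAnalysis:
    """Locate all fixed points of the generic switch on [0, (P+ks)/kd].

    Roots of the net rate are bracketed by a sign scan on a fine grid and
    refined with Brent's method; exact-zero grid nodes (e.g. X = 0 when
    P = 0) are kept as roots directly.  Stability follows from the sign of
    d(net rate)/dX at the root; a negative slope is stable.  The system is
    flagged bistable when at least two stable fixed points coexist.
    """
    upper = (params.P + params.ks) / params.kd
    if upper == 0.0:
        return SwitchAnalysis(fixed_points=(FixedPoint(0.0, True),), bistable=False)
    xs = np.linspace(0.0, upper * (1.0 + 1e-9), grid_points)
    fs = np.asarray(params.net_rate(xs), dtype=float)

    roots: list[float] = []
    for i in range(len(xs) - 1):
        f0, f1 = fs[i], fs[i + 1]
        if f0 == 0.0:
            roots.append(float(xs[i]))
        elif f0 * f1 < 0:
            roots.append(float(brentq(params.net_rate, xs[i], xs[i + 1], xtol=1e-12)))
    if fs[-1] == 0.0:
        roots.append(float(xs[-1]))
    # merge near-duplicates from adjacent brackets
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 1e-6 * max(1.0, upper):
            merged.append(r)

    eps = max(upper, 1.0) * 1e-7
    fps = []
    for r in merged:
        slope = (params.net_rate(r + eps) - params.net_rate(max(r - eps, 0.0))) / (
            r + eps - max(r - eps, 0.0)
        )
        fps.append(FixedPoint(x=r, stable=slope < 0))
    n_stable = sum(fp.stable for fp in fps)
    return SwitchAnalysis(fixed_points=tuple(fps), bistable=n_stable >= 2)


def im_geometry(
    l: float = 837.0,
    s: float = 554.0,
    r_ger: float = 400.0,
    c_total: float = 6500.0,
    *,
    A_im: float | None = None,
) -> GeometrySpec:
    """Inner-membrane area, channel density and germinosome channel capacity.

    The IM is approximated as a prolate ellipsoid with surface area
    ``A_im = 2*pi*(s^2 + l*s)`` (long semi-axis l, short semi-axis s, nm).
    With the channels spread uniformly, one channel occupies
    ``A_im / c_total`` nm^2.  The germinosome is a planar disk of radius
    ``r_ger`` whose area divided by the per-channel area bounds the number
    of channels a germinosome can contact ("at most": ceiling).

    Pass ``A_im`` explicitly to use a pre-computed/printed area instead of
    the ellipsoid formula (the formula and published value differ by
    ~0.1% for the reference semi-axes).  The default germinosome radius
    400 nm reproduces the published disk area of ~502,655 nm^2 even though
    the underlying fluorescence signal has a 300 nm full width at half
    maximum; the discrepancy is inherited from the source values.
    """
    if not l >= s > 0:
        raise ValueError(f"require l >= s > 0, got l={l}, s={s}")
    if r_ger <= 0 or c_total <= 0:
        raise ValueError("r_ger and c_total must be > 0")
    area = 2.0 * math.pi * (s**2 + l * s) if A_im is None else float(A_im)
    per_channel = area / c_total
    a_ger = math.pi * r_ger**2
    capacity = math.ceil(a_ger / per_channel)
    return GeometrySpec(
        l=l, s=s, A_im=area, area_per_channel=per_channel, A_ger=a_ger, capacity=capacity
    )
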