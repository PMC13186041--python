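"""Core kinetic network: parameters, germinant input, and the ODE right-hand side.

The model couples germinant receptors (GRs) in two states — inactive ``Ri``
and active ``Ra`` — to SpoVA channels in three states — closed inactive
``Cc``, closed activated ``Cca`` and open ``Co``.  Germinant at concentration
``S(t)`` (mM) activates GRs; active GRs activate closed channels; activated
channels open; open channels cooperatively promote further opening through a
Hill term, balanced by first-order closure back to the inactive closed state:

    dRi/dt  = -k1*S*Ri + k_minus1*Ra
    dRa/dt  = +k1*S*Ri - k_minus1*Ra
    dCc/dt  = -k2*Ra*Cc - k4*Co^n/(Co^n + theta^n) + k5*Co
    dCca/dt = +k2*Ra*Cc - k3*Cca
    dCo/dt  = +k3*Cca + k4*Co^n/(Co^n + theta^n) - k5*Co

Units throughout: time in minutes, germinant concentration in mM, state
variables in molecules (copies) per spore.  The source publications of such
rate constants rarely state units explicitly; minutes/mM/molecules is the
convention adopted here, inferred from the pulse protocols (minutes, mM) and
the copy-number initial conditions, and documented in ``docs/methods.md``.

Both receptor and channel totals are conserved: Ri+Ra and Cc+Cca+Co are
constant along every trajectory, exactly, by construction of the equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KineticParameters",
    "Pulse",
    "PulseProtocol",
    "SporeState",
    "pulse_concentration",
    "hill_production",
    "rhs",
    "rhs_array",
]

STATE_NAMES = ("Ri", "Ra", "Cc", "Cca", "Co")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and structural constants of the germination network.

    Attributes
    ----------
    k1 : float
        Germinant binding / GR activation rate constant (mM^-1 min^-1).
    k_minus1 : float
        GR deactivation (germinant dissociation) rate constant (min^-1).
    k2 : float
        GR -> channel activation rate constant (molecule^-1 min^-1).
    k3 : float
        Activated-closed -> open channel rate constant (min^-1).
    k4 : float
        Maximum cooperative channel-opening rate (molecules min^-1).
    k5 : float
        Open -> closed channel decay rate constant (min^-1).
    n : float
        Hill coefficient of the cooperative opening term (n >= 1; n > 1
        gives the positive feedback required for bistability).
    theta : float
        Hill half-saturation constant (molecules/spore): the open-channel
        count at which cooperative production runs at half its maximum.
    c_total : float
        Total SpoVA channels per spore (Cc+Cca+Co; default 6500).
    germination_threshold : float
        Open-channel count defining the germination event T_open
        (default 50 copies/spore).
    """

    k1: float
    k_minus1: float
    k2: float
    k3: float
    k4: float
    k5: float
    n: float = 3.0
    theta: float = 20.0
    c_total: float = 6500.0
    germination_threshold: float = 50.0

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2", "k3", "k4", "k5"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {getattr(self, name)}")
        if self.n < 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not 0 < self.germination_threshold < self.c_total:
            raise ValueError(
                "germination_threshold must lie in (0, c_total), got "
                f"{self.germination_threshold} with c_total={self.c_total}"
            )

    def with_overrides(self, **kwargs: float) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Pulse:
    """One square germinant pulse: concentration (mM) over [start, end) min."""

    start: float
    end: float
    concentration: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"pulse must satisfy 0 <= start < end, got [{self.start}, {self.end}]")
        if self.concentration < 0:
            raise ValueError(f"pulse concentration must be >= 0, got {self.concentration}")


@dataclass(frozen=True)
class PulseProtocol:
    """Piecewise-constant germinant input S(t): an ordered set of square pulses.

    The input is an exact square wave; discontinuities at pulse edges are
    handled downstream by restarting the integrator at every boundary, not by
    smoothing.
    """

    pulses: tuple[Pulse, ...]
    horizon: float = 60.0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError(f"horizon must be > 0, got {self.horizon}")
        pulses = tuple(
            p if isinstance(p, Pulse) else Pulse(*p) for p in self.pulses
        )
        object.__setattr__(self, "pulses", pulses)
        prev_end = 0.0
        for p in pulses:
            if p.start < prev_end:
                raise ValueError("pulses must be sorted and non-overlapping")
            if p.end > self.horizon:
                raise ValueError(f"pulse [{p.start}, {p.end}] extends past horizon {self.horizon}")
            prev_end = p.end

    @classmethod
    def double_pulse(
        cls,
        concentration: float,
        duration: float = 5.0,
        second_start: float = 30.0,
        horizon: float = 60.0,
    ) -> "PulseProtocol":
        """The canonical double-pulse memory protocol.

        Two identical pulses: [0, duration) and [second_start,
        second_start+duration), start-to-start spacing ``second_start`` min.
        """
        return cls(
            pulses=(
                Pulse(0.0, duration, concentration),
                Pulse(second_start, second_start + duration, concentration),
            ),
            horizon=horizon,
        )

    def concentration(self, t: float) -> float:
        return pulse_concentration(self, t)

    def boundaries(self) -> list[float]:
        """Sorted breakpoints of S(t) on [0, horizon], including both ends."""
        pts = {0.0, self.horizon}
        for p in self.pulses:
            pts.add(p.start)
            pts.add(p.end)
        return sorted(b for b in pts if 0.0 <= b <= self.horizon)

    @property
    def second_pulse_start(self) -> float | None:
        return self.pulses[1].start if len(self.pulses) >= 2 else None


@dataclass(frozen=True)
class SporeState:
    """Copy numbers of the five molecular species in one spore."""

    Ri: float
    Ra: float
    Cc: float
    Cca: float
    Co: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Ri, self.Ra, self.Cc, self.Cca, self.Co], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "SporeState":
        return cls(*(float(v) for v in y))

    @classmethod
    def resting(cls, Ri0: float, c_total: float = 6500.0) -> "SporeState":
        """Dormant initial condition: all GRs inactive, all channels closed."""
        return cls(Ri=Ri0, Ra=0.0, Cc=c_total, Cca=0.0, Co=0.0)

    @property
    def receptor_total(self) -> float:
        return self.Ri + self.Ra

    @property
    def channel_total(self) -> float:
        return self.Cc + self.Cca + self.Co


def pulse_concentration(protocol: PulseProtocol, t: float) -> float:
    """Germinant concentration S(t) in mM; 0 outside every pulse.

    Pulses are half-open [start, end), so the concentration at an exact
    pulse end is already that of the following (zero) segment.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    for p in protocol.pulses:
        if p.start <= t < p.end:
            return p.concentration
    return 0.0


def hill_production(Co: float, params: KineticParameters) -> float:
    """Cooperative channel-opening rate k4*Co^n/(Co^n + theta^n).

    Monotone nondecreasing in Co, bounded by k4, and defined as 0 at
    Co = 0 (theta > 0 makes the limit unambiguous).
    """
    if Co < 0:
        raise ValueError(f"Co must be >= 0, got {Co}")
    if Co == 0.0:
        return 0.0
    cn = Co ** params.n
    return params.k4 * cn / (cn + params.theta ** params.n)


def rhs_array(y: np.ndarray, S: float, p: KineticParameters) -> np.ndarray:
    """Time derivatives for state vector [Ri, Ra, Cc, Cca, Co] at germinant S.

    Written so the pairwise sums cancel exactly: dRi+dRa = 0 and
    dCc+dCca+dCo = 0 in floating point, not merely analytically.
    """
    Ri, Ra, Cc, Cca, Co = y
    activation = p.k1 * S * Ri - p.k_minus1 * Ra
    channel_act = p.k2 * Ra * Cc
    opening = p.k3 * Cca
    if Co > 0.0:
        cn = Co ** p.n
        hill = p.k4 * cn / (cn + p.theta ** p.n)
    else:
        hill = 0.0
    closure = p.k5 * Co
    d_cca = channel_act - opening
    d_co = opening + hill - closure
    # dCc is defined as the negative of the other two channel derivatives so
    # the channel total is conserved exactly in floating point (likewise the
    # receptor pair).
    return np.array([-activation, activation, -(d_cca + d_co), d_cca, d_co])


def rhs(
    state: SporeState,
    t: float,
    params: KineticParameters,
    protocol: PulseProtocol,
) -> SporeState:
    """State-level right-hand side: derivatives at time t under a protocol.

    Returns the five derivatives packaged as a ``SporeState`` (molecules/min).
    """
    S = pulse_concentration(protocol, t)
    return SporeState.from_array(rhs_array(state.as_array(), S, params))
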