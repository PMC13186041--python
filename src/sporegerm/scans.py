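"""Parameter sweeps: GR copy-number, germinant-concentration and variance scans.

The deterministic GR scan integrates one spore per copy number over a
shared protocol and splits the axis into the three contiguous
subpopulations the double-pulse experiment produces: spores that never
germinate, spores recruited only by the second pulse (the memory band),
and spores already triggered by the first pulse.  The ensemble scans
repeat a full gamma-distributed cycle per germinant concentration or per
distribution width and tabulate the pulse-window fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ensemble import (
    EnsembleConfig,
    GammaSpec,
    pulse_summary,
    run_ensemble,
)
from .kinetics import KineticParameters, Pulse, PulseProtocol
from .single_spore import (
    GerminationOutcome,
    Trajectory,
    classify_outcome,
    integrate_spore,
    release_interval,
)

__all__ = [
    "ScanResult",
    "gr_copy_scan",
    "peak_channel_activation",
    "concentration_scan",
    "variance_scan",
    "recruitment_boundaries",
    "asymptotic_pulse_fractions",
]

#: Trajectories are retained by default only for scans at or below this size.
TRAJECTORY_RETENTION_LIMIT = 100


@dataclass
class ScanResult:
    """Outcome of a deterministic GR copy-number scan.

    ``boundaries`` summarises the three subpopulations: the largest
    non-germinating copy number, the smallest copy number recruited by the
    second pulse, and the smallest recruited by the first pulse (each None
    when the class is absent from the scan).
    """

    values: np.ndarray
    outcomes: list[GerminationOutcome]
    trajectories: list[Trajectory] | None
    params: KineticParameters
    protocol: PulseProtocol

    def classes(self) -> list[str]:
        return [o.outcome for o in self.outcomes]

    @property
    def boundaries(self) -> dict[str, float | None]:
        def extreme(cls: str, fn) -> float | None:
            vals = [v for v, o in zip(self.values, self.outcomes) if o.outcome == cls]
            return float(fn(vals)) if vals else None

        return {
            "largest_no_germination": extreme("no_germination", max),
            "smallest_second_pulse": extreme("second_pulse", min),
            "smallest_first_pulse": extreme("first_pulse", min),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ri0": self.values,
                "outcome": self.classes(),
                "t_open": [np.nan if o.t_open is None else o.t_open for o in self.outcomes],
                "t_lag": [np.nan if o.t_lag is None else o.t_lag for o in self.outcomes],
                "t_release_proxy": [
                    np.nan if o.t_release_proxy is None else o.t_release_proxy
                    for o in self.outcomes
                ],
            }
        )


def gr_copy_scan(
    ri_values: np.ndarray,
    params: KineticParameters,
    protocol: PulseProtocol,
    *,
    keep_trajectories: bool | None = None,
) -> ScanResult:
    """Deterministic scan over initial GR copy numbers (one spore per value).

    ``ri_values`` must be nonempty and strictly increasing.  Trajectories
    are retained when the scan has at most ``TRAJECTORY_RETENTION_LIMIT``
    points (or when forced with ``keep_trajectories=True``) so channel
    activation peaks and plateaus can be read off afterwards.
    """
    ri_values = np.asarray(ri_values, dtype=float)
    if ri_values.size == 0:
        raise ValueError("ri_values must be nonempty")
    if np.any(np.diff(ri_values) <= 0):
        raise ValueError("ri_values must be strictly increasing")
    if keep_trajectories is None:
        keep_trajectories = ri_values.size <= TRAJECTORY_RETENTION_LIMIT

    outcomes = []
    trajectories: list[Trajectory] | None = [] if keep_trajectories else None
    for ri0 in ri_values:
        traj = integrate_spore(ri0, params, protocol)
        outcomes.append(
            classify_outcome(traj.t_open, protocol, t_release_proxy=release_interval(traj))
        )
        if trajectories is not None:
            trajectories.append(traj)
    return ScanResult(
        values=ri_values,
        outcomes=outcomes,
        trajectories=trajectories,
        params=params,
        protocol=protocol,
    )


def peak_channel_activation(scan: ScanResult) -> pd.DataFrame:
    """Per-spore peak of the activated-closed channel count Cca, plus Co at end.

    Requires the scan to have retained trajectories.  The scan-wide
    min/max of the peaks quantify how few channels direct GR contact
    activates (signal amplification happens downstream, through the
    cooperative opening term).
    """
    if scan.trajectories is None:
        raise ValueError("scan did not retain trajectories; rerun with keep_trajectories=True")
    rows = []
    for ri0, traj in zip(scan.values, scan.trajectories):
        rows.append(
            {
                "ri0": float(ri0),
                "peak_cca": float(traj.Cca.max()),
                "co_final": float(traj.Co[-1]),
            }
        )
    return pd.DataFrame(rows)


def _summary_row(config: EnsembleConfig) -> dict[str, float]:
    result = run_ensemble(config, fit_draws=False)
    s = pulse_summary(result)
    return {
        "first_window_pct": s.first_window_pct,
        "second_window_pct": np.nan if s.second_window_pct is None else s.second_window_pct,
        "cumulative_pct": s.cumulative_pct,
    }


def concentration_scan(
    s_values: np.ndarray,
    base_config: EnsembleConfig,
) -> pd.DataFrame:
    """Pulse-window germination fractions as a function of pulse concentration.

    Every run reuses the base configuration (kinetics, gamma distribution,
    spore count, seed — the identical draw vector isolates the concentration
    effect) and only rescales the pulse concentrations.
    """
    s_values = np.asarray(s_values, dtype=float)
    if np.any(s_values < 0):
        raise ValueError("concentrations must be >= 0")
    rows = []
    for s in s_values:
        protocol = PulseProtocol(
            pulses=tuple(
                Pulse(p.start, p.end, float(s)) for p in base_config.protocol.pulses
            ),
            horizon=base_config.protocol.horizon,
        )
        row = _summary_row(replace(base_config, protocol=protocol))
        rows.append({"concentration_mM": float(s), **row})
    return pd.DataFrame(rows)


def recruitment_boundaries(
    params: KineticParameters,
    protocol: PulseProtocol,
    lo: float = 1.0,
    hi: float = 10_000.0,
    xtol: float = 0.01,
) -> dict[str, float | None]:
    """Critical GR copy numbers separating the three response subpopulations.

    Germination outcome is monotone in the initial receptor count, so two
    thresholds fully describe a double-pulse response: ``germination`` (the
    smallest Ri0 that ever crosses the open-channel threshold) and
    ``first_pulse`` (the smallest Ri0 recruited before the second pulse).
    Both are located by bisection on deterministic single-spore
    integrations to ``xtol`` copies.  A boundary outside [lo, hi] is
    reported as None (e.g. no first-pulse recruitment at low germinant).
    """
    from scipy.optimize import brentq

    def crosses(ri0: float) -> bool:
        return integrate_spore(ri0, params, protocol).t_open is not None

    def crosses_first(ri0: float) -> bool:
        t = integrate_spore(ri0, params, protocol).t_open
        second = protocol.second_pulse_start
        return t is not None and (second is None or t < second)

    out: dict[str, float | None] = {}
    for name, pred in (("germination", crosses), ("first_pulse", crosses_first)):
        f = lambda ri: 1.0 if pred(ri) else -1.0
        if f(hi) < 0:
            out[name] = None
        elif f(lo) > 0:
            out[name] = lo
        else:
            out[name] = float(brentq(f, lo, hi, xtol=xtol))
    return out


def asymptotic_pulse_fractions(
    gamma: GammaSpec,
    params: KineticParameters,
    protocol: PulseProtocol,
    lo: float = 1.0,
    hi: float = 10_000.0,
) -> dict[str, float]:
    """Exact (infinite-population) pulse-window germination percentages.

    The ensemble percentages are Bernoulli means over the gamma draw, so
    their population values are just gamma tail masses above the
    deterministic recruitment boundaries — no sampling noise.  Returns
    first-window, second-window and cumulative percentages of the whole
    population, plus the two boundaries.
    """
    from scipy.stats import gamma as gamma_dist

    b = recruitment_boundaries(params, protocol, lo=lo, hi=hi)
    sf = lambda x: float(gamma_dist.sf(x, gamma.shape, scale=gamma.scale))
    cumulative = 100.0 * sf(b["germination"]) if b["germination"] is not None else 0.0
    first = 100.0 * sf(b["first_pulse"]) if b["first_pulse"] is not None else 0.0
    return {
        "first_window_pct": first,
        "second_window_pct": cumulative - first,
        "cumulative_pct": cumulative,
        "germination_boundary": b["germination"],
        "first_pulse_boundary": b["first_pulse"],
    }


def variance_scan(
    sd_values: np.ndarray,
    mean: float,
    base_config: EnsembleConfig,
) -> pd.DataFrame:
    """Pulse-window fractions as the GR-distribution width varies at fixed mean.

    For each target sd the gamma parameters are recomputed as
    a = (mean/sd)^2, b = sd^2/mean, so the mean stays pinned while the
    right tail grows with sd.  A heavier tail pushes more spores over the
    first-pulse recruitment boundary, so the first-window fraction is
    expected to be nondecreasing in sd.
    """
    sd_values = np.asarray(sd_values, dtype=float)
    if mean <= 0 or np.any(sd_values <= 0):
        raise ValueError("mean and sd values must be > 0")
    rows = []
    for sd in sd_values:
        gamma = GammaSpec.from_mean_sd(mean, float(sd))
        row = _summary_row(replace(base_config, gamma=gamma))
        rows.append(
            {"sd": float(sd), "gamma_shape": gamma.shape, "gamma_scale": gamma.scale, **row}
        )
    return pd.DataFrame(rows)
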