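"""Configuration loading, result serialization and experimental-curve handling.

Config files are TOML.  A config may name a preset (``fig1``, ``fig2c``,
``fig2d``, ``fig3``) and override individual fields; unspecified fields are
filled from the preset and unknown keys are rejected, so a typo never
silently falls back to a default.  All tables are comma-separated UTF-8
text with a mandatory header row and "." decimals; floats are written at
full precision so write-then-read round-trips exactly.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import EnsembleConfig, GammaSpec, GerminationCurve
from .kinetics import KineticParameters, Pulse, PulseProtocol
from .presets import get_preset

__all__ = [
    "RunConfig",
    "ExperimentalCurve",
    "CurveComparison",
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "read_experimental_curve",
    "compare_curves",
    "write_table",
    "read_table",
]

logger = logging.getLogger("sporegerm")

_PARAM_KEYS = {
    "k1",
    "k_minus1",
    "k2",
    "k3",
    "k4",
    "k5",
    "n",
    "theta",
    "c_total",
    "germination_threshold",
}
_TOP_KEYS = {"preset", "seed", "n_spores", "params", "protocol", "gamma"}


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run configuration (kinetics + protocol + ensemble)."""

    params: KineticParameters
    protocol: PulseProtocol
    gamma: GammaSpec | None
    n_spores: int
    seed: int
    preset: str | None = None

    def ensemble_config(self) -> EnsembleConfig:
        if self.gamma is None:
            raise ValueError("configuration has no gamma distribution; not an ensemble run")
        return EnsembleConfig(
            gamma=self.gamma,
            params=self.params,
            protocol=self.protocol,
            n_spores=self.n_spores,
            seed=self.seed,
        )


def _reject_unknown(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")


def _build_config(data: dict, source: str) -> RunConfig:
    _reject_unknown(data, _TOP_KEYS, source)

    preset_name = data.get("preset")
    preset = get_preset(preset_name) if preset_name else None

    params_over = dict(data.get("params", {}))
    _reject_unknown(params_over, _PARAM_KEYS, f"{source}:[params]")
    if preset is not None:
        params = preset.params.with_overrides(**params_over) if params_over else preset.params
    else:
        try:
            params = KineticParameters(**params_over)
        except TypeError as err:
            raise ValueError(f"{source}: incomplete [params] and no preset given ({err})") from err

    proto_over = dict(data.get("protocol", {}))
    _reject_unknown(proto_over, {"pulses", "horizon"}, f"{source}:[protocol]")
    if proto_over:
        base_horizon = preset.protocol.horizon if preset else 60.0
        base_pulses = (
            tuple((p.start, p.end, p.concentration) for p in preset.protocol.pulses)
            if preset
            else ()
        )
        pulses = tuple(
            Pulse(*map(float, p)) for p in proto_over.get("pulses", base_pulses)
        )
        protocol = PulseProtocol(pulses=pulses, horizon=float(proto_over.get("horizon", base_horizon)))
    elif preset is not None:
        protocol = preset.protocol
    else:
        raise ValueError(f"{source}: no [protocol] section and no preset given")

    gamma_over = dict(data.get("gamma", {}))
    _reject_unknown(gamma_over, {"shape", "scale", "mean", "sd"}, f"{source}:[gamma]")
    gamma: GammaSpec | None
    if {"mean", "sd"} <= set(gamma_over):
        gamma = GammaSpec.from_mean_sd(float(gamma_over["mean"]), float(gamma_over["sd"]))
    elif {"shape", "scale"} <= set(gamma_over):
        gamma = GammaSpec(shape=float(gamma_over["shape"]), scale=float(gamma_over["scale"]))
    elif gamma_over:
        raise ValueError(f"{source}:[gamma] needs shape+scale or mean+sd, got {sorted(gamma_over)}")
    elif preset is not None and preset.has_gamma:
        gamma = GammaSpec(shape=preset.gamma_shape, scale=preset.gamma_scale)
    else:
        gamma = None

    n_spores = int(data.get("n_spores", preset.n_spores if preset else 500))
    seed = int(data.get("seed", 0))
    return RunConfig(
        params=params,
        protocol=protocol,
        gamma=gamma,
        n_spores=n_spores,
        seed=seed,
        preset=preset_name,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration (optionally preset-based)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return _build_config(data, str(path))


def config_from_preset(name: str, *, seed: int = 0, **overrides) -> RunConfig:
    """Build a RunConfig straight from a named preset without a file."""
    data: dict = {"preset": name, "seed": seed}
    data.update(overrides)
    return _build_config(data, f"preset:{name}")


def config_to_dict(config: RunConfig) -> dict:
    """JSON/TOML-serializable snapshot; inverse of :func:`config_from_dict`."""
    out: dict = {
        "seed": config.seed,
        "n_spores": config.n_spores,
        "params": {k: getattr(config.params, k) for k in sorted(_PARAM_KEYS)},
        "protocol": {
            "pulses": [[p.start, p.end, p.concentration] for p in config.protocol.pulses],
            "horizon": config.protocol.horizon,
        },
    }
    if config.preset:
        out["preset"] = config.preset
    if config.gamma is not None:
        out["gamma"] = {"shape": config.gamma.shape, "scale": config.gamma.scale}
    return out


def config_from_dict(data: dict) -> RunConfig:
    """Rebuild a RunConfig from a snapshot produced by :func:`config_to_dict`."""
    data = dict(data)
    data.pop("preset", None)  # snapshot is complete; do not re-resolve the preset
    return _build_config(data, "snapshot")


@dataclass
class ExperimentalCurve:
    """A measured percentage-germination time series."""

    times: np.ndarray
    percent: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.percent = np.asarray(self.percent, dtype=float)
        if self.times.shape != self.percent.shape or self.times.ndim != 1:
            raise ValueError("times and percent must be 1-D arrays of equal length")
        if np.any((self.percent < 0) | (self.percent > 100)):
            bad = self.percent[(self.percent < 0) | (self.percent > 100)]
            raise ValueError(f"percent values outside [0, 100]: {bad[:5]}")


def read_experimental_curve(path: str | Path, **metadata) -> ExperimentalCurve:
    """Read a two-column (time, percent) CSV; sorts by time with a warning.

    The header must contain a time column and a percent column (first two
    columns are used).  Non-numeric cells and percentages outside [0, 100]
    are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (time, percent)")
    times = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    percent = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    if np.any(np.diff(times) < 0):
        logger.warning("%s: times not sorted; sorting", path)
        order = np.argsort(times, kind="stable")
        times, percent = times[order], percent[order]
    return ExperimentalCurve(times=times, percent=percent, metadata=dict(metadata))


@dataclass(frozen=True)
class CurveComparison:
    """Model-vs-data fit report, all quantities in percentage points."""

    rmse: float
    max_abs_deviation: float
    window_deltas: dict[str, float]
    n_points: int


def compare_curves(
    model: GerminationCurve,
    data: ExperimentalCurve,
    protocol: PulseProtocol | None = None,
) -> CurveComparison:
    """Interpolate the model curve onto the data times and report deviations.

    Only data points inside the model's time span are compared; the call
    fails if the two time ranges are disjoint.  When a protocol is given,
    per-window deltas (model - data) are reported at the second-pulse start
    and at the final shared time.
    """
    lo = max(model.times[0], data.times[0])
    hi = min(model.times[-1], data.times[-1])
    if lo > hi:
        raise ValueError(
            f"disjoint time ranges: model [{model.times[0]}, {model.times[-1]}] vs "
            f"data [{data.times[0]}, {data.times[-1]}]"
        )
    mask = (data.times >= lo) & (data.times <= hi)
    t = data.times[mask]
    resid = np.interp(t, model.times, model.percent) - data.percent[mask]
    deltas: dict[str, float] = {}
    if protocol is not None and protocol.second_pulse_start is not None:
        ts = protocol.second_pulse_start
        if lo <= ts <= hi:
            deltas["first_window"] = model.at(ts) - float(
                np.interp(ts, data.times, data.percent)
            )
    deltas["end"] = model.at(hi) - float(np.interp(hi, data.times, data.percent))
    return CurveComparison(
        rmse=float(np.sqrt(np.mean(resid**2))),
        max_abs_deviation=float(np.max(np.abs(resid))),
        window_deltas=deltas,
        n_points=int(mask.sum()),
    )


def write_table(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a CSV table, optionally preceded by '#' comment header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
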