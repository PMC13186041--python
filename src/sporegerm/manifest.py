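"""Run manifests: a JSON record sufficient to re-run a result bit-identically.

A manifest snapshots the full configuration (after preset resolution), the
seed, the solver tolerances, the package version, a timestamp and a
checksum inventory of every output file the run produced.  Replaying a
manifest rebuilds the configuration from the snapshot — not from the
preset table, which may change across versions — so outcome tables
reproduce exactly.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .ensemble import EnsembleResult, run_ensemble
from .io import RunConfig, config_from_dict, config_to_dict

__all__ = ["RunManifest", "write_manifest", "read_manifest", "replay"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    solver: dict
    version: str
    timestamp: str
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def write_manifest(
    config: RunConfig,
    output_files: list[Path],
    path: str | Path,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> RunManifest:
    """Snapshot a run and checksum its outputs into a JSON manifest."""
    manifest = RunManifest(
        config=config_to_dict(config),
        seed=config.seed,
        solver={"rtol": rtol, "atol": atol},
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs={str(Path(f).name): _sha256(Path(f)) for f in output_files},
    )
    Path(path).write_text(manifest.to_json(), encoding="utf-8")
    return manifest


def read_manifest(path: str | Path) -> RunManifest:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return RunManifest(**data)


def replay(manifest: RunManifest) -> EnsembleResult:
    """Re-run the ensemble recorded in a manifest; bit-identical outcome table."""
    config = config_from_dict(manifest.config)
    return run_ensemble(config.ensemble_config())
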