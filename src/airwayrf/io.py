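"""Result serialization: telemetry CSV, budget JSON, run manifest.

Files are written atomically (temp file + rename) so a crashed run
never leaves a truncated artifact, and every acceptance-level quantity
is recomputable from the written outputs alone.
"""

from __future__ import annotations

import json
import os
import time
from pathlib import Path

from . import __version__
from .config import config_hash, dump_config
from .simulation import SimulationResult
from .vtkio import write_vtk


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_outputs(result: SimulationResult, output_dir: str | Path,
                  write_fields: bool | None = None) -> dict:
    """Write telemetry, budget, controller log, config, and manifest.

    Returns the manifest dict.  The config hash changes iff the
    configuration changes, giving a cheap provenance check for sweeps.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    _atomic_write(out / "telemetry.csv",
                  result.telemetry.to_csv(index=False, float_format="%.10g"))
    _atomic_write(out / "budget.json",
                  json.dumps(result.budget.as_dict(), indent=2) + "\n")
    _atomic_write(out / "metrics.json",
                  json.dumps(result.metrics, indent=2) + "\n")
    _atomic_write(out / "controller_log.csv",
                  result.controller_log.to_csv(index=False,
                                               float_format="%.10g"))
    _atomic_write(out / "config.yaml", dump_config(result.config))

    if write_fields is None:
        write_fields = result.config.output.write_vtk
    if write_fields:
        write_vtk(str(out / "fields.vtk"), result.mesh,
                  point_data={"temperature_C": result.final_temperature.T})

    manifest = {
        "config_hash": config_hash(result.config),
        "code_version": __version__,
        "wall_clock_s": round(time.time() - t0, 3),
        "files": sorted(p.name for p in out.iterdir()
                        if not p.name.endswith(".tmp")
                        and p.name != "manifest.json"),
    }
    _atomic_write(out / "manifest.json", json.dumps(manifest, indent=2) + "\n")
    return manifest
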