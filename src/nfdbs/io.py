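"""Result serialization: CSV tables with unit headers plus JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .simulate import SimulationResult

__all__ = ["write_results", "write_table", "read_table", "write_metadata"]

UNITS_COMMENT = "# units: time_ms in ms, rates/amplitudes in spk/s, frequencies in Hz, T_ms in ms"


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """CSV with a unit header comment and stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    try:
        with open(tmp, "w") as fh:
            fh.write(UNITS_COMMENT + "\n")
            table.to_csv(fh, index=False)
        tmp.replace(path)
    finally:
        tmp.unlink(missing_ok=True)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_metadata(meta: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(
    result: SimulationResult,
    out_dir: str | Path,
    name: str = "run",
    config_hash: str | None = None,
) -> dict[str, Path]:
    """Write a simulation result as long CSV + per-node stimulation + metadata.

    The metadata JSON records the exact seed and configuration enabling a
    bit-identical re-simulation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    files["rates"] = write_table(result.to_frame(), out / f"{name}_rates.csv")
    u = pd.DataFrame(result.u, columns=[f"u_node_{i}" for i in range(result.u.shape[1])])
    u.insert(0, "time_ms", result.times)
    files["stimulation"] = write_table(u, out / f"{name}_stimulation.csv")
    meta = {
        "seed": result.seed,
        "config": result.config.__dict__,
        "config_hash": config_hash,
        "package_version": _pkg_version,
        "n_steps": int(result.z1.shape[0]),
    }
    files["metadata"] = write_metadata(meta, out / f"{name}_metadata.json")
    return files
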