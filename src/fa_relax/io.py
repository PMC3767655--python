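"""File formats: multi-page TIFF movies, FRAP trace CSVs, record tables, JSON.

Movies are written as 16-bit unsigned multi-page TIFFs (one page per frame);
FRAP traces as long-format CSV with columns (curve_id, time_s, intensity,
is_prebleach); configs as YAML or JSON.  Every JSON report written by the
pipeline carries the package version and a hash of the generating config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from fa_relax.frap_model import FRAPCurve

__all__ = [
    "write_movie_tiff",
    "read_movie_tiff",
    "write_traces_csv",
    "read_traces_csv",
    "load_config_file",
    "config_hash",
    "write_report_json",
]


def write_movie_tiff(path: str | Path, frames: np.ndarray) -> None:
    """Write a movie as 16-bit unsigned multi-page TIFF (values clipped)."""
    data = np.clip(np.asarray(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_movie_tiff(path: str | Path) -> np.ndarray:
    frames = tifffile.imread(str(path)).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return frames


def write_traces_csv(path: str | Path, curves: list[FRAPCurve]) -> None:
    rows = []
    for i, c in enumerate(curves):
        for j in range(len(c.times)):
            rows.append({
                "curve_id": i,
                "time_s": c.times[j],
                "intensity": c.intensity[j],
                "is_prebleach": j < c.bleach_index,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[FRAPCurve]:
    df = pd.read_csv(path)
    curves = []
    for _, grp in df.groupby("curve_id", sort=True):
        grp = grp.sort_values("time_s")
        bleach_index = int(grp["is_prebleach"].sum())
        curves.append(FRAPCurve(grp["time_s"].to_numpy(), grp["intensity"].to_numpy(),
                                bleach_index))
    return curves


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def config_hash(config) -> str:
    """Stable short hash of a configuration (dataclass or dict)."""
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_report_json(path: str | Path, payload: dict, config=None) -> None:
    from fa_relax import __version__

    out = {"package_version": __version__}
    if config is not None:
        out["config_hash"] = config_hash(config)
    out.update(_jsonable(payload))
    Path(path).write_text(json.dumps(out, indent=2, allow_nan=False))
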