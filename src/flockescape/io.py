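"""Track-table CSV readers/writers and run manifests.

The track table is the interchange format between the simulator and
the detectors: a tidy time x agent CSV with columns
``t_s, agent_id, x_m, y_m`` plus optional ``heading_deg, speed_ms,
is_predator, manoeuvring``.  Writing rounds positions to 0.01 m and
times to 0.001 s; a write/read round trip is lossless at that
precision.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import DetectConfig, SimConfig, config_hash, config_to_dict

__all__ = ["read_tracks", "write_tracks", "write_manifest", "TrackFormatError"]

_REQUIRED = ["t_s", "agent_id", "x_m", "y_m"]


class TrackFormatError(ValueError):
    """Raised when a track CSV violates the schema."""


def write_tracks(tracks: pd.DataFrame, path) -> None:
    """Write a track table CSV (header mandatory, '.' decimal separator)."""
    missing = [c for c in _REQUIRED if c not in tracks.columns]
    if missing:
        raise TrackFormatError(f"missing columns: {missing}")
    out = tracks.copy()
    out["t_s"] = out["t_s"].round(3)
    for col in ("x_m", "y_m"):
        out[col] = out[col].round(2)
    for col in ("heading_deg", "speed_ms"):
        if col in out.columns:
            out[col] = out[col].round(3)
    out.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a track table CSV.

    Rejects missing columns, duplicate (t, agent) pairs and a
    non-uniform sampling grid, naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    df["agent_id"] = df["agent_id"].astype(int)
    dup = df.duplicated(subset=["t_s", "agent_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise TrackFormatError(f"{path}: duplicate (t, agent) pair at row {row}")
    for agent, sub in df.groupby("agent_id"):
        t = np.sort(sub["t_s"].to_numpy(dtype=float))
        if len(t) > 2:
            steps = np.diff(t)
            bad = np.flatnonzero(np.abs(steps - np.median(steps)) > 1e-6)
            if bad.size:
                k = int(sub.index[bad[0] + 1])
                raise TrackFormatError(
                    f"{path}: non-uniform sampling for agent {agent} at row {k}")
    return df


def write_manifest(path, seed: int, sim_cfg: Optional[SimConfig] = None,
                   detect_cfg: Optional[DetectConfig] = None,
                   extra: Optional[dict] = None) -> dict:
    """Write a JSON run manifest sufficient to reproduce a run.

    Records the package version, seed, full resolved configs and their
    hash; returns the manifest dict.
    """
    cfgs = [c for c in (sim_cfg, detect_cfg) if c is not None]
    manifest = {
        "package": "flockescape",
        "version": __version__,
        "python": platform.python_version(),
        "seed": int(seed),
        "config_hash": config_hash(*cfgs) if cfgs else None,
        "sim_config": config_to_dict(sim_cfg) if sim_cfg else None,
        "detect_config": config_to_dict(detect_cfg) if detect_cfg else None,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
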