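"""Readers/writers and provenance for reproducible pipeline runs.

Kymographs travel as multi-page TIFF (one page per channel, position x
time) with calibration in the image description; tracks, events, dwell
sets and step lists as CSV with the column names fixed in the shipped
``schema.yaml``; fits and simulation reports as JSON.  Every JSON report
embeds a provenance record (package version, seed, SHA-256 of the
generating configuration) so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .kinetics import DwellSet
from .kymo import Kymograph, LoopTrack, SpotTrack


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — valid YAML) configuration file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON encoding of a configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def provenance(config: dict, seed: int | None) -> dict:
    from . import __version__

    return {"package": "loopbarrier", "version": __version__,
            "seed": seed, "config_sha256": config_hash(config),
            "config": config}


def save_kymograph(path: str | Path, kym: Kymograph) -> None:
    names = list(kym.channels)
    stack = np.stack([kym.channels[n] for n in names]).astype(np.float32)
    meta = {"channels": names, "pixel_size_um": kym.pixel_size_um,
            "frame_interval_s": kym.frame_interval_s,
            "tether_px": list(kym.tether_px)}
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def load_kymograph(path: str | Path) -> Kymograph:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    channels = {n: stack[i].astype(float)
                for i, n in enumerate(meta["channels"])}
    return Kymograph(channels=channels,
                     pixel_size_um=float(meta["pixel_size_um"]),
                     frame_interval_s=float(meta["frame_interval_s"]),
                     tether_px=tuple(meta["tether_px"]))


def save_track(path: str | Path, track: LoopTrack | SpotTrack) -> None:
    track.to_frame().to_csv(path, index=False)


def load_loop_track(path: str | Path, total_bp: float = 0.0) -> LoopTrack:
    df = pd.read_csv(path)
    return LoopTrack(frame=df["frame"].to_numpy(),
                     time_s=df["time_s"].to_numpy(),
                     position_bp=df["position_bp"].to_numpy(),
                     loop_size_bp=df["loop_size_bp"].to_numpy(),
                     intensity_fraction=df["intensity_fraction"].to_numpy(),
                     flag=df["flag"].fillna("").to_numpy(dtype=object),
                     total_bp=total_bp)


def load_spot_track(path: str | Path) -> SpotTrack:
    df = pd.read_csv(path)
    return SpotTrack(frame=df["frame"].to_numpy(),
                     time_s=df["time_s"].to_numpy(),
                     position_bp=df["position_bp"].to_numpy(),
                     intensity=df["intensity"].to_numpy(),
                     present=df["present"].to_numpy(dtype=bool))


def save_dwell_set(path: str | Path, dwells: DwellSet) -> None:
    pd.DataFrame({"duration": dwells.durations,
                  "censored": dwells.censored,
                  "context": dwells.context}).to_csv(path, index=False)


def load_dwell_set(path: str | Path, frame_interval: float = 0.0) -> DwellSet:
    df = pd.read_csv(path)
    ctx = str(df["context"].iloc[0]) if "context" in df and len(df) else ""
    return DwellSet(durations=df["duration"].to_numpy(),
                    censored=df["censored"].to_numpy(dtype=bool),
                    frame_interval=frame_interval, context=ctx)


def write_report(path: str | Path, payload: dict, config: dict,
                 seed: int | None) -> None:
    """Write a JSON analysis report with an embedded provenance record."""
    out = {"provenance": provenance(config, seed), **payload}
    Path(path).write_text(json.dumps(_jsonable(out), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj
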