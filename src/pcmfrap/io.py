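"""File formats: multi-page TIFF movies with JSON sidecars, profile CSV/JSON.

A movie is stored as ``<stem>.tif`` (one page per frame) plus
``<stem>.json`` carrying the physical calibration, frame times, bleach
events, centrosome seeds and any simulation metadata — everything the
analysis needs that TIFF does not carry natively.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ConfigError
from .images import BleachEvent, FrapMovie
from .profiling import ProfileSet, RadialProfile

__all__ = ["write_movie", "read_movie", "write_profile_set", "read_profile_set",
           "profiles_to_frame", "sha256_file", "write_json"]


def write_movie(movie: FrapMovie, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.tif`` + ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    tif_path = stem.with_suffix(".tif")
    json_path = stem.with_suffix(".json")
    tifffile.imwrite(tif_path, movie.frames.astype(np.float32))
    sidecar = {
        "pixel_size_um": movie.pixel_size,
        "frame_times_s": movie.times.tolist(),
        "bleach_events": [
            {"time_s": ev.time, "center_um": list(ev.center),
             "radius_um": ev.radius, "efficiency": ev.efficiency}
            for ev in movie.bleach_events],
        "centrosomes_um": [list(c) for c in movie.centrosomes],
        "channel": movie.channel,
        "metadata": movie.metadata,
    }
    write_json(sidecar, json_path)
    return tif_path, json_path


def read_movie(stem: str | Path) -> FrapMovie:
    stem = Path(stem)
    tif_path = stem.with_suffix(".tif")
    json_path = stem.with_suffix(".json")
    if not tif_path.exists() or not json_path.exists():
        raise ConfigError(f"movie {stem} needs both a .tif and a .json sidecar")
    frames = np.asarray(tifffile.imread(tif_path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    try:
        meta = json.loads(json_path.read_text())
        events = tuple(BleachEvent(time=ev["time_s"], center=tuple(ev["center_um"]),
                                   radius=ev["radius_um"], efficiency=ev["efficiency"])
                       for ev in meta["bleach_events"])
        return FrapMovie(frames=frames, times=np.asarray(meta["frame_times_s"]),
                         pixel_size=meta["pixel_size_um"], bleach_events=events,
                         centrosomes=tuple(tuple(c) for c in meta["centrosomes_um"]),
                         channel=meta.get("channel"), metadata=meta.get("metadata", {}))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed movie sidecar {json_path}: {exc}") from exc


def _profile_record(p: RadialProfile) -> dict:
    return {"radii_um": p.radii.tolist(), "values": p.values.tolist(),
            "n_subpixels": np.asarray(p.n_subpixels).tolist(), "spacing_um": p.spacing,
            "background_subtracted": p.background_subtracted,
            "normalized": p.normalized, "mirrored": p.mirrored}


def _profile_from_record(rec: dict) -> RadialProfile:
    return RadialProfile(radii=np.asarray(rec["radii_um"]),
                         values=np.asarray(rec["values"]),
                         n_subpixels=np.asarray(rec["n_subpixels"]),
                         spacing=rec["spacing_um"],
                         background_subtracted=rec["background_subtracted"],
                         normalized=rec["normalized"], mirrored=rec["mirrored"])


def write_profile_set(pset: ProfileSet, path: str | Path) -> Path:
    payload = {"times_s": pset.times.tolist(),
               "bleach_times_s": pset.bleach_times.tolist(),
               "n_centrosomes": pset.n_centrosomes,
               "prebleach_index": pset.prebleach_index,
               "profiles": [_profile_record(p) for p in pset.profiles]}
    return write_json(payload, path)


def read_profile_set(path: str | Path) -> ProfileSet:
    try:
        payload = json.loads(Path(path).read_text())
        return ProfileSet(times=np.asarray(payload["times_s"]),
                          profiles=[_profile_from_record(r) for r in payload["profiles"]],
                          n_centrosomes=payload["n_centrosomes"],
                          bleach_times=np.asarray(payload["bleach_times_s"]),
                          prebleach_index=payload["prebleach_index"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed profile-set file {path}: {exc}") from exc


def profiles_to_frame(pset: ProfileSet) -> pd.DataFrame:
    """Long-format table (time_s, radius_um, value, n_subpixels) for CSV export."""
    rows = []
    for t, p in zip(pset.times, pset.profiles):
        for r, v, n in zip(p.radii, p.values, np.asarray(p.n_subpixels)):
            rows.append((t, r, v, n))
    return pd.DataFrame(rows, columns=["time_s", "radius_um", "value", "n_subpixels"])


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
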