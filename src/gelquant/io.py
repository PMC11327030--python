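"""File round-trips: track tables, TrackMate-style XML, TIFF images.

Track CSVs use the schema ``track_id, frame, t_min, x_um, y_um[, z_um]``
— the same table :func:`gelquant.trajectory_metrics.read_tracks`
consumes.  Images go to TIFF with the pixel/voxel size recorded in
ImageJ-style metadata, ground truth to JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from lxml import etree

from .collagen_structure import FiberImage
from .trajectory_metrics import Trajectory

__all__ = [
    "write_tracks_csv",
    "write_trackmate_xml",
    "write_fiber_tiff",
    "read_fiber_tiff",
    "write_volume_tiff",
    "read_volume_tiff",
    "write_json_sidecar",
]


def write_tracks_csv(tracks: Sequence[Trajectory], path: str | Path) -> Path:
    """Write trajectories as one long-format CSV."""
    rows = []
    for traj in tracks:
        t = traj.times_min
        for i in range(traj.n_points):
            row = {
                "track_id": traj.track_id,
                "frame": int(traj.frames[i]),
                "t_min": float(t[i]),
                "x_um": traj.positions[i, 0],
                "y_um": traj.positions[i, 1],
            }
            if traj.ndim == 3:
                row["z_um"] = traj.positions[i, 2]
            rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_trackmate_xml(
    tracks: Sequence[Trajectory],
    path: str | Path,
    space_units: str = "micron",
    time_units: str = "min",
    detector_settings: dict | None = None,
) -> Path:
    """Write tracks in the TrackMate track-export XML dialect.

    ``detector_settings`` (e.g. the LoG threshold / blob diameter /
    linking distances used upstream) are recorded verbatim as root
    attributes — pass-through metadata, never re-executed here.
    """
    if not tracks:
        raise ValueError("no tracks to write")
    root = etree.Element(
        "Tracks",
        nTracks=str(len(tracks)),
        frameInterval=str(tracks[0].frame_interval),
        spaceUnits=space_units,
        timeUnits=time_units,
    )
    for key, value in (detector_settings or {}).items():
        root.set(key, str(value))
    for traj in tracks:
        particle = etree.SubElement(root, "particle",
                                    nSpots=str(traj.n_points))
        for i in range(traj.n_points):
            z = traj.positions[i, 2] if traj.ndim == 3 else 0.0
            etree.SubElement(
                particle, "detection",
                t=str(int(traj.frames[i])),
                x=repr(float(traj.positions[i, 0])),
                y=repr(float(traj.positions[i, 1])),
                z=repr(float(z)),
            )
    path = Path(path)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")
    return path


def write_fiber_tiff(image: FiberImage, path: str | Path) -> Path:
    """2D fiber image → TIFF with the pixel size in resolution tags."""
    path = Path(path)
    tifffile.imwrite(
        path,
        image.data.astype(np.float32),
        resolution=(1.0 / image.pixel_size, 1.0 / image.pixel_size),
        metadata={"unit": "um", "pixel_size_um": image.pixel_size,
                  "layer": image.layer},
    )
    return path


def read_fiber_tiff(path: str | Path,
                    pixel_size: float | None = None) -> FiberImage:
    """Read a 2D TIFF; pixel size from metadata unless overridden."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if pixel_size is None:
        pixel_size = float(meta.get("pixel_size_um", 0) or 0)
        if pixel_size <= 0:
            raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size")
    return FiberImage(data=data, pixel_size=pixel_size,
                      layer=meta.get("layer"))


def write_volume_tiff(volume: np.ndarray,
                      voxel_size: tuple[float, float, float],
                      path: str | Path) -> Path:
    """Two-channel (2, z, y, x) stack → TIFF with voxel size metadata."""
    path = Path(path)
    tifffile.imwrite(
        path,
        volume.astype(np.float32),
        metadata={"unit": "um", "voxel_size_um": list(voxel_size),
                  "axes": "CZYX"},
    )
    return path


def read_volume_tiff(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    voxel = meta.get("voxel_size_um")
    if voxel is None:
        raise ValueError(f"{path}: no voxel size metadata")
    return data, tuple(float(v) for v in voxel)


def write_json_sidecar(record: dict, path: str | Path) -> Path:
    """Ground-truth / metadata record as a JSON sidecar file."""
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(record, indent=2, default=default))
    return path
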