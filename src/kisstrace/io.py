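"""Image containers and on-disk formats.

Movies and volumes travel as multi-page TIFF plus a JSON sidecar carrying the
physical pixel spacing, frame interval and channel names (proprietary
microscope formats are out of scope; users convert to TIFF upstream).
Tabular results (spots, tracks, traces) are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile


@dataclass
class FrameStack:
    """A time-ordered multi-channel 2D image sequence, axes ``(t, c, y, x)``."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channels = tuple(self.channels)
        if self.data.ndim != 4:
            raise ValueError("FrameStack data must be (t, channel, y, x)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class VolumeStack:
    """A fixed-cell multi-channel z-stack, axes ``(c, z, y, x)``."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]  # (z, y, x)
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channels = tuple(self.channels)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if self.data.ndim != 4:
            raise ValueError("VolumeStack data must be (channel, z, y, x)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel axis does not match channel names")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def write_movie(stack: FrameStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(stack.data, dtype=np.float32), photometric="minisblack"
    )
    meta = {
        "kind": "live_movie",
        "axes": "TCYX",
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channels": list(stack.channels),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_movie(path: str | Path) -> FrameStack:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    data = tifffile.imread(path)
    if data.ndim == 3:  # single channel stored without channel axis
        data = data[:, None]
    return FrameStack(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        channels=tuple(meta["channels"]),
    )


def write_volume(vol: VolumeStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(vol.data, dtype=np.float32), photometric="minisblack"
    )
    meta = {
        "kind": "fixed_volume",
        "axes": "CZYX",
        "voxel_size_um": list(vol.voxel_size_um),
        "channels": list(vol.channels),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_volume(path: str | Path) -> VolumeStack:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    return VolumeStack(
        data=data,
        voxel_size_um=tuple(meta["voxel_size_um"]),
        channels=tuple(meta["channels"]),
    )


def spots_to_frame(spots: Sequence) -> pd.DataFrame:
    """Flatten SpotRecords into a DataFrame (one row per spot)."""
    rows = []
    for s in spots:
        row = {
            "frame": s.frame,
            "channel": s.channel,
            "label": s.label,
            "nucleus_id": s.nucleus_id,
            "sum_intensity": s.sum_intensity,
            "peak_intensity": s.peak_intensity,
            "area_um2": s.area_um2,
            "volume_um3": s.volume_um3,
            "low_confidence": s.low_confidence,
        }
        center = np.asarray(s.center_um, dtype=float)
        if center.size == 2:
            row["y_um"], row["x_um"] = center
        else:
            row["z_um"], row["y_um"], row["x_um"] = center
        rows.append(row)
    return pd.DataFrame(rows)


def write_spots_csv(spots: Sequence, path: str | Path) -> None:
    spots_to_frame(spots).to_csv(path, index=False)


def tracks_to_frame(tracks: Sequence) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for frame, spot in zip(tr.frames, tr.spots):
            center = np.asarray(spot.center_um, dtype=float)
            rows.append(
                {
                    "object_id": tr.object_id,
                    "channel": tr.channel,
                    "frame": frame,
                    "y_um": center[-2],
                    "x_um": center[-1],
                    "sum_intensity": spot.sum_intensity,
                    "interpolated": frame in tr.gap_frames,
                }
            )
    return pd.DataFrame(rows)


def write_tracks_csv(tracks: Sequence, path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)
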