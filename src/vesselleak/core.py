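"""Core data containers shared across pipeline stages."""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this


class ChannelRole(str, enum.Enum):
    """What a stack is used for downstream.

    Structure-only preprocessing steps (background subtraction,
    flat-field normalization) refuse ``LEAKAGE`` stacks unless
    explicitly overridden, so quantitative halos are never distorted.
    """

    STRUCTURE = "structure"
    LEAKAGE = "leakage"
    HISTOLOGY = "histology"


@dataclass
class ImageStack4D:
    """A (t, z, y, x) intensity grid with physical calibration.

    Single 3D volumes are stored as one-frame stacks; ``frame_interval_s``
    is then ignored.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (2.0, 0.692, 0.692)
    frame_interval_s: float = 15.0
    channel_role: ChannelRole = ChannelRole.STRUCTURE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected (t,z,y,x) data, got ndim={self.data.ndim}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.n_frames > 1 and self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive for time-lapse data")
        self.channel_role = ChannelRole(self.channel_role)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0

    def volume(self, t: int = 0) -> np.ndarray:
        return self.data[t]

    def with_data(self, data: np.ndarray, role: ChannelRole | None = None) -> "ImageStack4D":
        return ImageStack4D(
            data=data,
            voxel_size_um=self.voxel_size_um,
            frame_interval_s=self.frame_interval_s,
            channel_role=role if role is not None else self.channel_role,
        )

    # ---- OME-TIFF I/O -------------------------------------------------

    def save(self, path: str | Path) -> None:
        vz, vy, vx = self.voxel_size_um
        tifffile.imwrite(
            str(path),
            self.data.astype(np.float32),
            metadata={
                "axes": "TZYX",
                "PhysicalSizeZ": vz,
                "PhysicalSizeY": vy,
                "PhysicalSizeX": vx,
                "TimeIncrement": self.frame_interval_s,
                "TimeIncrementUnit": "s",
                "ChannelRole": self.channel_role.value,
            },
        )

    @classmethod
    def load(cls, path: str | Path, channel_role: ChannelRole | None = None) -> "ImageStack4D":
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            meta = {}
            if tf.ome_metadata:
                ome = tifffile.xml2dict(tf.ome_metadata)
                try:
                    meta = ome["OME"]["Image"]["Pixels"]
                except (KeyError, TypeError):
                    meta = {}
            elif tf.shaped_metadata:
                meta = tf.shaped_metadata[0]
        vz = float(meta.get("PhysicalSizeZ", 2.0))
        vy = float(meta.get("PhysicalSizeY", 0.692))
        vx = float(meta.get("PhysicalSizeX", 0.692))
        dt = float(meta.get("TimeIncrement", 15.0))
        role = channel_role or ChannelRole(meta.get("ChannelRole", "structure"))
        return cls(data=data, voxel_size_um=(vz, vy, vx), frame_interval_s=dt, channel_role=role)


def fwhm_to_sigma_px(fwhm_um: float, voxel_size_um: tuple[float, ...]) -> tuple[float, ...]:
    """Convert an isotropic physical FWHM to per-axis sigmas in pixels."""
    if fwhm_um <= 0:
        raise ValueError("fwhm_um must be positive")
    return tuple(fwhm_um * FWHM_TO_SIGMA / v for v in voxel_size_um)


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
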