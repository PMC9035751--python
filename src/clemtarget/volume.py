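"""Axis-ordered 3D image volumes with physical voxel metadata.

Conventions used throughout the package:

* World frame: right-handed, units of nanometres, ``z = 0`` at the glass
  substrate plane.
* Voxel-centre convention: index ``i`` along a world axis maps to world
  coordinate ``origin + i * voxel_size`` (0-based indices, half-open voxel
  extents).
* ``axis_order`` names the world axis of each storage axis.  ``"XYZ"``
  means ``values[ix, iy, iz]``; ``"XZY"`` (the native orientation of
  serial FIB-SEM slice stacks, where each frame is an X-Z image and the
  milling direction is Y) means ``values[ix, iz, iy]``.
* ``voxel_size`` is always given in world-axis order ``(dx, dy, dz)``
  regardless of the storage layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = ["Modality", "ImageVolume", "LabelVolume"]


class Modality(str, Enum):
    """Acquisition modality tags."""

    FM_confocal = "FM_confocal"
    FM_integrated = "FM_integrated"
    EM_BSE = "EM_BSE"
    EM_SE = "EM_SE"

    @property
    def is_fm(self) -> bool:
        return self.value.startswith("FM")

    @property
    def is_em(self) -> bool:
        return self.value.startswith("EM")


_AXIS_ORDERS = {"XYZ": (0, 1, 2), "XZY": (0, 2, 1)}


@dataclass
class ImageVolume:
    """A 3D scalar grid with per-axis voxel size and a modality tag.

    Parameters
    ----------
    values
        3D array of intensities (arbitrary units).
    voxel_size
        ``(dx, dy, dz)`` voxel pitch in nm, world-axis order.
    axis_order
        ``"XYZ"`` or ``"XZY"``; names the world axis of each storage axis.
    origin
        World coordinates (nm) of the centre of voxel ``(0, 0, 0)``.
    modality
        One of :class:`Modality`.
    channel_name
        Free-text channel label.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    axis_order: str = "XYZ"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.FM_confocal
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        if self.axis_order not in _AXIS_ORDERS:
            raise ValueError(f"axis_order must be one of {sorted(_AXIS_ORDERS)}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("values must be finite")
        self.modality = Modality(self.modality)

    # -- geometry helpers -------------------------------------------------

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        """Grid extent per world axis (nx, ny, nz)."""
        perm = _AXIS_ORDERS[self.axis_order]
        shape = [0, 0, 0]
        for storage_axis, world_axis in enumerate(perm):
            shape[world_axis] = self.values.shape[storage_axis]
        return tuple(shape)

    def axis_coords(self, world_axis: int) -> np.ndarray:
        """World coordinates (nm) of voxel centres along a world axis."""
        n = self.shape_xyz[world_axis]
        return self.origin[world_axis] + np.arange(n) * self.voxel_size[world_axis]

    def to_xyz(self) -> "ImageVolume":
        """Return a view of this volume in canonical XYZ storage order."""
        if self.axis_order == "XYZ":
            return self
        return replace(self, values=np.swapaxes(self.values, 1, 2), axis_order="XYZ")

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points (N, 3) nm to fractional XYZ grid indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional XYZ grid indices (N, 3) to world points in nm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_size)

    def like(self, values: np.ndarray, **overrides) -> "ImageVolume":
        """New volume sharing this volume's grid metadata."""
        kwargs = dict(
            voxel_size=self.voxel_size,
            axis_order=self.axis_order,
            origin=self.origin,
            modality=self.modality,
            channel_name=self.channel_name,
        )
        kwargs.update(overrides)
        return ImageVolume(values=values, **kwargs)


@dataclass
class LabelVolume:
    """Integer organelle labels sharing an :class:`ImageVolume` grid.

    ``labels`` is stored in XYZ order; 0 is background.  ``class_map``
    assigns an organelle class name to every nonzero label.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    class_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.class_map)
        if missing:
            raise ValueError(f"class_map missing entries for labels {sorted(missing)}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def class_mask(self, cls: str) -> np.ndarray:
        ids = [k for k, v in self.class_map.items() if v == cls]
        return np.isin(self.labels, ids)
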