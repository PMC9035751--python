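"""Rigid FM-to-EM coordinate transforms.

The registration model is a rotation about the optical (z) axis plus a 3D
translation, optionally with per-axis scale.  The flat glass substrate
pins the z axis of both modalities, so a full 3D rotation is deliberately
excluded; the optional z-scale absorbs axial calibration mismatch of the
fluorescence stack.

A transform maps FM-frame world coordinates (nm) to EM-frame world
coordinates: ``p_em = R_z(theta) @ (scale * p_fm) + t``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Transform3D"]


@dataclass(frozen=True)
class Transform3D:
    """Z-axis rotation + translation (+ optional per-axis scale), nm units."""

    theta_z: float = 0.0  # degrees, counter-clockwise about +z
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(s == 0 for s in self.scale):
            raise ValueError("scale components must be nonzero")

    @property
    def rotation_matrix(self) -> np.ndarray:
        th = np.deg2rad(self.theta_z)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform points (N, 3) or (3,) from FM frame to EM frame."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = (self.rotation_matrix @ (pts * np.asarray(self.scale)).T).T
        out = out + np.asarray(self.translation)
        return out[0] if single else out

    def inverse(self) -> "Transform3D":
        Rinv = self.rotation_matrix.T
        s = np.asarray(self.scale)
        t = np.asarray(self.translation)
        # p_fm = (Rinv @ (p_em - t)) / s
        return Transform3D(
            theta_z=-self.theta_z,
            translation=tuple(-(Rinv @ t) / s),
            scale=tuple(1.0 / s),
        )

    def compose(self, other: "Transform3D") -> "Transform3D":
        """Return the transform applying ``other`` first, then ``self``.

        Only defined when the combined map stays in the z-rotation +
        diagonal-scale family, i.e. when either transform has isotropic
        in-plane scale or zero rotation.
        """
        sx, sy, _ = self.scale
        if not (np.isclose(sx, sy) or np.isclose(other.theta_z % 360.0, 0.0)):
            raise ValueError(
                "composition leaves the z-rotation + diagonal-scale family"
            )
        theta = self.theta_z + other.theta_z
        scale = tuple(np.asarray(self.scale) * np.asarray(other.scale))
        t = self.apply(np.asarray(other.translation))
        # self.apply(other.apply(p)) = R1 S1 R2 S2 p + R1 S1 t2 + t1
        # with S1 commuting with R2 under the guard above.
        return Transform3D(theta_z=theta, translation=tuple(t), scale=scale)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "theta_z_deg": self.theta_z,
            "translation_nm": list(self.translation),
            "scale": list(self.scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Transform3D":
        return cls(
            theta_z=float(d["theta_z_deg"]),
            translation=tuple(float(v) for v in d["translation_nm"]),
            scale=tuple(float(v) for v in d.get("scale", (1.0, 1.0, 1.0))),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Transform3D":
        return cls.from_dict(json.loads(Path(path).read_text()))
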