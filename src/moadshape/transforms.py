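"""Rigid-body transforms (proper rotation + translation) in 3D.

A :class:`RigidTransform` acts on coordinates as ``x -> R x + t`` where
``R`` is a proper rotation (det = +1) stored as a unit quaternion and
``t`` a translation in Angstrom.  Quaternions follow the scipy scalar-last
convention ``(x, y, z, w)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform: rotation (unit quaternion) + translation (A)."""

    quat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        q = np.asarray(self.quat, dtype=float).reshape(4)
        n = float(np.linalg.norm(q))
        if not np.isfinite(n) or abs(n - 1.0) > 1e-6:
            raise ValueError(f"quaternion norm {n!r} is not 1")
        object.__setattr__(self, "quat", q / n)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_rotation(cls, rotation: Rotation, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(quat=rotation.as_quat(), translation=np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls.from_rotation(Rotation.from_matrix(matrix), translation)

    # -- algebra ------------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quat)

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply ``x -> R x + t`` to an (n, 3) array (or a single point)."""
        pts = np.asarray(points, dtype=float)
        return self.rotation.apply(pts) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        r = self.rotation * other.rotation
        t = self.rotation.apply(other.translation) + self.translation
        return RigidTransform.from_rotation(r, t)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        return RigidTransform.from_rotation(rinv, -rinv.apply(self.translation))
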