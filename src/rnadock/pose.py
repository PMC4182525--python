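"""Rigid-body pose: three Euler angles plus a translation.

A pose moves the mobile partner (the RNA) relative to the fixed partner
(the protein).  Rotation is applied about a pivot point -- by convention
the mobile partner's geometric centre -- so that rotation and translation
amplitudes act approximately independently on the interface geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

EULER_CONVENTION = "ZYX"


@dataclass(frozen=True)
class Pose:
    """Rigid transform: intrinsic ZYX Euler rotation (degrees) + translation (A)."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @staticmethod
    def identity() -> "Pose":
        return Pose()

    @property
    def is_identity(self) -> bool:
        return all(a == 0.0 for a in self.rotation) and all(
            t == 0.0 for t in self.translation
        )

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            EULER_CONVENTION, self.rotation, degrees=True
        ).as_matrix()

    def apply(self, coords: np.ndarray, pivot: np.ndarray) -> np.ndarray:
        """Rotate ``coords`` about ``pivot`` then translate.

        Parameters
        ----------
        coords : (n, 3) array of positions, A.
        pivot : (3,) rotation centre, A.
        """
        coords = np.asarray(coords, dtype=float)
        pivot = np.asarray(pivot, dtype=float)
        if self.is_identity:
            return coords.copy()
        R = self.rotation_matrix()
        return (coords - pivot) @ R.T + pivot + np.asarray(self.translation)

    def compose(self, other: "Pose", pivot: np.ndarray) -> "Pose":
        """Pose equivalent to applying ``other`` first, then ``self``.

        Both poses are interpreted about the same ``pivot``.
        """
        Ra = self.rotation_matrix()
        Rb = other.rotation_matrix()
        R = Ra @ Rb
        ta = np.asarray(self.translation, dtype=float)
        tb = np.asarray(other.translation, dtype=float)
        # x -> Ra (Rb (x - p) + p + tb - p) + p + ta
        t = Ra @ tb + ta
        angles = Rotation.from_matrix(R).as_euler(EULER_CONVENTION, degrees=True)
        return Pose(rotation=tuple(angles), translation=tuple(t))
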