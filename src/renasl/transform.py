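"""2-D affine transforms parameterized the way breathing motion is modelled.

A kidney that shifts between breath-holds is well described by a small
translation, rotation, anisotropic scaling and shear.  The transform acts
about a user-supplied center (typically the contour centroid) so that the
rotation/scale/shear parameters stay decoupled from the translation.

Coordinate conventions: points are (row, col) with 0-based pixel-center
indexing; internally matrices act on homogeneous (x, y) = (col, row)
vectors, matching :mod:`skimage.transform`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import ProjectiveTransform, warp

__all__ = ["AffineTransform2D", "warp_image"]

# Normalisation scales that bring each parameter to order 1:
# 10 px of translation, 10 degrees of rotation, scale-1 and shear as-is.
_PARAM_SCALES = np.array([10.0, 10.0, 10.0, 1.0, 1.0, 1.0])


@dataclass(frozen=True)
class AffineTransform2D:
    """Translation + rotation + scaling + shearing about a center point.

    Parameters
    ----------
    tx, ty : float
        Translation in pixels along columns (x) and rows (y).
    rotation : float
        Rotation in degrees, positive from +x towards +y.
    scale_x, scale_y : float
        Anisotropic scale factors; must be positive.
    shear : float
        Shear coefficient applied along x as a function of y.
    """

    tx: float = 0.0
    ty: float = 0.0
    rotation: float = 0.0
    scale_x: float = 1.0
    scale_y: float = 1.0
    shear: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("scale factors must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            self.tx == 0.0
            and self.ty == 0.0
            and self.rotation == 0.0
            and self.scale_x == 1.0
            and self.scale_y == 1.0
            and self.shear == 0.0
        )

    def matrix(self, center: tuple[float, float]) -> np.ndarray:
        """3x3 homogeneous matrix in (x, y) coordinates.

        ``center`` is given as (row, col); rotation, scaling and shearing
        are performed about it, then the translation is added.
        """
        cy, cx = float(center[0]), float(center[1])
        th = np.deg2rad(self.rotation)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0, 0, 1.0]]
        )
        sh = np.array([[1.0, self.shear, 0.0], [0.0, 1.0, 0.0], [0, 0, 1.0]])
        sc = np.diag([self.scale_x, self.scale_y, 1.0])
        t_in = np.array([[1.0, 0, -cx], [0, 1.0, -cy], [0, 0, 1.0]])
        t_out = np.array([[1.0, 0, cx + self.tx], [0, 1.0, cy + self.ty], [0, 0, 1.0]])
        return t_out @ rot @ sh @ sc @ t_in

    def apply_to_points(
        self, points_rc: np.ndarray, center: tuple[float, float]
    ) -> np.ndarray:
        """Map an (N, 2) array of (row, col) points; returns floats."""
        pts = np.asarray(points_rc, dtype=float)
        xy = np.column_stack([pts[:, 1], pts[:, 0], np.ones(len(pts))])
        out = xy @ self.matrix(center).T
        return np.column_stack([out[:, 1], out[:, 0]])

    # -- parameter-vector plumbing used by the registration optimizer ------
    def to_normalized(self) -> np.ndarray:
        raw = np.array(
            [self.tx, self.ty, self.rotation, self.scale_x - 1.0, self.scale_y - 1.0, self.shear]
        )
        return raw / _PARAM_SCALES

    @staticmethod
    def from_normalized(x: np.ndarray) -> "AffineTransform2D":
        raw = np.asarray(x, dtype=float) * _PARAM_SCALES
        return AffineTransform2D(
            tx=raw[0],
            ty=raw[1],
            rotation=raw[2],
            scale_x=1.0 + raw[3],
            scale_y=1.0 + raw[4],
            shear=raw[5],
        )

    def translation_norm(self) -> float:
        return float(np.hypot(self.tx, self.ty))

    def deviation_from_identity(self) -> float:
        """Euclidean norm of the normalized parameter vector."""
        return float(np.linalg.norm(self.to_normalized()))

    def with_translation(self, tx: float, ty: float) -> "AffineTransform2D":
        return replace(self, tx=tx, ty=ty)


def warp_image(
    image: np.ndarray,
    transform: AffineTransform2D,
    center: tuple[float, float],
    *,
    inverse: bool = False,
    order: int = 1,
    mode: str = "edge",
) -> np.ndarray:
    """Resample ``image`` so its content moves by ``transform``.

    With ``inverse=True`` the content is moved by the inverse transform,
    which is how an acquisition is brought back into the reference frame.
    The identity transform is a no-op copy, so noiseless round-trips are
    bit-exact.
    """
    if transform.is_identity:
        return np.array(image, dtype=float, copy=True)
    m = transform.matrix(center)
    # skimage's warp wants the output->input (x, y) map.
    inv_map = m if inverse else np.linalg.inv(m)
    return warp(
        np.asarray(image, dtype=float),
        ProjectiveTransform(matrix=inv_map),
        order=order,
        mode=mode,
        preserve_range=True,
    )
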