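"""Homogeneous world-to-world affine transforms and their parameterisation.

A transform maps points in the moving image's world frame to the fixed
image's world frame.  The rigid subcase has 6 parameters (3 rotations in
degrees, 3 translations in mm); the full affine adds 3 log-scales and 3
shears, 12 parameters in total.  Rotation/scale/shear act about a centre
point so the parameters stay well conditioned for head-sized volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["AffineTransform", "params_to_matrix", "matrix_is_rigid"]

RIGID_NPARAMS = 6
AFFINE_NPARAMS = 12


@dataclass
class AffineTransform:
    """4x4 homogeneous world-mm to world-mm mapping with a model tag."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))
    model: str = "affine"  # "rigid" or "affine"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row of a homogeneous transform must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform is singular")
        if self.model not in ("rigid", "affine"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "rigid" and not matrix_is_rigid(self.matrix):
            raise ValueError("matrix tagged rigid has a non-orthonormal rotation block")

    @classmethod
    def identity(cls, model: str = "affine") -> "AffineTransform":
        return cls(np.eye(4), model=model)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) world points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply `other` first, then `self`."""
        model = "rigid" if self.model == other.model == "rigid" else "affine"
        return AffineTransform(self.matrix @ other.matrix, model=model)

    def invert(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), model=self.model)

    def save(self, path: str | Path) -> None:
        payload = {"model": self.model, "matrix": self.matrix.tolist()}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["matrix"]), model=payload.get("model", "affine"))


def matrix_is_rigid(matrix: np.ndarray, tol: float = 1e-6) -> bool:
    block = matrix[:3, :3]
    return bool(
        np.allclose(block.T @ block, np.eye(3), atol=tol)
        and abs(np.linalg.det(block) - 1.0) < tol
    )


def params_to_matrix(params: np.ndarray, model: str, center: np.ndarray) -> np.ndarray:
    """Build a 4x4 matrix from the 6- or 12-parameter vector.

    params = (rx, ry, rz [deg], tx, ty, tz [mm]) for rigid, plus
    (log sx, log sy, log sz, shear xy, xz, yz) for affine.  The linear part
    is R @ S @ H applied about `center`, followed by the translation.
    """
    params = np.asarray(params, dtype=float)
    expected = RIGID_NPARAMS if model == "rigid" else AFFINE_NPARAMS
    if params.shape != (expected,):
        raise ValueError(f"{model} model expects {expected} parameters, got {params.shape}")
    rot = Rotation.from_euler("xyz", params[:3], degrees=True).as_matrix()
    linear = rot
    if model == "affine":
        scale = np.diag(np.exp(params[6:9]))
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = params[9:12]
        linear = rot @ scale @ shear
    center = np.asarray(center, dtype=float)
    matrix = np.eye(4)
    matrix[:3, :3] = linear
    matrix[:3, 3] = center - linear @ center + params[3:6]
    return matrix
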