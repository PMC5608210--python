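"""Rigid (Euclidean) alignment of volumes acquired at different pressures.

Volumes of the same lung imaged at different peak-inspiratory pressures are
related by a rotation R and translation t.  The transform is estimated from
user-provided landmark pairs by solving the orthogonal Procrustes problem
(Kabsch, SVD with sign correction — no scaling, no reflection), and applied
by resampling into the fixed frame so all fields of view share one shape.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volio import BinaryVolume, GrayVolume


@dataclasses.dataclass
class RigidTransform:
    """y = R @ x + t, with R orthonormal, det(R) = +1; t in µm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1, no reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation, self.rotation @ other.translation + self.translation)


def estimate_rigid(landmarks_fixed: np.ndarray, landmarks_moving: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping moving landmarks onto fixed ones.

    Requires >= 3 non-collinear point pairs (µm, (z, y, x) order).
    """
    fixed = np.asarray(landmarks_fixed, dtype=float)
    moving = np.asarray(landmarks_moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("landmark lists must be (n, 3) arrays of equal length")
    if fixed.shape[0] < 3:
        raise ValueError("at least 3 landmark pairs are required")
    mu_f = fixed.mean(axis=0)
    mu_m = moving.mean(axis=0)
    fc = fixed - mu_f
    mc = moving - mu_m
    if np.linalg.matrix_rank(mc, tol=1e-9 * max(1.0, np.abs(mc).max())) < 2:
        raise ValueError("landmarks are collinear/degenerate; cannot determine a unique rotation")
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_f - rot @ mu_m
    return RigidTransform(rot, t)


def landmark_rms(transform: RigidTransform, fixed: np.ndarray, moving: np.ndarray) -> float:
    """Root-mean-square landmark distance after applying the transform."""
    resid = transform.apply(moving) - np.asarray(fixed, dtype=float)
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def apply_rigid(
    vol: GrayVolume | BinaryVolume,
    transform: RigidTransform,
    out_shape: tuple[int, int, int] | None = None,
) -> GrayVolume | BinaryVolume:
    """Resample a moving volume into the fixed frame, cropped to ``out_shape``.

    Gray volumes use linear interpolation with constant fill outside; binary
    masks use nearest-neighbour to avoid fractional labels.
    """
    out_shape = tuple(out_shape if out_shape is not None else vol.shape)
    if len(out_shape) != 3 or min(out_shape) < 1:
        raise ValueError(f"out_shape must be 3 positive integers, got {out_shape}")
    # output voxel i (fixed frame) samples input voxel x = R^T (i*s - t) / s
    rot_inv = transform.rotation.T
    offset = -rot_inv @ transform.translation / vol.spacing
    is_binary = isinstance(vol, BinaryVolume)
    data = vol.data.astype(np.float32) if not is_binary else vol.data
    out = ndimage.affine_transform(
        data,
        matrix=rot_inv,
        offset=offset,
        output_shape=out_shape,
        order=0 if is_binary else 1,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    result = vol.replace(out.astype(bool) if is_binary else out)
    result.record("apply_rigid", out_shape=list(out_shape))
    return result


def read_landmarks(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a landmark CSV with columns fixed_z,fixed_y,fixed_x,moving_z,moving_y,moving_x (µm)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = ["fixed_z", "fixed_y", "fixed_x", "moving_z", "moving_y", "moving_x"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV is missing columns {missing}")
    return df[cols[:3]].to_numpy(float), df[cols[3:]].to_numpy(float)
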