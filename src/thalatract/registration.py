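"""AC-fixed rigid (6-DOF) landmark normalization and landmark QC.

Subjects are mapped into a template frame by a rotation + translation that
keeps the anterior commissure (AC) exactly fixed while aligning the AC-PC
line and the midsagittal plane.  Because those three constraints determine a
rigid transform completely, the rotation is built in closed form from the
two AC-PC frames — no least-squares fit is involved, and no scaling is ever
applied (a subject whose AC-PC line is shorter than the template's keeps its
own length after normalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LandmarkSet, as_vec3

log = logging.getLogger("thalatract.registration")

_ORTHO_TOL = 1e-8


@dataclass
class RigidTransform:
    """A proper rigid transform p -> R p + t (world mm to world mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = as_vec3(self.translation)
        R = self.rotation
        if np.linalg.norm(R.T @ R - np.eye(3)) >= 1e-6:
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) >= 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def to_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        return cls(M[:3, :3], M[:3, 3])

    def save(self, path) -> None:
        """Write as a plain-text 4x4 homogeneous matrix (world-to-world, mm)."""
        np.savetxt(path, self.to_matrix(), fmt="%.12g")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))


def acpc_frame(lm: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal AC-PC frame (origin, 3x3 axes-as-columns).

    origin = AC; axis 1 points from AC to PC; axis 2 is the component of
    (IH - AC) orthogonal to axis 1 (in-plane superior direction); axis 3 is
    their cross product (normal to the midsagittal plane).
    """
    lm.validate()
    a1 = lm.PC - lm.AC
    a1 = a1 / np.linalg.norm(a1)
    v = lm.IH - lm.AC
    a2 = v - (v @ a1) * a1
    n2 = np.linalg.norm(a2)
    if n2 <= lm.collinearity_tol:
        raise ValueError("IH lies on the AC-PC line; midsagittal plane undefined")
    a2 = a2 / n2
    a3 = np.cross(a1, a2)
    axes = np.column_stack([a1, a2, a3])
    assert np.linalg.norm(axes.T @ axes - np.eye(3)) < 1e-10
    return lm.AC.copy(), axes


def register_landmarks(subject: LandmarkSet, template: LandmarkSet) -> RigidTransform:
    """Rigid transform taking the subject frame onto the template frame.

    Maps subject AC exactly onto template AC and rotates the subject AC-PC
    frame onto the template's.  No scaling: subject PC lands on the template
    AC-PC *line*, at the subject's own AC-PC distance from AC.
    """
    o_s, F_s = acpc_frame(subject)
    o_t, F_t = acpc_frame(template)
    R = F_t @ F_s.T
    t = o_t - R @ o_s
    T = RigidTransform(R, t)
    residual = np.linalg.norm(T.apply(subject.AC) - template.AC)
    if residual >= 1e-9:
        raise AssertionError(f"AC fixity violated: residual {residual:g} mm")
    return T


def apply_transform(T: RigidTransform, points) -> np.ndarray:
    """Map a point or point list through a rigid transform."""
    return T.apply(points)


def random_rigid(
    rng: np.random.Generator,
    max_angle_deg: float,
    max_translation_mm: float,
    about: np.ndarray | None = None,
) -> RigidTransform:
    """A random proper rigid transform (uniform axis, bounded angle/shift).

    If ``about`` is given the rotation pivots around that point instead of
    the world origin, which keeps transformed anatomy near its original
    location.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    if about is not None:
        about = as_vec3(about)
        t = t + about - R @ about
    return RigidTransform(R, t)


def transform_landmarks(T: RigidTransform, lm: LandmarkSet) -> LandmarkSet:
    return LandmarkSet(AC=T.apply(lm.AC), PC=T.apply(lm.PC), IH=T.apply(lm.IH))


def landmark_discrepancy(
    a: dict[str, np.ndarray], b: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-landmark displacement between two named point sets (QC).

    Returns a tidy frame with per-axis components and the Euclidean
    magnitude (mm) for every landmark name; summarize with
    :func:`discrepancy_summary`.
    """
    if set(a) != set(b):
        raise ValueError(
            f"landmark name mismatch: {sorted(set(a) ^ set(b))}"
        )
    rows = []
    for name in sorted(a):
        d = as_vec3(b[name]) - as_vec3(a[name])
        rows.append(
            {
                "landmark": name,
                "dx_mm": d[0],
                "dy_mm": d[1],
                "dz_mm": d[2],
                "magnitude_mm": float(np.linalg.norm(d)),
            }
        )
    return pd.DataFrame(rows)


def resample_mask(mask, T: RigidTransform, template) -> "object":
    """Nearest-neighbor resampling of a binary mask into a template grid.

    ``T`` maps subject world coordinates onto template world coordinates;
    each template voxel center is pulled back through ``T``⁻¹ into the
    subject grid and assigned the nearest subject voxel's value.
    """
    from scipy.ndimage import affine_transform

    from .core import VoxelGrid, require_binary

    data = require_binary(mask, "mask").astype(np.uint8)
    # template voxel -> template world -> subject world -> subject voxel
    M = (
        np.linalg.inv(mask.affine)
        @ T.inverse().to_matrix()
        @ template.affine
    )
    out = affine_transform(
        data,
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=template.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return VoxelGrid(out.astype(np.uint8), template.affine)


def discrepancy_summary(table: pd.DataFrame) -> dict[str, float]:
    """Mean ± sample SD (n-1) of displacement magnitudes across landmarks."""
    mags = table["magnitude_mm"].to_numpy()
    return {
        "mean_mm": float(np.mean(mags)),
        "sd_mm": float(np.std(mags, ddof=1)) if len(mags) > 1 else 0.0,
        "max_mm": float(np.max(mags)),
    }
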