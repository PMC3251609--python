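"""Digital fiber phantoms: synthetic subjects with known thalamo-cortical bundles.

A phantom subject emulates what the analysis needs from a real scan after
preprocessing: a brain mask, a thalamic seed mask, cortical target masks, a
per-voxel fiber-orientation field, AC/PC/IH landmarks — plus the ground truth
the real data never offers, the exact mm location of each bundle's thalamic
terminus ("truth peak").

Geometry is deliberately simple: a spherical thalamus, ball-shaped cortical
patches, and curved quadratic (Bezier) bundle centerlines.  Each bundle is a
tube of voxels carrying the centerline tangent as their orientation; the tube
narrows to a thin "mouth" inside the thalamus so that the bundle has a
well-defined thalamic terminus, mirroring the convergence of thalamo-cortical
fibers onto their nucleus.  Voxels off every bundle are isotropic
(no stored direction) and terminate streamlines.

Cohorts displace each bundle's thalamic origin by an independent 3D Gaussian
offset per subject (per-axis SD ``peak_sd_mm``) — the controllable stand-in
for inter-individual anatomical variability — and can additionally move each
subject into its own rigidly-perturbed world frame with a recorded transform,
giving registration a known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .core import LandmarkSet, OrientationField, VoxelGrid, as_vec3
from .registration import RigidTransform, random_rigid

log = logging.getLogger("thalatract.phantom")

#: tube radius (mm) of the bundle "mouth" inside the thalamus
MOUTH_RADIUS_MM = 1.2
#: perpendicular offset of the Bezier control point, as a fraction of chord length
CURVATURE_FRACTION = 0.15
#: dense samples along each bundle centerline
N_CENTERLINE_SAMPLES = 256


@dataclass
class BundleSpec:
    """One thalamo-cortical bundle: terminus, cortical patch, tube geometry."""

    target_name: str
    thalamic_origin_mm: np.ndarray
    cortical_patch_center_mm: np.ndarray
    cortical_patch_radius_mm: float
    bundle_radius_mm: float = 2.0
    dispersion_deg: float = 0.0

    def __post_init__(self) -> None:
        self.thalamic_origin_mm = as_vec3(self.thalamic_origin_mm)
        self.cortical_patch_center_mm = as_vec3(self.cortical_patch_center_mm)
        if self.cortical_patch_radius_mm <= 0 or self.bundle_radius_mm <= 0:
            raise ValueError("bundle and patch radii must be positive")
        if not (0 <= self.dispersion_deg < 90):
            raise ValueError("dispersion_deg must lie in [0, 90)")


@dataclass
class PhantomSpec:
    """Full recipe for one synthetic subject."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 1.0
    thalamus_center_mm: np.ndarray = field(
        default_factory=lambda: np.array([10.0, 16.0, 14.0])
    )
    thalamus_radius_mm: float = 6.0
    bundles: list[BundleSpec] = field(default_factory=list)
    landmark_positions_mm: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            "AC": np.array([16.0, 26.0, 12.0]),
            "PC": np.array([16.0, 14.0, 12.0]),
            "IH": np.array([16.0, 20.0, 24.0]),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.thalamus_center_mm = as_vec3(self.thalamus_center_mm)
        self.landmark_positions_mm = {
            k: as_vec3(v) for k, v in self.landmark_positions_mm.items()
        }
        self.validate()

    # --- validation ------------------------------------------------------------

    def validate(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape components must be >= 16")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.thalamus_radius_mm <= 0:
            raise ValueError("thalamus_radius_mm must be positive")
        LandmarkSet(**{k: self.landmark_positions_mm[k] for k in ("AC", "PC", "IH")})
        extent = (np.asarray(self.grid_shape) - 1) * self.voxel_size_mm
        for b in self.bundles:
            for name, p in (
                ("thalamic_origin_mm", b.thalamic_origin_mm),
                ("cortical_patch_center_mm", b.cortical_patch_center_mm),
            ):
                if np.any(p < 0) or np.any(p > extent):
                    raise ValueError(
                        f"bundle '{b.target_name}': {name} {p} outside grid extent {extent}"
                    )
            r = np.linalg.norm(b.thalamic_origin_mm - self.thalamus_center_mm)
            if r >= self.thalamus_radius_mm:
                raise ValueError(
                    f"bundle '{b.target_name}': thalamic origin outside the thalamus"
                )
            gap = np.linalg.norm(b.cortical_patch_center_mm - self.thalamus_center_mm)
            if gap <= self.thalamus_radius_mm + b.cortical_patch_radius_mm:
                raise ValueError(
                    f"bundle '{b.target_name}': cortical patch overlaps the thalamus"
                )

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0] = A[1, 1] = A[2, 2] = self.voxel_size_mm
        return A

    # --- (de)serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": float(self.voxel_size_mm),
            "thalamus_center_mm": self.thalamus_center_mm.tolist(),
            "thalamus_radius_mm": float(self.thalamus_radius_mm),
            "landmark_positions_mm": {
                k: v.tolist() for k, v in self.landmark_positions_mm.items()
            },
            "seed": int(self.seed),
            "bundles": [
                {
                    "target_name": b.target_name,
                    "thalamic_origin_mm": b.thalamic_origin_mm.tolist(),
                    "cortical_patch_center_mm": b.cortical_patch_center_mm.tolist(),
                    "cortical_patch_radius_mm": float(b.cortical_patch_radius_mm),
                    "bundle_radius_mm": float(b.bundle_radius_mm),
                    "dispersion_deg": float(b.dispersion_deg),
                }
                for b in self.bundles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["bundles"] = [BundleSpec(**b) for b in d.get("bundles", [])]
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SyntheticSubject:
    """One generated subject with ground truth attached."""

    brain_mask: VoxelGrid
    thalamus_mask: VoxelGrid
    target_masks: dict[str, VoxelGrid]
    orientation_field: OrientationField
    landmarks: LandmarkSet
    truth_peaks_mm: dict[str, np.ndarray]
    #: recorded world-frame perturbation (template -> subject), identity if None
    world_transform: RigidTransform | None = None

    def validate(self) -> None:
        brain = self.brain_mask.data.astype(bool)
        thal = self.thalamus_mask.data.astype(bool)
        if np.any(thal & ~brain):
            raise ValueError("thalamus mask extends outside the brain mask")
        for name, m in self.target_masks.items():
            tm = m.data.astype(bool)
            if np.any(tm & ~brain):
                raise ValueError(f"target '{name}' extends outside the brain mask")
            if np.any(tm & thal):
                raise ValueError(f"target '{name}' overlaps the thalamus")
        self.orientation_field.validate_units()


def default_spec(dispersion_deg: float = 0.0, seed: int = 0) -> PhantomSpec:
    """The stock two-bundle phantom: thalamo-premotor and thalamo-motor tubes.

    The premotor-connected territory stands in for the putative Vop, the
    motor-connected one for the putative Vim.
    """
    return PhantomSpec(
        bundles=[
            BundleSpec(
                target_name="premotor",
                thalamic_origin_mm=[10.0, 18.5, 14.0],
                cortical_patch_center_mm=[27.0, 22.0, 16.0],
                cortical_patch_radius_mm=3.0,
                dispersion_deg=dispersion_deg,
            ),
            BundleSpec(
                target_name="motor",
                thalamic_origin_mm=[10.0, 13.0, 14.0],
                cortical_patch_center_mm=[27.0, 10.0, 16.0],
                cortical_patch_radius_mm=3.0,
                dispersion_deg=dispersion_deg,
            ),
        ],
        seed=seed,
    )


# --- geometry helpers ---------------------------------------------------------


def _bezier(origin: np.ndarray, target: np.ndarray, t: np.ndarray):
    """Quadratic Bezier centerline and unit tangents, origin -> target.

    The control point is offset perpendicular to the chord by a fixed fraction
    of its length, giving every bundle a gentle curve.
    """
    chord = target - origin
    length = np.linalg.norm(chord)
    u = chord / length
    perp = np.array([0.0, 0.0, 1.0]) - u * u[2]
    if np.linalg.norm(perp) < 1e-8:
        perp = np.array([0.0, 1.0, 0.0]) - u * u[1]
    perp /= np.linalg.norm(perp)
    ctrl = 0.5 * (origin + target) + CURVATURE_FRACTION * length * perp

    t = t[:, None]
    pts = (1 - t) ** 2 * origin + 2 * t * (1 - t) * ctrl + t**2 * target
    dpts = 2 * (1 - t) * (ctrl - origin) + 2 * t * (target - ctrl)
    tangents = dpts / np.linalg.norm(dpts, axis=1, keepdims=True)
    return pts, tangents


def _paint_bundle(
    field: OrientationField,
    bundle: BundleSpec,
    spec: PhantomSpec,
    coords: np.ndarray,
) -> None:
    """Rasterize one bundle's tube into the orientation field (in place)."""
    t = np.linspace(0.0, 1.0, N_CENTERLINE_SAMPLES)
    pts, tangents = _bezier(
        bundle.thalamic_origin_mm, bundle.cortical_patch_center_mm, t
    )
    dist, idx = cKDTree(pts).query(coords.reshape(-1, 3))
    dist = dist.reshape(spec.grid_shape)
    idx = idx.reshape(spec.grid_shape)

    # tube radius depends on whether the nearest centerline point is still
    # inside the thalamus (narrow mouth) or already en route to cortex
    in_thal = (
        np.linalg.norm(pts - spec.thalamus_center_mm, axis=1)
        < spec.thalamus_radius_mm
    )
    radius = np.where(in_thal[idx], MOUTH_RADIUS_MM, bundle.bundle_radius_mm)
    inside = dist <= radius

    tang = tangents[idx[inside]]
    n = field.n_directions[inside]
    dirs = field.directions[inside]
    disp = field.dispersion_deg[inside]

    free = n < 2
    if np.any(~free):
        log.debug(
            "bundle %s: %d voxels already carry two fibers, skipped",
            bundle.target_name,
            int(np.sum(~free)),
        )
    slot = n[free]
    dirs[np.flatnonzero(free), slot] = tang[free]
    n[free] += 1
    disp[free] = np.maximum(disp[free], bundle.dispersion_deg)

    field.n_directions[inside] = n
    field.directions[inside] = dirs
    field.dispersion_deg[inside] = disp


# --- public generators --------------------------------------------------------


def generate_subject(spec: PhantomSpec) -> SyntheticSubject:
    """Build one synthetic subject from its spec.

    Deterministic: the subject's anatomy is a pure function of the spec
    (stochasticity enters only at tracking time, through the per-voxel
    dispersion stored in the orientation field).
    """
    spec.validate()
    affine = spec.affine
    shape = spec.grid_shape

    brain = VoxelGrid(np.ones(shape, dtype=np.uint8), affine)
    coords = brain.world_coordinates()

    thal = (
        np.linalg.norm(coords - spec.thalamus_center_mm, axis=-1)
        <= spec.thalamus_radius_mm
    )
    thalamus = VoxelGrid(thal.astype(np.uint8), affine)

    targets: dict[str, VoxelGrid] = {}
    for b in spec.bundles:
        patch = (
            np.linalg.norm(coords - b.cortical_patch_center_mm, axis=-1)
            <= b.cortical_patch_radius_mm
        )
        if np.any(patch & thal):
            raise ValueError(
                f"bundle '{b.target_name}': cortical patch voxels overlap the thalamus"
            )
        targets[b.target_name] = VoxelGrid(patch.astype(np.uint8), affine)

    field = OrientationField.empty(shape, affine)
    for b in spec.bundles:
        _paint_bundle(field, b, spec, coords)
    field.validate_units()

    subject = SyntheticSubject(
        brain_mask=brain,
        thalamus_mask=thalamus,
        target_masks=targets,
        orientation_field=field,
        landmarks=LandmarkSet(**spec.landmark_positions_mm),
        truth_peaks_mm={
            b.target_name: b.thalamic_origin_mm.copy() for b in spec.bundles
        },
    )
    subject.validate()
    return subject


def _displace_origin(
    origin: np.ndarray,
    center: np.ndarray,
    radius: float,
    sd: float,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> tuple[np.ndarray, bool]:
    """Gaussian-displace a truth peak, resampling to stay inside the thalamus.

    Resampling (rather than projecting onto the boundary) preserves the
    Gaussian shape of the accepted offsets whenever the SD is small relative
    to the thalamus radius, which keeps closed-form distance predictions
    valid.  Returns (new origin, whether resampling saturated).
    """
    if sd == 0:
        return origin.copy(), False
    for _ in range(max_tries):
        candidate = origin + rng.normal(0.0, sd, size=3)
        if np.linalg.norm(candidate - center) < radius:
            return candidate, False
    # saturated: fall back to a boundary-projected point
    candidate = origin + rng.normal(0.0, sd, size=3)
    v = candidate - center
    candidate = center + v / np.linalg.norm(v) * (radius * 0.99)
    return candidate, True


def generate_cohort(
    base: PhantomSpec,
    n_subjects: int,
    peak_sd_mm: float,
    seed: int,
    landmark_jitter_deg: float = 0.0,
    landmark_jitter_mm: float = 0.0,
) -> list[SyntheticSubject]:
    """Generate a cohort whose truth peaks scatter around the base spec's.

    Each subject's bundle origins are the base origins plus an independent
    3D Gaussian offset with per-axis SD ``peak_sd_mm`` (resampled, up to 100
    tries, to stay inside the thalamus).  If landmark jitter is requested,
    the subject's entire world frame — landmarks, thalamus, bundles, truth
    peaks — is additionally moved by a random rigid transform about the grid
    center (rotation angle up to ``landmark_jitter_deg``, translation up to
    ``landmark_jitter_mm`` per axis), recorded on the subject so registration
    can be checked against ground truth.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if peak_sd_mm < 0:
        raise ValueError("peak_sd_mm must be >= 0")
    rng = np.random.default_rng(seed)
    extent_center = (np.asarray(base.grid_shape) - 1) * base.voxel_size_mm / 2.0

    subjects: list[SyntheticSubject] = []
    n_saturated = 0
    for i in range(n_subjects):
        bundles = []
        for b in base.bundles:
            new_origin, saturated = _displace_origin(
                b.thalamic_origin_mm,
                base.thalamus_center_mm,
                base.thalamus_radius_mm,
                peak_sd_mm,
                rng,
            )
            n_saturated += saturated
            bundles.append(dataclasses.replace(b, thalamic_origin_mm=new_origin))

        T: RigidTransform | None = None
        if landmark_jitter_deg > 0 or landmark_jitter_mm > 0:
            T = random_rigid(
                rng,
                max_angle_deg=landmark_jitter_deg,
                max_translation_mm=landmark_jitter_mm,
                about=extent_center,
            )

        spec_i = dataclasses.replace(
            base,
            bundles=bundles,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if T is not None:
            spec_i = dataclasses.replace(
                spec_i,
                thalamus_center_mm=T.apply(spec_i.thalamus_center_mm),
                bundles=[
                    dataclasses.replace(
                        b,
                        thalamic_origin_mm=T.apply(b.thalamic_origin_mm),
                        cortical_patch_center_mm=T.apply(b.cortical_patch_center_mm),
                    )
                    for b in spec_i.bundles
                ],
                landmark_positions_mm={
                    k: T.apply(v) for k, v in spec_i.landmark_positions_mm.items()
                },
            )
        subj = generate_subject(spec_i)
        subj.world_transform = T
        subjects.append(subj)

    if n_saturated:
        log.warning(
            "peak displacement saturated resampling for %d bundle(s); "
            "peak_sd_mm=%.2f is large relative to the thalamus radius",
            n_saturated,
            peak_sd_mm,
        )
    return subjects


# --- on-disk layout -----------------------------------------------------------


def write_subject(subject: SyntheticSubject, out_dir, index: int) -> list[Path]:
    """Write one subject as NIfTI volumes plus a JSON truth/landmark file."""
    from .io import write_volume  # local import: io depends on core only

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = f"sub-{index:02d}"
    written = []

    roles = {
        "brain": subject.brain_mask,
        "thalamus": subject.thalamus_mask,
    }
    for name, m in subject.target_masks.items():
        roles[f"target-{name}"] = m
    for role, grid in roles.items():
        p = out_dir / f"{prefix}_{role}.nii.gz"
        write_volume(grid, p)
        written.append(p)

    # 4D orientation volume: two 3-component directions stacked -> 6 components
    f = subject.orientation_field
    stacked = f.directions.reshape(*f.shape, 6)
    import nibabel as nib

    for name, arr in (
        ("orient", stacked),
        ("ndirs", f.n_directions.astype(np.uint8)),
        ("dispersion", f.dispersion_deg),
    ):
        p = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), f.affine), p)
        written.append(p)

    truth = {
        "landmarks": subject.landmarks.as_dict(),
        "truth_peaks_mm": {k: v.tolist() for k, v in subject.truth_peaks_mm.items()},
        "world_transform": (
            subject.world_transform.to_matrix().tolist()
            if subject.world_transform is not None
            else None
        ),
    }
    p = out_dir / f"{prefix}_truth.json"
    p.write_text(json.dumps(truth, indent=2))
    written.append(p)
    return written


def read_subject(in_dir, index: int) -> SyntheticSubject:
    """Read back a subject written by :func:`write_subject`."""
    import nibabel as nib

    from .io import read_volume

    in_dir = Path(in_dir)
    prefix = f"sub-{index:02d}"

    def _img(name):
        return nib.load(in_dir / f"{prefix}_{name}.nii.gz")

    brain = read_volume(in_dir / f"{prefix}_brain.nii.gz")
    thalamus = read_volume(in_dir / f"{prefix}_thalamus.nii.gz")
    targets = {}
    for p in sorted(in_dir.glob(f"{prefix}_target-*.nii.gz")):
        name = p.name[len(prefix) + 8 : -len(".nii.gz")]
        targets[name] = read_volume(p)

    orient = _img("orient")
    stacked = np.asarray(orient.dataobj, dtype=float)
    field = OrientationField(
        directions=stacked.reshape(*stacked.shape[:3], 2, 3),
        n_directions=np.asarray(_img("ndirs").dataobj).astype(np.uint8),
        dispersion_deg=np.asarray(_img("dispersion").dataobj, dtype=float),
        affine=orient.affine,
    )

    truth = json.loads((in_dir / f"{prefix}_truth.json").read_text())
    T = truth.get("world_transform")
    subject = SyntheticSubject(
        brain_mask=brain,
        thalamus_mask=thalamus,
        target_masks=targets,
        orientation_field=field,
        landmarks=LandmarkSet.from_dict(truth["landmarks"]),
        truth_peaks_mm={
            k: np.asarray(v, dtype=float)
            for k, v in truth["truth_peaks_mm"].items()
        },
        world_transform=(
            RigidTransform.from_matrix(np.asarray(T)) if T is not None else None
        ),
    )
    subject.validate()
    return subject
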