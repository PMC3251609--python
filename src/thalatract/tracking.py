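"""Probabilistic multi-fiber streamline tractography with target counters.

The sampler repeatedly propagates streamlines from seed voxels through a
per-voxel orientation field.  At each step one of the voxel's stored fiber
directions is chosen uniformly, perturbed by a Gaussian angular deviation
whose SD is the voxel's dispersion, sign-aligned with the previous step, and
followed for a fixed step length.  Streamlines stop on leaving the brain
mask, entering a direction-free (isotropic) voxel, exceeding the per-step
curvature limit, or reaching the step budget.  Each seed voxel is sampled
``n_samples_per_voxel`` times (the study protocol uses 5000); per-target
visitation counters divided by the sample count estimate the probability
that a seed voxel is connected to that target.

Streamlines are bidirectional: every sample is propagated both along the
initially chosen orientation and along its negation, as is standard for
seed-based probabilistic tracking, so a seed in the middle of a bundle
reaches both of its ends.

Orientation lookup is nearest-voxel (no interpolation — averaging antipodal
fiber vectors is ill-defined); the default step of half a voxel keeps the
discretization error bounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import OrientationField, VoxelGrid, require_binary

log = logging.getLogger("thalatract.tracking")

_CHUNK = 200_000  # streamlines propagated per vectorized batch


class OutOfMaskError(ValueError):
    """Raised when a streamline is seeded outside the brain mask."""


@dataclass
class TrackingConfig:
    """Propagation parameters.

    step_mm defaults to half the (smallest) voxel size when left as None.
    max_steps is a per-direction budget (each half of a bidirectional
    streamline gets the full budget).
    """

    n_samples_per_voxel: int = 5000
    step_mm: float | None = None
    max_steps: int = 2000
    curvature_limit_deg: float = 80.0
    rng_seed: int = 0

    def resolve_step(self, voxel_size: np.ndarray) -> float:
        step = self.step_mm if self.step_mm is not None else 0.5 * float(
            np.min(voxel_size)
        )
        if step <= 0:
            raise ValueError("step_mm must be positive")
        if step > float(np.min(voxel_size)) + 1e-12:
            raise ValueError("step_mm must not exceed the voxel size")
        if self.n_samples_per_voxel < 1:
            raise ValueError("n_samples_per_voxel must be >= 1")
        if not (0 < self.curvature_limit_deg <= 180):
            raise ValueError("curvature_limit_deg must lie in (0, 180]")
        return step


@dataclass
class ConnectivityResult:
    """Per-target visitation counts over the seed mask."""

    counts: dict[str, VoxelGrid]
    n_samples: int
    seed_mask: VoxelGrid

    def __post_init__(self) -> None:
        seed = self.seed_mask.data.astype(bool)
        for name, grid in self.counts.items():
            c = grid.data
            if np.any(c < 0) or np.any(c > self.n_samples):
                raise ValueError(f"counts for '{name}' outside [0, n_samples]")
            if np.any(c[~seed] != 0):
                raise ValueError(f"counts for '{name}' nonzero outside the seed mask")

    @property
    def target_names(self) -> list[str]:
        return list(self.counts)

    def probability(self, target: str) -> VoxelGrid:
        """Connection-probability map: counts / n_samples."""
        g = self.counts[target]
        return g.like(g.data.astype(float) / self.n_samples)


# --- vectorized propagation engine -------------------------------------------


def _tangent_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the plane perpendicular to each unit vector."""
    helper = np.zeros_like(d)
    helper[np.arange(len(d)), np.argmin(np.abs(d), axis=1)] = 1.0
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    return e1, e2


def _run_phase(
    pos0: np.ndarray,
    prev0: np.ndarray | None,
    active0: np.ndarray,
    field: OrientationField,
    brain: np.ndarray,
    inv_affine: np.ndarray,
    step: float,
    max_steps: int,
    cos_limit: float,
    rng: np.random.Generator,
    target_bits: np.ndarray | None,
    n_targets: int,
    hits: np.ndarray | None,
    visit_pairs: list | None,
    first_dir_out: np.ndarray | None,
) -> None:
    """Propagate one half of a batch of streamlines (mutates hits/visits)."""
    M = len(pos0)
    pos = pos0.copy()
    prev = np.zeros((M, 3)) if prev0 is None else prev0.copy()
    has_prev = (
        np.zeros(M, dtype=bool)
        if prev0 is None
        else ~np.isnan(prev0[:, 0])
    )
    prev = np.nan_to_num(prev)
    active = active0.copy()
    shape = np.asarray(field.shape)
    nvox_flat = int(np.prod(shape))

    for it in range(max_steps):
        ia = np.flatnonzero(active)
        if ia.size == 0:
            break
        # nearest voxel under the current position
        homo = pos[ia] @ inv_affine[:3, :3].T + inv_affine[:3, 3]
        idx = np.rint(homo).astype(np.int64)
        inb = np.all((idx >= 0) & (idx < shape), axis=1)
        if np.any(inb):
            ii = idx[inb]
            inb2 = inb.copy()
            inb2[inb] = brain[ii[:, 0], ii[:, 1], ii[:, 2]]
            inb = inb2
        active[ia[~inb]] = False
        ia = ia[inb]
        if ia.size == 0:
            continue
        idx = idx[inb]
        flat = idx[:, 0] * shape[1] * shape[2] + idx[:, 1] * shape[2] + idx[:, 2]

        if visit_pairs is not None:
            visit_pairs.append((ia.copy(), flat.copy()))
        if hits is not None and target_bits is not None:
            bits = target_bits.reshape(-1)[flat]
            for k in range(n_targets):
                hit_k = (bits >> k) & 1 == 1
                if np.any(hit_k):
                    hits[ia[hit_k], k] = True

        nd = field.n_directions[idx[:, 0], idx[:, 1], idx[:, 2]]
        stop = nd == 0
        active[ia[stop]] = False
        ia = ia[~stop]
        if ia.size == 0:
            continue
        idx = idx[~stop]
        nd = nd[~stop]

        # choose one stored orientation uniformly
        u = rng.random(ia.size)
        j = np.minimum((u * nd).astype(np.int64), nd - 1)
        d = field.directions[idx[:, 0], idx[:, 1], idx[:, 2], j, :].copy()

        # orientations are sign-ambiguous: align with the incoming direction
        hp = has_prev[ia]
        dots = np.einsum("ij,ij->i", d, prev[ia])
        d[hp & (dots < 0)] *= -1.0

        # Gaussian angular perturbation on the tangent plane
        sigma = np.deg2rad(field.dispersion_deg[idx[:, 0], idx[:, 1], idx[:, 2]])
        g = rng.standard_normal((ia.size, 2)) * sigma[:, None]
        theta = np.hypot(g[:, 0], g[:, 1])
        perturbed = theta > 0
        if np.any(perturbed):
            e1, e2 = _tangent_basis(d[perturbed])
            th = theta[perturbed][:, None]
            gp = g[perturbed]
            trans = (gp[:, :1] * e1 + gp[:, 1:] * e2) / th
            d[perturbed] = np.cos(th) * d[perturbed] + np.sin(th) * trans
            d[perturbed] /= np.linalg.norm(d[perturbed], axis=1, keepdims=True)

        # curvature stopping rule (per step, against the previous direction)
        curv = np.einsum("ij,ij->i", d, prev[ia])
        too_sharp = hp & (curv < cos_limit)
        active[ia[too_sharp]] = False
        ia = ia[~too_sharp]
        if ia.size == 0:
            continue
        d = d[~too_sharp]

        if first_dir_out is not None and it == 0:
            first_dir_out[ia] = d

        pos[ia] += step * d
        prev[ia] = d
        has_prev[ia] = True


def _propagate_batch(
    starts: np.ndarray,
    field: OrientationField,
    brain: np.ndarray,
    config: TrackingConfig,
    rng: np.random.Generator,
    target_bits: np.ndarray | None = None,
    n_targets: int = 0,
    record_visits: bool = False,
):
    """Bidirectionally propagate a batch; return (hits, visit pairs)."""
    grid = VoxelGrid(field.n_directions, field.affine)
    step = config.resolve_step(grid.voxel_size)
    inv_affine = np.linalg.inv(field.affine)
    cos_limit = float(np.cos(np.deg2rad(config.curvature_limit_deg)))
    M = len(starts)

    hits = np.zeros((M, n_targets), dtype=bool) if n_targets else None
    visit_pairs: list | None = [] if record_visits else None
    first_dir = np.full((M, 3), np.nan)

    active0 = np.ones(M, dtype=bool)
    _run_phase(
        starts, None, active0, field, brain, inv_affine, step, config.max_steps,
        cos_limit, rng, target_bits, n_targets, hits, visit_pairs, first_dir,
    )
    # backward half: restart from the seed against the initial direction
    started = ~np.isnan(first_dir[:, 0])
    _run_phase(
        starts, -first_dir, started, field, brain, inv_affine, step,
        config.max_steps, cos_limit, rng, target_bits, n_targets, hits,
        visit_pairs, None,
    )
    return hits, visit_pairs


# --- public API ---------------------------------------------------------------


def propagate_streamline(
    start_mm,
    field: OrientationField,
    brain_mask: VoxelGrid,
    config: TrackingConfig,
    rng_state,
) -> np.ndarray:
    """Propagate a single bidirectional streamline; returns its polyline (mm).

    ``rng_state`` is an integer seed or a ``numpy.random.Generator``.  The
    polyline runs from the backward terminus through the seed to the forward
    terminus; a seed in an isotropic voxel yields a single-point path.
    """
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    brain = require_binary(brain_mask, "brain_mask")
    start = np.asarray(start_mm, dtype=float).reshape(3)
    grid = VoxelGrid(field.n_directions, field.affine)
    idx0 = grid.world_to_index(start)
    if not grid.contains_index(idx0)[0] or not brain[tuple(idx0)]:
        raise OutOfMaskError(f"streamline seed {start} lies outside the brain mask")

    step = config.resolve_step(grid.voxel_size)
    cos_limit = float(np.cos(np.deg2rad(config.curvature_limit_deg)))

    def walk(prev_init: np.ndarray | None) -> tuple[list[np.ndarray], np.ndarray | None]:
        pos = start.copy()
        prev = prev_init
        pts: list[np.ndarray] = []
        d0 = None
        for it in range(config.max_steps):
            idx = grid.world_to_index(pos)
            if not grid.contains_index(idx)[0] or not brain[tuple(idx)]:
                break
            i, jx, k = idx
            nd = int(field.n_directions[i, jx, k])
            if nd == 0:
                break
            j = min(int(rng.random() * nd), nd - 1)
            d = field.directions[i, jx, k, j].copy()
            if prev is not None and d @ prev < 0:
                d = -d
            sigma = float(np.deg2rad(field.dispersion_deg[i, jx, k]))
            g = rng.standard_normal(2) * sigma
            theta = float(np.hypot(g[0], g[1]))
            if theta > 0:
                e1, e2 = _tangent_basis(d[None, :])
                trans = (g[0] * e1[0] + g[1] * e2[0]) / theta
                d = np.cos(theta) * d + np.sin(theta) * trans
                d /= np.linalg.norm(d)
            if prev is not None and d @ prev < cos_limit:
                break
            if it == 0:
                d0 = d.copy()
            pos = pos + step * d
            prev = d
            pts.append(pos.copy())
        return pts, d0

    forward, d0 = walk(None)
    backward: list[np.ndarray] = []
    if d0 is not None:
        backward, _ = walk(-d0)
    poly = backward[::-1] + [start] + forward
    return np.asarray(poly)


def _validate_tracking_inputs(seed_mask, field, brain_mask):
    grid = VoxelGrid(field.n_directions, field.affine)
    if not seed_mask.same_geometry(brain_mask) or seed_mask.shape != grid.shape:
        raise ValueError("seed, brain and orientation grids must share geometry")
    seed = require_binary(seed_mask, "seed_mask")
    brain = require_binary(brain_mask, "brain_mask")
    if not np.any(seed):
        raise ValueError("seed mask is empty")
    if np.any(seed & ~brain):
        raise ValueError("seed mask extends outside the brain mask")
    return seed, brain


def track_from_mask(
    seed_mask: VoxelGrid,
    targets: dict[str, VoxelGrid],
    field: OrientationField,
    brain_mask: VoxelGrid,
    config: TrackingConfig,
) -> ConnectivityResult:
    """Seed every voxel of the mask n_samples_per_voxel times and count hits.

    A streamline increments a target's counter (at its own seed voxel) at
    most once, on first entry into the target mask, so counts divided by the
    sample count are connection-probability estimates.
    """
    seed, brain = _validate_tracking_inputs(seed_mask, field, brain_mask)
    if not targets:
        raise ValueError("at least one target mask is required")
    names = list(targets)
    if len(names) > 62:
        raise ValueError("too many targets (bitmask limit)")
    target_bits = np.zeros(seed_mask.shape, dtype=np.int64)
    for k, name in enumerate(names):
        t = require_binary(targets[name], f"target '{name}'")
        if np.any(t & seed):
            raise ValueError(f"target '{name}' overlaps the seed mask")
        target_bits[t] |= 1 << k

    rng = np.random.default_rng(config.rng_seed)
    seed_idx = np.argwhere(seed)
    starts_all = VoxelGrid(seed, seed_mask.affine).voxel_to_world(seed_idx)
    n = config.n_samples_per_voxel

    counts = {name: np.zeros(seed_mask.shape, dtype=np.int64) for name in names}
    voxels_per_chunk = max(1, _CHUNK // n)
    for lo in range(0, len(seed_idx), voxels_per_chunk):
        hi = min(lo + voxels_per_chunk, len(seed_idx))
        starts = np.repeat(starts_all[lo:hi], n, axis=0)
        owner = np.repeat(np.arange(lo, hi), n)
        hits, _ = _propagate_batch(
            starts, field, brain, config, rng,
            target_bits=target_bits, n_targets=len(names),
        )
        for k, name in enumerate(names):
            hit_owner = owner[hits[:, k]]
            np.add.at(
                counts[name],
                (
                    seed_idx[hit_owner, 0],
                    seed_idx[hit_owner, 1],
                    seed_idx[hit_owner, 2],
                ),
                1,
            )

    log.info(
        "tracked %d seed voxels x %d samples toward %d target(s)",
        len(seed_idx), n, len(names),
    )
    return ConnectivityResult(
        counts={n_: VoxelGrid(c, seed_mask.affine) for n_, c in counts.items()},
        n_samples=n,
        seed_mask=seed_mask,
    )


def track_from_lesion(
    lesion_mask: VoxelGrid,
    field: OrientationField,
    brain_mask: VoxelGrid,
    config: TrackingConfig,
) -> VoxelGrid:
    """Whole-brain visitation map of streamlines seeded in a lesion.

    Each voxel's value is the number of streamlines (particles) that entered
    it at least once; thresholding at a particle count (e.g. 10% of the
    total sample count) gives the display maps used to read out a lesion's
    connectivity.
    """
    lesion, brain = _validate_tracking_inputs(lesion_mask, field, brain_mask)

    rng = np.random.default_rng(config.rng_seed)
    lesion_idx = np.argwhere(lesion)
    starts_all = VoxelGrid(lesion, lesion_mask.affine).voxel_to_world(lesion_idx)
    n = config.n_samples_per_voxel
    nvox = int(np.prod(lesion_mask.shape))

    visit_counts = np.zeros(nvox, dtype=np.int64)
    voxels_per_chunk = max(1, _CHUNK // n)
    for lo in range(0, len(lesion_idx), voxels_per_chunk):
        hi = min(lo + voxels_per_chunk, len(lesion_idx))
        starts = np.repeat(starts_all[lo:hi], n, axis=0)
        _, pairs = _propagate_batch(
            starts, field, brain, config, rng, record_visits=True,
        )
        assert pairs is not None
        if pairs:
            sid = np.concatenate([p[0] for p in pairs])
            vox = np.concatenate([p[1] for p in pairs])
            keys = np.unique(sid.astype(np.int64) * nvox + vox)
            visit_counts += np.bincount(keys % nvox, minlength=nvox)

    return VoxelGrid(visit_counts.reshape(lesion_mask.shape), lesion_mask.affine)
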