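"""Independent reference implementations used to cross-check the package.

These are deliberately written without reusing the package's propagation
engine: a plain per-voxel path follower for noise-free fields, so that the
vectorized stochastic tracker can be compared against it voxel-for-voxel.
"""

import numpy as np


def deterministic_connectivity(
    seed_mask,
    targets,
    field,
    brain_mask,
    step_mm: float,
    max_steps: int = 2000,
    curvature_limit_deg: float = 80.0,
):
    """Exhaustive deterministic path following for dispersion-free fields.

    Valid only when every voxel stores at most one direction and zero
    dispersion, so each seed voxel's bidirectional path is unique.  Returns
    {target: boolean indicator array over seed voxels}.
    """
    assert np.all(field.n_directions <= 1), "oracle requires single-fiber fields"
    assert np.all(field.dispersion_deg == 0), "oracle requires zero dispersion"
    inv = np.linalg.inv(field.affine)
    shape = np.asarray(field.shape)
    brain = brain_mask.data.astype(bool)
    cos_limit = np.cos(np.deg2rad(curvature_limit_deg))
    target_arrays = {name: g.data.astype(bool) for name, g in targets.items()}

    def walk(start, prev):
        """Follow the field from `start`; yields hit target names; returns d0."""
        pos = np.asarray(start, dtype=float).copy()
        hits = set()
        d0 = None
        for _ in range(max_steps):
            idx = np.rint(pos @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            if np.any(idx < 0) or np.any(idx >= shape) or not brain[tuple(idx)]:
                break
            for name, arr in target_arrays.items():
                if arr[tuple(idx)]:
                    hits.add(name)
            if field.n_directions[tuple(idx)] == 0:
                break
            d = field.directions[tuple(idx)][0].copy()
            if prev is not None and d @ prev < 0:
                d = -d
            if prev is not None and d @ prev < cos_limit:
                break
            if d0 is None:
                d0 = d.copy()
            pos = pos + step_mm * d
            prev = d
        return hits, d0

    seed_idx = np.argwhere(seed_mask.data.astype(bool))
    starts = (
        np.c_[seed_idx, np.ones(len(seed_idx))] @ np.asarray(field.affine).T
    )[:, :3]
    indicators = {
        name: np.zeros(seed_mask.shape, dtype=bool) for name in target_arrays
    }
    for ijk, start in zip(seed_idx, starts):
        hits, d0 = walk(start, None)
        if d0 is not None:
            back_hits, _ = walk(start, -d0)
            hits |= back_hits
        for name in hits:
            indicators[name][tuple(ijk)] = True
    return indicators
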