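import numpy as np
import pytest

import thalatract as tt

SHAPE = (40, 12, 12)


def make_straight_field(dispersion_deg: float = 0.0, half_width: int = 2):
    """An x-aligned straight tube through a (40,12,12) 1 mm grid."""
    field = tt.OrientationField.empty(SHAPE, np.eye(4))
    lo, hi = 6 - half_width, 7 + half_width
    field.directions[:, lo:hi, lo:hi, 0, :] = [1.0, 0.0, 0.0]
    field.n_directions[:, lo:hi, lo:hi] = 1
    field.dispersion_deg[:, lo:hi, lo:hi] = dispersion_deg
    return field


@pytest.fixture
def straight():
    """Straight-bundle test bench: field, brain, an on-axis seed, an end target."""
    brain = tt.VoxelGrid(np.ones(SHAPE, np.uint8), np.eye(4))
    seed = tt.VoxelGrid(np.zeros(SHAPE, np.uint8), np.eye(4))
    seed.data[2:5, 5:8, 5:8] = 1
    target = tt.VoxelGrid(np.zeros(SHAPE, np.uint8), np.eye(4))
    target.data[35:38, 4:9, 4:9] = 1
    return {
        "brain": brain,
        "seed": seed,
        "target": target,
        "field": make_straight_field(),
        "make_field": make_straight_field,
    }


@pytest.fixture(scope="session")
def default_subject():
    """The stock two-bundle phantom subject (zero dispersion)."""
    return tt.generate_subject(tt.default_spec(seed=0))


@pytest.fixture(scope="session")
def default_connectivity(default_subject):
    """Deterministic connectivity of the stock subject (10 samples/voxel)."""
    cfg = tt.TrackingConfig(n_samples_per_voxel=10, rng_seed=1)
    return tt.track_from_mask(
        default_subject.thalamus_mask,
        default_subject.target_masks,
        default_subject.orientation_field,
        default_subject.brain_mask,
        cfg,
    )
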