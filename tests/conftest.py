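"""Shared fixtures: small phantoms and cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hncnet.phantom import PhantomSpec, SyntheticCohortConfig, generate_phantom_volume

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from hncnet.preprocess import CTVolume, GTVMask


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A compact phantom that keeps per-test rendering under ~50 ms."""
    return PhantomSpec(
        volume_shape=(12, 64, 64),
        spacing=(3.0, 1.0, 1.0),
        tumor_center=(6, 32, 32),
        tumor_radii=(8.0, 10.0, 10.0),
        texture_heterogeneity=30.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom_volume(small_spec)


@pytest.fixture()
def volume_mask_pair():
    """Deterministic hand-built (volume, mask) pair, 4 slices of 16x16."""
    rng = np.random.default_rng(7)
    vox = rng.uniform(-100, 200, size=(4, 16, 16)).astype(np.float32)
    mask = np.zeros((4, 16, 16), dtype=np.uint8)
    mask[1, 5:9, 6:10] = 1
    mask[2, 4:10, 5:11] = 1
    spacing = (3.0, 1.0, 1.0)
    return CTVolume(vox, spacing), GTVMask(mask, spacing)


@pytest.fixture(scope="session")
def medium_cohort():
    """400 patients, labels only (no volumes): null-signal configuration."""
    from hncnet.phantom import generate_synthetic_cohort

    cfg = SyntheticCohortConfig(n_patients=400, effect_size=0.0, seed=5)
    _, records = generate_synthetic_cohort(cfg, with_volumes=False)
    return records
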