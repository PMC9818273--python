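"""Shared fixtures: random mask factories and a session-scoped synthetic
two-cohort study reused by the heavier pipeline-level tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from lnspatial.structures import StructureVolume


def random_blob_mask(rng: np.random.Generator, shape, n_seeds: int = 3, iters: int = 4) -> np.ndarray:
    """A random connected-ish binary blob: seeded dilation with erosion noise.
    Always non-empty."""
    m = np.zeros(shape, bool)
    idx = rng.integers(0, np.asarray(shape)[None, :], size=(n_seeds, 3))
    for i in idx:
        m[tuple(i)] = True
    for _ in range(iters):
        m = ndimage.binary_dilation(m, ndimage.generate_binary_structure(3, 1))
        m &= rng.random(shape) < 0.9
    m[tuple(idx[0])] = True
    return m


def random_structure_pair(seed: int, shape=(16, 16, 16)) -> tuple[StructureVolume, StructureVolume]:
    """A random (tumor, organ) pair on a shared anisotropic grid."""
    rng = np.random.default_rng(seed)
    spacing = tuple(rng.uniform(0.8, 2.5, 3))
    gtv = StructureVolume("GTVn", random_blob_mask(rng, shape), spacing)
    oar = StructureVolume("OAR", random_blob_mask(rng, shape), spacing)
    return gtv, oar


@pytest.fixture(scope="session")
def study():
    """One full synthetic two-cohort study (200 + 200 patients, 48^3
    phantoms) with prognosis results; shared by end-to-end tests."""
    import time

    from lnspatial.io import PipelineConfig
    from lnspatial.pipeline import run_prognosis, simulate_study

    cfg = PipelineConfig(seed=0)
    t0 = time.perf_counter()
    s = simulate_study(n_discovery=200, n_validation=200, seed=0, config=cfg)
    results = run_prognosis(
        s["factors_discovery"],
        s["clinical_discovery"],
        cfg,
        s["factors_validation"],
        s["clinical_validation"],
    )
    s["results"] = results
    s["elapsed_seconds"] = time.perf_counter() - t0
    return s
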