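import numpy as np
import pytest

from adta.io import ImagePatchSet, PatchRecord, TumorAnnotation
from adta.simulate import SimConfig, gen_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square_annotation():
    ring = [(0.0, 0.0), (200.0, 0.0), (200.0, 200.0), (0.0, 200.0), (0.0, 0.0)]
    return TumorAnnotation(image_id="sq", polygons=[(ring, [])])


@pytest.fixture
def grid_patch_set():
    """3x3 grid of 100-px patches covering a 300x300 image."""
    patches = [
        PatchRecord(x, y, 0.9 if (x + y) % 200 == 0 else 0.2)
        for y in (0, 100, 200)
        for x in (0, 100, 200)
    ]
    return ImagePatchSet(image_id="grid", patch_size=100, patches=patches)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 30-patient synthetic cohort shared across tests."""
    return gen_cohort(SimConfig(seed=42, n_patients=30))


def random_star(rng, width, height, n_vertices=None, rmin=0.2, rmax=0.48):
    """Random star-shaped polygon (open ring) for oracle comparisons.

    Angles are jittered around regular spacing so every angular gap stays
    below pi, which guarantees the ring is simple for any radii.
    """
    if n_vertices is None:
        n_vertices = int(rng.integers(4, 18))
    cx = width * rng.uniform(0.35, 0.65)
    cy = height * rng.uniform(0.35, 0.65)
    angles = (np.arange(n_vertices)
              + rng.uniform(0.05, 0.95, n_vertices)) * 2 * np.pi / n_vertices
    radii = rng.uniform(rmin, rmax, n_vertices) * min(width, height)
    return [
        (float(cx + r * np.cos(a)), float(cy + r * np.sin(a)))
        for a, r in zip(angles, radii)
    ]
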