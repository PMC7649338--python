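import numpy as np
import pytest

from sunseg.imaging import InstanceLabelMap
from sunseg.network import BackboneConfig, SUNets
from sunseg.synthetic import SceneSpec, generate_batch


@pytest.fixture(scope="session")
def tiny_model() -> SUNets:
    """Smallest legal stage-1 model (random weights) for shape/contract tests."""
    return SUNets(BackboneConfig(in_channels=3, base_width=4, depth=2), seed=0)


@pytest.fixture(scope="session")
def small_scene_spec() -> SceneSpec:
    """A 32x32 scene spec small enough for fast training tests."""
    return SceneSpec(
        canvas=(32, 32), n_nuclei=3, radius_range=(3.0, 5.0), overlap_fraction=0.5, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_scene_spec):
    return generate_batch(small_scene_spec, 20)


def random_instance_map(rng: np.random.Generator, shape=(32, 32), max_objects=5) -> InstanceLabelMap:
    """Random instance map of 0..max_objects disks (possibly overlapping)."""
    k = int(rng.integers(0, max_objects + 1))
    objects = []
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for i in range(k):
        cy, cx = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        r = int(rng.integers(2, 7))
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if mask.any():
            objects.append((i + 1, mask))
    return InstanceLabelMap(shape=shape, objects=objects)
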