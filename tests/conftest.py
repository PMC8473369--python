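import numpy as np
import pytest

from pcsrefine.structure import ModuleSegmentation
from pcsrefine.synthetic import (
    RepeatSpec,
    build_repeat_protein,
    default_tags,
    generate_virtual_pcs,
)


@pytest.fixture(scope="session")
def small_spec() -> RepeatSpec:
    """Two internal modules plus caps: the cheap unit-test solenoid."""
    return RepeatSpec(n_internal_modules=2)


@pytest.fixture(scope="session")
def small_structure(small_spec):
    return build_repeat_protein(small_spec)


@pytest.fixture(scope="session")
def small_segmentation(small_spec) -> ModuleSegmentation:
    return small_spec.segmentation()


@pytest.fixture(scope="session")
def small_tags(small_structure, small_segmentation):
    return default_tags(small_structure, small_segmentation)


@pytest.fixture(scope="session")
def small_pcs(small_structure, small_tags):
    """Noiseless, fully assigned virtual PCS data plus the true tensors."""
    return generate_virtual_pcs(
        small_structure, small_tags, noise_sd=0.0, assignment_fraction=1.0, seed=11
    )


@pytest.fixture(scope="session")
def bench_spec() -> RepeatSpec:
    """The benchmark solenoid: four internal modules plus caps (252 residues)."""
    return RepeatSpec(n_internal_modules=4)


@pytest.fixture(scope="session")
def bench_structure(bench_spec):
    return build_repeat_protein(bench_spec)


@pytest.fixture(scope="session")
def bench_segmentation(bench_spec):
    return bench_spec.segmentation()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
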