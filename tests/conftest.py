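import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, max_examples=50)
settings.load_profile("derandomized")

from crowdprior.dataset import DemographicProfile, ResponseTable
from crowdprior.synthetic import PopulationSpec, generate


@pytest.fixture
def tiny_table() -> ResponseTable:
    """2 volunteers x 2 images, codes [[1,2],[3,0]], truth (1,2)."""
    return ResponseTable(
        volunteer_ids=["v1", "v2"],
        image_ids=["i1", "i2"],
        outcomes=np.array([[1, 2], [3, 0]]),
        truth=np.array([1, 2]),
    )


def two_class_population(seed: int = 0, n_volunteers: int = 40, n_images: int = 30) -> PopulationSpec:
    """A sharp class and a noisy class with genuinely different reliability."""
    sharp = np.array([[0.05, 0.75, 0.1, 0.1], [0.05, 0.1, 0.75, 0.1]])
    noisy = np.array([[0.25, 0.3, 0.25, 0.2], [0.25, 0.25, 0.3, 0.2]])
    return PopulationSpec(
        class_labels=[1, 2],
        class_proportions=[0.5, 0.5],
        class_grids={1: sharp, 2: noisy},
        n_volunteers=n_volunteers,
        n_images=n_images,
        threat_prevalence=0.5,
        seed=seed,
    )


@pytest.fixture
def small_synthetic():
    """(table, profiles, class_of) from a seeded two-class population."""
    return generate(two_class_population(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
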