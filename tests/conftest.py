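import numpy as np
import pytest

from moawave.preprocess import DEFAULT_GRID, TCRC, TCRCSet
from moawave.synthetic import (
    GeneratorConfig,
    MOAArchetype,
    default_preset,
    generate_dataset,
    generate_tcrc_set,
    growth_curve,
)


def noiseless(config: GeneratorConfig) -> GeneratorConfig:
    from dataclasses import replace

    return replace(config, noise_mult_sigma=0.0, noise_add_sigma=0.0, jitter_sigma=0.0)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID.copy()


@pytest.fixture()
def clean_set(grid):
    """One noise-free chemical with a mid-potency kill archetype."""
    arch = MOAArchetype("C1", k_max=0.1, ec50=10.0, hill=2.0, lag=4.0)
    config = noiseless(GeneratorConfig(archetypes=(arch,), counts=(1,)))
    return generate_tcrc_set(arch, config, seed=0, jitter=False)


@pytest.fixture()
def flat_set(grid):
    """A set whose treated curves all equal the negative control exactly."""
    g = growth_curve(grid)
    conc = 100.0 / 3.0 ** np.arange(11)
    curves = [
        TCRC(times=grid, nci=g.copy(), concentration=float(c), chemical_id="flat")
        for c in conc
    ]
    nc = TCRC(times=grid, nci=g.copy(), concentration=None, chemical_id="flat")
    return TCRCSet(chemical_id="flat", curves=curves, negative_control=nc, label="C0")


@pytest.fixture(scope="session")
def default_dataset():
    """The full 63-chemical default synthetic dataset (seeded)."""
    return generate_dataset(default_preset(), seed=42)


@pytest.fixture(scope="session")
def two_cluster_dataset(default_dataset):
    """The two largest clusters of the default dataset (20 + 13 chemicals)."""
    return [s for s in default_dataset if s.label in ("C1", "C10")]


class OracleModel:
    """Stub classifier that memorizes nothing and answers the truth."""

    def __init__(self, truth_of):
        self._truth_of = truth_of

    def predict(self, features):
        return np.array([self._truth_of(tuple(row)) for row in np.atleast_2d(features)])


def oracle_factory(all_features, all_labels):
    """Factory whose models look the true label up by feature row."""
    truth = {tuple(row): label for row, label in zip(np.atleast_2d(all_features), all_labels)}
    def factory(train_X, train_y, seed):
        return OracleModel(truth.__getitem__)
    return factory


class MajorityModel:
    def __init__(self, label):
        self.label = label

    def predict(self, features):
        return np.full(np.atleast_2d(features).shape[0], self.label, dtype=object)


def majority_factory(train_X, train_y, seed):
    values, counts = np.unique(train_y, return_counts=True)
    return MajorityModel(values[np.argmax(counts)])
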