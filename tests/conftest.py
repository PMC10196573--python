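import numpy as np
import pytest

from foragemod.geometry import ArenaGeometry
from foragemod.synthetic import (ArchetypeSpec, SimConfig, _flat,
                                 default_archetypes, generate_cohort)
from foragemod.tracking import KinematicsConfig


@pytest.fixture(scope="session")
def geometry() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast miniature cohort: 8 mice, 8-minute trials, three archetypes."""
    n_min = 8
    arch = [a for a in default_archetypes()
            if a.name in ("dart_pot4", "check_pot2", "center_explore")]
    rates = {a.name: {"WT": _flat(3.0, n_min), "KO": _flat(3.0, n_min)}
             for a in arch}
    cfg = SimConfig(n_per_group=2, trial_min=n_min, archetypes=arch,
                    archetype_rates=rates, noise_rate=0.1)
    return cfg


@pytest.fixture(scope="session")
def small_cohort(small_config, geometry):
    return generate_cohort(small_config, geometry, seed=7)


@pytest.fixture(scope="session")
def processed_small(small_cohort, geometry):
    from foragemod.pipeline import process_cohort

    trajs, manifest, truth = small_cohort
    excursions, matrix, processed = process_cohort(
        trajs, geometry, KinematicsConfig(), analysis_window_min=None)
    return excursions, matrix, processed, manifest, truth


@pytest.fixture(scope="session")
def blob_data():
    """Six well-separated Gaussian blobs plus diffuse noise, 57-dim-free."""
    rng = np.random.default_rng(0)
    cents = rng.normal(0, 6, (6, 8))
    X, labels = [], []
    for k in range(6):
        X.append(rng.normal(cents[k], 1.0, (120, 8)))
        labels += [k + 1] * 120
    X.append(rng.uniform(-12, 12, (100, 8)))
    labels += [0] * 100
    return np.vstack(X), np.array(labels)
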