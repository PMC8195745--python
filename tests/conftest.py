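import numpy as np
import pandas as pd
import pytest

from rhizonet.containers import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_table(counts, conditions=None, experiments=None):
    """Small CountTable with auto-generated ids and metadata."""
    counts = np.asarray(counts)
    n_otus, n_samples = counts.shape
    otus = [f"OTU_{i:03d}" for i in range(n_otus)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "experiment": experiments or ["exp1"] * n_samples,
            "condition": conditions or ["bare_soil"] * n_samples,
        },
        index=samples,
    )
    return CountTable(counts, otus, samples, meta)


@pytest.fixture
def small_table(rng):
    return make_table(rng.integers(0, 50, size=(12, 8)))


@pytest.fixture(scope="session")
def tiny_study():
    """A fast five-condition, two-experiment study with planted structure."""
    import rhizonet as rz

    design = rz.default_design(
        seed=7, n_otus=40, n_samples_per_condition=12,
        n_backbone=6, n_sc=3, n_ic_specific=3, n_common_ic=3,
    )
    tables, truth = rz.simulate_study(design)
    return design, tables, truth
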