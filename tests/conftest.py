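import numpy as np
import pytest

import gxglink as gx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    return gx.ExperimentDesign(
        n_isolates_host=4,
        n_isolates_parasite=4,
        trials_per_cell=5,
        replicates=3,
        sampling_interval=10,
        error_rate=0.05,
    )


def make_table(
    model="MA",
    K=2,
    f=(0.6, 0.4),
    g=(0.5, 0.5),
    design=None,
    seed=0,
    matrix_params=None,
):
    """Simulate one cross-infection table from explicit genotype frequencies."""
    design = design or gx.ExperimentDesign(
        n_isolates_host=3, n_isolates_parasite=3, replicates=2, error_rate=0.05
    )
    rng = np.random.default_rng(seed)
    alpha = gx.build_infection_matrix(model, K, **(matrix_params or {}))
    hosts = gx.sample_isolates(np.asarray(f, float), design.n_isolates_host, rng)
    paras = gx.sample_isolates(np.asarray(g, float), design.n_isolates_parasite, rng)
    return gx.run_cross_infection(hosts, paras, alpha, design, rng)
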