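import numpy as np
import pytest

from seqlift import ExpressionMatrix, simulate_perturbation_study, simulate_world


@pytest.fixture(scope="session")
def tiny_world():
    """Small cross-platform world shared by fast unit tests."""
    return simulate_world(n_genes=60, n_landmark=12, n_factors=4,
                          n_train_per_domain=80, n_paired=40,
                          noise_sd=0.05, distortion_strength=1.0, seed=13)


@pytest.fixture(scope="session")
def tiny_study(tiny_world):
    return simulate_perturbation_study(tiny_world, n_batches=4,
                                       treat_per_batch=4, control_per_batch=4,
                                       target_set_size=8, effect_size=2.0,
                                       seed=29)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(5)
    return ExpressionMatrix(values=rng.uniform(0, 10, size=(6, 4)),
                            gene_ids=[f"g{i}" for i in range(6)],
                            sample_ids=[f"s{j}" for j in range(4)],
                            space="full", scale="log2")
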