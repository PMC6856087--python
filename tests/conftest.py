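import numpy as np
import pytest

from mtgp.genotypes import GRM, MarkerMatrix, cholesky_factor, compute_grm, impute_missing, qc_markers
from mtgp.simulate import SimulationConfig, make_incomplete_design, simulate_markers, simulate_phenotypes


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_lines=20, n_markers=300, n_envs=4, lines_per_env_range=(10, 16), seed=11
    )


@pytest.fixture(scope="session")
def small_grm(small_config):
    markers = simulate_markers(small_config)
    return compute_grm(impute_missing(qc_markers(markers)))


@pytest.fixture(scope="session")
def small_pheno(small_config, small_grm):
    design = make_incomplete_design(small_config)
    pheno, effects = simulate_phenotypes(design, small_grm, small_config)
    return pheno, effects


def random_psd(J: int, rng) -> np.ndarray:
    """Random well-conditioned PSD matrix scaled like a kinship matrix."""
    A = rng.standard_normal((J, J + 3))
    G = A @ A.T / (J + 3)
    return (G + G.T) / 2


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
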