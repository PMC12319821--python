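import numpy as np
import pytest

from neurodist.synthetic import generate_beta_set, generate_design


@pytest.fixture(scope="session")
def design60():
    """The full study layout: 2 superordinate x 3 basic x 10 exemplars."""
    return generate_design(2, 3, 10)


@pytest.fixture(scope="session")
def design_small():
    """Reduced layout for fast decoding tests: 2 x 3 x 4 = 24 scenes."""
    return generate_design(2, 3, 4)


@pytest.fixture()
def separable_betas(design_small):
    """Noiseless, strongly separable beta set (both category levels)."""
    betas, truth = generate_beta_set(
        design_small, n_runs=8, n_voxels=30, super_effect=4.0, basic_effect=2.0,
        exemplar_sd=0.05, run_noise_sd=0.0, exemplar_axis_sd=0.2, seed=11,
    )
    return betas, truth


@pytest.fixture()
def null_betas(design_small):
    """No category signal anywhere: decoding must sit at chance."""
    betas, truth = generate_beta_set(
        design_small, n_runs=8, n_voxels=30, super_effect=0.0, basic_effect=0.0,
        exemplar_sd=0.0, run_noise_sd=1.0, seed=7,
    )
    return betas, truth
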