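import numpy as np
import pytest

from qenspol.spectra_core import ResolutionModel, SqwMap
from qenspol.synthetic_data import default_omega_grid, default_q_grid


@pytest.fixture(scope="session")
def omega():
    return default_omega_grid()


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid()


@pytest.fixture(scope="session")
def resolution():
    return ResolutionModel(kind="gaussian", fwhm=0.06577)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-conditions pipeline run shared across test modules."""
    from qenspol.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline_run")
    return run_pipeline(seed=0, out_dir=out)


def random_map(rng, n_q=3, n_omega=5):
    """Small random SqwMap for arithmetic/I-O tests."""
    q = np.linspace(0.5, 0.5 + 0.1 * (n_q - 1), n_q)
    om = np.linspace(-1.0, 1.0, n_omega)
    return SqwMap(
        q_centers=q,
        omega=om,
        intensity=rng.normal(size=(n_q, n_omega)),
        sigma=rng.uniform(0.1, 1.0, size=(n_q, n_omega)),
        dq=0.1,
        label="random",
    )


@pytest.fixture
def small_map(rng):
    return random_map(rng)
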