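import numpy as np
import pytest

from iccmix.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset from the three-component n=600, p=2000 benchmark design."""
    return generate_dataset(SimulationConfig(), seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    """Lower-dimensional variant (p=200) of the benchmark design."""
    return generate_dataset(SimulationConfig.scaled(p=200), seed=42)


@pytest.fixture(scope="session")
def small_trace(small_dataset):
    """A short ICC run on the p=200 design, shared across consensus and
    model-selection tests."""
    from iccmix.icc import run_icc

    return run_icc(small_dataset.X, small_dataset.y, K=3, T=150, t0=50, seed=7)


def orthonormal_design(n: int, d: int, seed: int) -> np.ndarray:
    """Columns with exact zero mean and X'X/n = I, so that internal
    standardization is the identity and coordinate updates decouple."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, d))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    # QR of column-centered A keeps columns mean-zero (span is preserved)
    return Q * np.sqrt(n)
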