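import numpy as np
import pytest

from multimarker import CaseControlData, chr10_block8, chr10_block7


@pytest.fixture(scope="session")
def block1():
    return chr10_block8()


@pytest.fixture(scope="session")
def block2():
    return chr10_block7()


def random_corr(k: int, rng: np.random.Generator) -> np.ndarray:
    """Random well-conditioned correlation matrix."""
    a = rng.normal(size=(k, k + 3))
    s = a @ a.T + 0.5 * k * np.eye(k)
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return 0.5 * (r + r.T)


def dataset_with_freqs(n: int, pi1: float, pi0: float) -> CaseControlData:
    """Balanced single-marker data set realizing exact case/control frequencies."""
    half = n // 2
    g_case = np.zeros(half, dtype=int)
    g_case[: int(round(pi1 * half))] = 1
    g_ctrl = np.zeros(half, dtype=int)
    g_ctrl[: int(round(pi0 * half))] = 1
    return CaseControlData(
        phenotype=np.r_[np.ones(half, int), np.zeros(half, int)],
        genotypes=np.r_[g_case, g_ctrl][:, None],
    )
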