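import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from hmmbeam import HMMPosterior, SensorDataset, StateSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_generating_hmm(var_ratio: float = 9.0, stay: float = 0.99, N: int = 2):
    """Two-state generating parameters with well-separated covariances."""
    trans = np.array([[stay, 1 - stay], [1 - stay, stay]])
    covs = np.array([np.eye(N), var_ratio * np.eye(N)])
    return HMMPosterior(
        means=np.zeros((2, N)),
        covariances=covs,
        transition=trans,
        initial=np.full(2, 0.5),
    )


def align_labels(pred: np.ndarray, true: np.ndarray, K: int) -> np.ndarray:
    """Relabel ``pred`` by Hungarian matching on the confusion matrix."""
    conf = np.zeros((K, K))
    for p, t in zip(pred, true):
        conf[p - 1, t - 1] += 1
    row, col = linear_sum_assignment(-conf)
    mapping = {r + 1: c + 1 for r, c in zip(row, col)}
    return np.array([mapping[p] for p in pred])


@pytest.fixture
def small_dataset(rng):
    return SensorDataset(rng.standard_normal((4, 500)), fs=100.0)


def random_spd(rng, n: int) -> np.ndarray:
    A = rng.standard_normal((n, n))
    return A @ A.T + n * np.eye(n)
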