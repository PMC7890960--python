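import numpy as np
import pytest

from roikit.core import Spacing


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def unit_spacing():
    return Spacing(1.0, 1.0, 1.0)


@pytest.fixture
def confocal_spacing():
    # reference confocal geometry: 70 nm in xy, 210 nm in z
    return Spacing(210.0, 70.0, 70.0)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0


def best_match_jaccard(labels: np.ndarray, truth: np.ndarray, truth_label: int) -> float:
    """Jaccard of a truth region vs its best-overlapping computed label."""
    tr = truth == truth_label
    best = 0.0
    for l in range(1, labels.max() + 1):
        best = max(best, jaccard(labels == l, tr))
    return best
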