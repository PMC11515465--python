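import numpy as np
import pytest

from balmet import ConfusionMatrix

# Reader-average confusion matrices of the published breast-cancer MRMC study
# (new AI-assisted technology vs current standard of care; N = 663, 10 readers).
NEW_TECH = (45, 72, 4, 542)
CURRENT_STD = (44, 117, 5, 497)


@pytest.fixture
def cm_new():
    return ConfusionMatrix(*NEW_TECH)


@pytest.fixture
def cm_std():
    return ConfusionMatrix(*CURRENT_STD)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_matrices(rng, size, max_cell=200, positive_marginals=True):
    """Random integer confusion matrices; optionally reject zero marginals."""
    out = []
    while len(out) < size:
        tp, fp, fn, tn = rng.integers(0, max_cell + 1, 4)
        if positive_marginals and (
            tp + fn == 0 or tn + fp == 0 or tp + fp == 0 or tn + fn == 0
        ):
            continue
        out.append(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
    return out
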