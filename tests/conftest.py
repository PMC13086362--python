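import numpy as np
import pytest

from paleoherd import synth
from paleoherd.seqmodel import ToothSequence


@pytest.fixture
def clean_cosine_seq():
    """Noiseless seasonal cosine, coarse enough that both optima are clear."""
    truth = synth.ToothTruth(A=4.0, X=25.0, x0=10.0, M=-5.0, sigma=0.0)
    seq, _ = synth.gen_tooth_sequence(truth, step=1.5, crown_length=28.5, specimen_id="CLEAN")
    return seq, truth


@pytest.fixture
def noisy_cosine_seq():
    truth = synth.ToothTruth(A=3.0, X=25.0, x0=10.0, M=-5.0, sigma=0.3, seed=17)
    seq, _ = synth.gen_tooth_sequence(truth, step=1.0, crown_length=30.0, specimen_id="NOISY")
    return seq, truth


def grid_search_cosine(x, y, A_grid, X_grid, x0_grid, M_grid):
    """Brute-force SSE minimisation over a parameter grid (oracle)."""
    best = (np.inf, None)
    for A in A_grid:
        for X in X_grid:
            w = 2 * np.pi / X
            for x0 in x0_grid:
                c = np.cos(w * (x - x0))
                for M in M_grid:
                    sse = float(np.sum((A * c + M - y) ** 2))
                    if sse < best[0]:
                        best = (sse, (A, X, x0, M))
    return best
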