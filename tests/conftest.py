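import numpy as np
import pytest

from mudcrab.hmm import (
    EmissionParams,
    HMMData,
    HMMParams,
    TransitionModel,
    intercepts_for_matrix,
)
from mudcrab.simulate import TABLE_EMISSIONS, TABLE_TRANSITIONS, simulate_hmm_series


@pytest.fixture(scope="session")
def crab_emissions() -> EmissionParams:
    """Published two-state emission parameters (15-min interval)."""
    return TABLE_EMISSIONS


@pytest.fixture(scope="session")
def crab_matrix() -> np.ndarray:
    """Published homogeneous two-state transition matrix."""
    return TABLE_TRANSITIONS


@pytest.fixture(scope="session")
def crab_params(crab_emissions, crab_matrix) -> HMMParams:
    beta = intercepts_for_matrix(crab_matrix)
    return HMMParams(2, crab_emissions, TransitionModel(2, ("intercept",), beta))


@pytest.fixture(scope="session")
def small_series_df():
    """Six simulated tracks of 300 intervals under the published model."""
    return simulate_hmm_series(6, 300, seed=42)


@pytest.fixture(scope="session")
def small_data(small_series_df) -> HMMData:
    return HMMData.from_table(small_series_df)


def make_hmm_data(step, angle, accel=None, X=None, track_ids=None):
    """Assemble a batched HMMData directly from per-track arrays."""
    step = [np.asarray(s, dtype=float) for s in step]
    angle = [np.asarray(a, dtype=float) for a in angle]
    B = len(step)
    lengths = np.array([len(s) for s in step])
    T = int(lengths.max())
    S = np.full((B, T), np.nan)
    A = np.full((B, T), np.nan)
    C = np.full((B, T), np.nan) if accel is not None else None
    p = 1 if X is None else X[0].shape[1]
    D = np.zeros((B, T, p))
    D[:, :, 0] = 1.0
    for b in range(B):
        L = lengths[b]
        S[b, :L] = step[b]
        A[b, :L] = angle[b]
        if accel is not None:
            C[b, :L] = np.asarray(accel[b], dtype=float)
        if X is not None:
            D[b, :L] = X[b]
    ids = track_ids or [f"t{b}" for b in range(B)]
    cols = ("intercept",) + tuple(f"c{j}" for j in range(1, p))
    return HMMData(list(ids), [i.split("-")[0] for i in ids], lengths, S, A, C, D, cols)
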