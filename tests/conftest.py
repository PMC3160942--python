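import numpy as np
import pytest

from vaval import CauseList, ProbabilityMatrix, build_probability_matrix


@pytest.fixture
def small_matrix() -> ProbabilityMatrix:
    """Five causes, thirty indicators, fairly informative, fixed seed."""
    return build_probability_matrix(5, 30, informativeness=0.8, seed=1)


@pytest.fixture
def two_cause_matrix() -> ProbabilityMatrix:
    """Hand-built two-cause, one-indicator matrix for exact Bayes arithmetic."""
    return ProbabilityMatrix(
        causes=CauseList(("a", "b")),
        indicators=("fever",),
        priors=np.array([0.5, 0.5]),
        emit=np.array([[0.8, 0.1]]),
    )


def random_probability_matrix(rng: np.random.Generator, n_causes: int,
                              n_indicators: int) -> ProbabilityMatrix:
    """Fully random matrix (no signature structure) for oracle checks."""
    priors = rng.dirichlet(np.ones(n_causes))
    emit = rng.uniform(0.05, 0.95, size=(n_indicators, n_causes))
    return ProbabilityMatrix(
        causes=CauseList(tuple(f"c{i}" for i in range(n_causes))),
        indicators=tuple(f"i{i}" for i in range(n_indicators)),
        priors=priors,
        emit=emit,
    )
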