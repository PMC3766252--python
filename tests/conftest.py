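import numpy as np
import pytest

from linklcm import AgreementPatternTable, InteractionTerm, ModelSpec
from linklcm.synthetic import SimulationScenario


@pytest.fixture
def toy_table_k2() -> AgreementPatternTable:
    # pattern order (00, 01, 10, 11) -> counts f(00)=50, f(01)=10, f(10)=10, f(11)=30
    return AgreementPatternTable(2, np.array([50, 10, 10, 30]))


@pytest.fixture
def ci_scenario_k4() -> SimulationScenario:
    return SimulationScenario(
        K=4,
        pi=0.05,
        m=np.array([0.8, 0.7, 0.6, 0.9]),
        u=np.array([0.1, 0.05, 0.2, 0.3]),
        N=50_000,
        seed=11,
    )


@pytest.fixture
def dep_scenario_k4() -> SimulationScenario:
    return SimulationScenario(
        K=4,
        pi=0.05,
        m=np.array([0.8, 0.7, 0.6, 0.9]),
        u=np.array([0.1, 0.05, 0.2, 0.3]),
        N=100_000,
        seed=7,
        injected=((InteractionTerm(1, 3, "both_distinct"), 1.2, -0.9),),
    )


@pytest.fixture
def dep_scenario_k7() -> SimulationScenario:
    """Registry-like K=7 scenario with strong nonmatch-class dependence on pair (3, 4).

    At K=7 the misspecified CI fit cannot absorb the pairwise dependence, so
    the correlation residual shows up at the injected pair itself.
    """
    return SimulationScenario(
        K=7,
        pi=0.037,
        m=np.array([0.581, 0.025, 0.572, 0.173, 0.409, 0.710, 0.716]),
        u=np.array([0.026, 1e-4, 0.032, 5e-4, 0.037, 0.661, 0.082]),
        N=300_000,
        seed=7,
        injected=((InteractionTerm(3, 4, "both_distinct"), 4.0, 2.0),),
    )


def mchd_like_scenario(N: int = 500_000, seed: int = 0) -> SimulationScenario:
    """CI scenario with magnitudes similar to a blocked registry de-duplication."""
    return SimulationScenario(
        K=7,
        pi=0.037,
        m=np.array([0.581, 0.025, 0.572, 0.173, 0.409, 0.710, 0.716]),
        u=np.array([0.026, 1e-4, 0.032, 5e-4, 0.037, 0.661, 0.082]),
        N=N,
        seed=seed,
    )


def fs_mixture_probs(pi: float, m: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Independent brute-force oracle: classical F-S mixture over all patterns."""
    from linklcm.model import pattern_matrix

    K = len(m)
    Y = pattern_matrix(K)
    pm = np.prod(m**Y * (1 - m) ** (1 - Y), axis=1)
    pu = np.prod(u**Y * (1 - u) ** (1 - Y), axis=1)
    return pi * pm + (1 - pi) * pu
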