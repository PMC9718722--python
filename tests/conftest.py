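import numpy as np
import pytest

from htmarginal.models import LocalTransition, SANSpec, ThetaMatrix, mhn_to_san


def random_theta(rng: np.random.Generator, d: int, sigma: float = 0.3) -> ThetaMatrix:
    """Random fully-coupled MHN parameters (log-normal around 1)."""
    return ThetaMatrix(theta=np.exp(rng.normal(0.0, sigma, size=(d, d))))


def random_sanspec(rng: np.random.Generator, d: int, max_states: int = 3) -> SANSpec:
    """Random generalized SAN: mixed state counts, random local transitions."""
    sizes = [int(rng.integers(2, max_states + 1)) for _ in range(d)]
    transitions = []
    effects = []
    for i in range(d):
        n_i = sizes[i]
        n_trans = int(rng.integers(1, 3))
        pairs = set()
        for _ in range(n_trans):
            x = int(rng.integers(n_i))
            y = int(rng.integers(n_i))
            if x == y or (x, y) in pairs:
                continue
            pairs.add((x, y))
            transitions.append(LocalTransition(automaton=i, source=x, target=y))
            eff = []
            for j in range(d):
                if j == i:
                    vec = np.zeros(sizes[j])
                    vec[x] = rng.uniform(0.2, 2.0)
                else:
                    vec = rng.uniform(0.2, 2.0, size=sizes[j])
                eff.append(vec)
            effects.append(eff)
    if not transitions:  # guarantee at least one enabled transition
        transitions.append(LocalTransition(automaton=0, source=0, target=1))
        eff = []
        for j in range(d):
            if j == 0:
                vec = np.zeros(sizes[j])
                vec[0] = 1.0
            else:
                vec = rng.uniform(0.2, 2.0, size=sizes[j])
            eff.append(vec)
        effects.append(eff)
    return SANSpec(sizes=sizes, transitions=transitions, effects=effects)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def mhn3(rng):
    """Small random MHN (d=3) with its SAN spec."""
    theta = random_theta(rng, 3)
    return theta, mhn_to_san(theta)
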