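"""Markov-chain models with separable transition rates.

A stochastic automata network (SAN) couples ``d`` small Markov chains
("automata").  Transitions happen in one automaton at a time, and each
transition rate factorizes over the current local states of all automata,

    Q[y, x] = prod_j Theta(t_i, x_j),

where ``x`` and ``y`` differ only in automaton ``i`` via the local transition
``t_i = (x_i -> y_i)``.  The infinitesimal generator is then a short sum of
Kronecker products (one term per local transition), which is the CP-format
structure everything downstream exploits.

Mutual Hazard Networks (MHNs) are the special case used in tumor-progression
modeling: every automaton is binary (event absent/present), the only local
transition is irreversible activation ``0 -> 1``, and the effect of an
*inactive* event on any other event is neutral (equal to 1).  The full
parameterization is then a single nonnegative ``d x d`` matrix ``Theta`` whose
diagonal holds baseline activation rates and whose off-diagonal entry
``Theta[i, j]`` is the multiplicative effect of an active event ``j`` on the
activation rate of event ``i``.

Convention: generators are *column* generators, ``Q[y, x]`` is the rate of the
transition ``x -> y``, so every column sums to zero.  Global states are
``d``-tuples ``(x_1, ..., x_d)`` of 0-based local states, linearized in mixed
radix with ``x_1`` as the slowest-varying index (matching the Kronecker factor
order of the CP representation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThetaMatrix",
    "LocalTransition",
    "SANSpec",
    "CPOperator",
    "InitialState",
    "mhn_to_san",
    "build_generator_cp",
    "generator_dense",
    "gamma_bound",
    "uniformized_cp",
    "state_index",
    "enumerate_states",
]

DENSE_CAP_DEFAULT = 2**14


class ModelValidationError(ValueError):
    """Raised when model parameters violate their invariants."""


class DegenerateModelError(ValueError):
    """Raised when a model has no enabled transition (all rates zero)."""


class SizeCapError(ValueError):
    """Raised when a dense realization would exceed the configured cap."""


@dataclass(frozen=True)
class ThetaMatrix:
    """Parameter matrix of a Mutual Hazard Network.

    ``theta[i, j]`` (i != j) is the multiplicative effect of active event ``j``
    on the activation rate of event ``i``; ``theta[i, i]`` is the baseline
    activation rate of event ``i``.  All entries must be finite and >= 0.
    """

    theta: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.theta, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ModelValidationError(
                f"theta must be a square matrix, got shape {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise ModelValidationError("theta must have d >= 1")
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ModelValidationError(
                f"theta[{i}, {j}] = {arr[i, j]!r} is negative or non-finite"
            )
        object.__setattr__(self, "theta", arr)

    @property
    def d(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class LocalTransition:
    """A local transition ``source -> target`` inside one automaton."""

    automaton: int
    source: int
    target: int


@dataclass
class SANSpec:
    """Generalized stochastic automata network with separable rates.

    Parameters
    ----------
    sizes
        Local state-space size ``n_i >= 2`` per automaton.
    transitions
        All local transitions, each within a single automaton.
    effects
        For each transition ``t`` (in the order of ``transitions``) a list of
        ``d`` nonnegative vectors; entry ``effects[t][j][x_j]`` is the factor
        contributed by local state ``x_j`` of automaton ``j``.  For ``j`` equal
        to the transition's automaton only the source-state entry is used (the
        baseline rate).
    is_mhn
        True when the spec was derived from a :class:`ThetaMatrix`; selects
        the cheaper MHN form of the uniformization bound.
    """

    sizes: list[int]
    transitions: list[LocalTransition]
    effects: list[list[np.ndarray]]
    is_mhn: bool = False
    theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sizes = [int(n) for n in self.sizes]
        if any(n < 2 for n in self.sizes):
            raise ModelValidationError("every automaton needs n_i >= 2 states")
        d = self.d
        if len(self.effects) != len(self.transitions):
            raise ModelValidationError("one effect table required per transition")
        for t, eff in zip(self.transitions, self.effects):
            if not (0 <= t.automaton < d):
                raise ModelValidationError(f"transition references automaton {t.automaton}")
            n_i = self.sizes[t.automaton]
            if not (0 <= t.source < n_i and 0 <= t.target < n_i):
                raise ModelValidationError(
                    f"transition {t.source}->{t.target} outside S_{t.automaton}"
                )
            if t.source == t.target:
                raise ModelValidationError("local transitions must change the state")
            if len(eff) != d:
                raise ModelValidationError("effect table must cover all automata")
            for j, vec in enumerate(eff):
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (self.sizes[j],):
                    raise ModelValidationError(
                        f"effect vector for automaton {j} has wrong length"
                    )
                if (~np.isfinite(vec) | (vec < 0)).any():
                    raise ModelValidationError(
                        f"effect values for automaton {j} must be finite and >= 0"
                    )
                eff[j] = vec

    @property
    def d(self) -> int:
        return len(self.sizes)

    @property
    def n_states(self) -> int:
        return int(np.prod(self.sizes))


@dataclass
class CPOperator:
    """Operator in CP format: a sum of ``rank`` Kronecker products.

    ``terms[k][j]`` is the ``n_j x n_j`` factor of term ``k`` acting on mode
    ``j``; the represented operator is ``sum_k kron(terms[k][0], ...,
    terms[k][d-1])``.
    """

    sizes: list[int]
    terms: list[list[np.ndarray]]

    def __post_init__(self) -> None:
        self.sizes = [int(n) for n in self.sizes]
        d = self.d
        for term in self.terms:
            if len(term) != d:
                raise ModelValidationError("every CP term needs d factor matrices")
            for j, mat in enumerate(term):
                mat = np.asarray(mat, dtype=float)
                if mat.shape != (self.sizes[j], self.sizes[j]):
                    raise ModelValidationError(
                        f"factor {j} has shape {mat.shape}, expected "
                        f"({self.sizes[j]}, {self.sizes[j]})"
                    )
                term[j] = mat

    @property
    def d(self) -> int:
        return len(self.sizes)

    @property
    def rank(self) -> int:
        return len(self.terms)

    def dense(self, cap: int = DENSE_CAP_DEFAULT) -> np.ndarray:
        """Expand to a dense ``|S| x |S|`` matrix (small models only)."""
        n = int(np.prod(self.sizes))
        if n > cap:
            raise SizeCapError(f"dense expansion with {n} states exceeds cap {cap}")
        out = np.zeros((n, n))
        for term in self.terms:
            acc = np.ones((1, 1))
            for mat in term:
                acc = np.kron(acc, mat)
            out += acc
        return out


@dataclass(frozen=True)
class InitialState:
    """Deterministic initial global state ``z``; ``p(0)`` is the unit tensor e_z."""

    z: tuple[int, ...]

    @staticmethod
    def all_zero(d: int) -> "InitialState":
        return InitialState(tuple([0] * d))

    def validate(self, sizes: list[int]) -> None:
        if len(self.z) != len(sizes):
            raise ModelValidationError("initial state length must equal d")
        for i, (zi, ni) in enumerate(zip(self.z, sizes)):
            if not (0 <= zi < ni):
                raise ModelValidationError(f"z[{i}] = {zi} outside S_{i}")

    def dense(self, sizes: list[int]) -> np.ndarray:
        self.validate(sizes)
        p0 = np.zeros(int(np.prod(sizes)))
        p0[state_index(self.z, sizes)] = 1.0
        return p0


def state_index(x: tuple[int, ...], sizes: list[int]) -> int:
    """Mixed-radix linear index of a global state; ``x_1`` varies slowest."""
    idx = 0
    for xi, ni in zip(x, sizes):
        idx = idx * ni + xi
    return idx


def enumerate_states(sizes: list[int]):
    """All global states in linearization order."""
    d = len(sizes)
    x = [0] * d
    total = int(np.prod(sizes))
    for _ in range(total):
        yield tuple(x)
        for i in reversed(range(d)):
            x[i] += 1
            if x[i] < sizes[i]:
                break
            x[i] = 0


def mhn_to_san(theta: ThetaMatrix) -> SANSpec:
    """Express an MHN as a generalized SAN.

    Every event becomes a binary automaton with the single irreversible
    transition ``0 -> 1``.  Effect vectors encode neutrality of inactive
    events: ``Theta(t_i, x_j) = 1`` if ``x_j = 0`` (j != i), ``Theta[i, j]``
    if ``x_j = 1``, and the baseline ``Theta[i, i]`` for ``j = i``.
    """
    th = theta.theta
    d = theta.d
    transitions = []
    effects = []
    for i in range(d):
        transitions.append(LocalTransition(automaton=i, source=0, target=1))
        eff = []
        for j in range(d):
            if j == i:
                # baseline rate attached to the source state 0
                eff.append(np.array([th[i, i], 0.0]))
            else:
                eff.append(np.array([1.0, th[i, j]]))
        effects.append(eff)
    return SANSpec(
        sizes=[2] * d,
        transitions=transitions,
        effects=effects,
        is_mhn=True,
        theta=th.copy(),
    )


def build_generator_cp(spec: SANSpec) -> CPOperator:
    """CP representation of the generator: one Kronecker term per transition.

    For term ``t_i`` the factor on mode ``j != i`` is ``diag(Theta(t_i, .))``;
    the factor on mode ``i`` has the baseline at ``(y_i, x_i)`` and its
    negative at ``(x_i, x_i)`` so each term (and hence Q) has zero column sums.
    """
    terms = []
    for t, eff in zip(spec.transitions, spec.effects):
        term = []
        for j in range(spec.d):
            if j == t.automaton:
                base = eff[j][t.source]
                mat = np.zeros((spec.sizes[j], spec.sizes[j]))
                mat[t.target, t.source] = base
                mat[t.source, t.source] = -base
            else:
                mat = np.diag(eff[j])
            term.append(mat)
        terms.append(term)
    return CPOperator(sizes=list(spec.sizes), terms=terms)


def generator_dense(spec: SANSpec, cap: int = DENSE_CAP_DEFAULT) -> np.ndarray:
    """Entrywise dense generator over the full state space (oracle path).

    Built directly from the rate product, independently of the CP
    representation, so the two can be cross-checked.
    """
    n = spec.n_states
    if n > cap:
        raise SizeCapError(f"state space of size {n} exceeds cap {cap}")
    q = np.zeros((n, n))
    states = list(enumerate_states(spec.sizes))
    for t, eff in zip(spec.transitions, spec.effects):
        i = t.automaton
        for x in states:
            if x[i] != t.source:
                continue
            rate = 1.0
            for j in range(spec.d):
                rate *= eff[j][x[j]] if j != i else eff[i][t.source]
            y = list(x)
            y[i] = t.target
            xi = state_index(x, spec.sizes)
            yi = state_index(tuple(y), spec.sizes)
            q[yi, xi] += rate
            q[xi, xi] -= rate
    return q


def gamma_bound(spec: SANSpec) -> float:
    """Uniformization rate: cheap upper bound on max_x |Q[x, x]|.

    For an MHN this is ``sum_i prod_j max(1, Theta[i, j])``; for a general
    SAN, for each automaton the worst local source state is taken, and every
    other automaton contributes its worst-case effect.  Costs O(d^2 n^2 T),
    never enumerating the global state space.
    """
    if spec.is_mhn and spec.theta is not None:
        gamma = float(np.sum(np.prod(np.maximum(1.0, spec.theta), axis=1)))
    else:
        gamma = 0.0
        for i in range(spec.d):
            per_source = np.zeros(spec.sizes[i])
            for t, eff in zip(spec.transitions, spec.effects):
                if t.automaton != i:
                    continue
                prod = eff[i][t.source]
                for j in range(spec.d):
                    if j != i:
                        prod *= float(np.max(eff[j]))
                per_source[t.source] += prod
            gamma += float(np.max(per_source))
    if gamma <= 0.0:
        raise DegenerateModelError(
            "all transition rates are zero; no uniformization rate exists"
        )
    return gamma


def uniformized_cp(q: CPOperator, gamma: float) -> CPOperator:
    """Uniformized jump operator ``P = Id + Q / gamma`` in CP format.

    Appends a single identity term, so the rank grows by at most one.  For
    ``gamma >= max_x |Q[x, x]|`` the dense expansion is column-stochastic with
    nonnegative entries.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    terms = [[np.eye(n) for n in q.sizes]]
    for term in q.terms:
        scaled = [mat.copy() for mat in term]
        scaled[0] = scaled[0] / gamma
        terms.append(scaled)
    return CPOperator(sizes=list(q.sizes), terms=terms)
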