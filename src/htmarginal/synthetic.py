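"""Synthetic block-structured MHN parameter matrices.

The generator emulates networks of genomic events organized in pathways:
automata within a block affect one another directly, automata in different
blocks do not (B1), or do so only sparsely (B2: a few effects between
neighboring blocks; B3: additionally a few effects between arbitrary
blocks).  Within-block effects (diagonal included) have log values drawn from
Normal(0, 0.25); cross-block effects use Normal(0, 0.125) (natural
logarithms), so all sampled parameters are log-normal around the neutral
value 1.  Every other entry is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .models import ThetaMatrix

__all__ = [
    "BlockDesign",
    "sample_theta",
    "describe_blocks",
    "block_separating_order",
]


@dataclass(frozen=True)
class BlockDesign:
    """Design of a block-structured parameter matrix.

    ``kind`` selects the structure: "B1" strict blocks, "B2" plus
    ``neighbor_effects`` random effects per pair of neighboring blocks
    (blocks are neighbors when their indices differ by one), "B3"
    additionally ``random_effects`` effects between arbitrary distinct
    blocks.  ``seed`` makes sampling reproducible.
    """

    d: int
    n_blocks: int
    kind: str = "B1"
    sigma_within: float = 0.25
    sigma_between: float = 0.125
    neighbor_effects: int = 4
    random_effects: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("B1", "B2", "B3"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.d < 1 or self.n_blocks < 1 or self.d % self.n_blocks != 0:
            raise ValueError("n_blocks must divide d")
        if self.sigma_within <= 0 or self.sigma_between <= 0:
            raise ValueError("sigma values must be positive")
        if self.kind != "B1" and self.n_blocks < 2:
            raise ValueError("cross-block effects need at least two blocks")

    @property
    def block_size(self) -> int:
        return self.d // self.n_blocks

    def with_seed(self, seed: int) -> "BlockDesign":
        return replace(self, seed=int(seed))


def describe_blocks(design: BlockDesign) -> np.ndarray:
    """1-based block index of each automaton (blocks are contiguous)."""
    return np.repeat(np.arange(1, design.n_blocks + 1), design.block_size)


def block_separating_order(design: BlockDesign) -> tuple[int, ...]:
    """Leaf order that interleaves blocks (0-based automaton indices).

    Places members of every block in both subtrees of the root, the
    worst-case layout for the achievable ranks; e.g. d=8 with 2 blocks gives
    (0, 4, 1, 5, 2, 6, 3, 7) (automata 1,5,2,6,3,7,4,8 in 1-based labels).
    """
    b = design.block_size
    order = [
        k * b + m
        for m in range(b)
        for k in range(design.n_blocks)
    ]
    return tuple(order)


def _draw_cross_pair(
    rng: np.random.Generator,
    theta: np.ndarray,
    blocks: np.ndarray,
    allowed: set[tuple[int, int]],
) -> tuple[int, int]:
    """Uniform ordered cross-block pair with a still-neutral entry."""
    d = theta.shape[0]
    for _ in range(100_000):
        i = int(rng.integers(d))
        j = int(rng.integers(d))
        if i == j or blocks[i] == blocks[j]:
            continue
        key = (int(blocks[i]), int(blocks[j]))
        if key not in allowed and (key[1], key[0]) not in allowed:
            continue
        if theta[i, j] != 1.0:
            continue
        return i, j
    raise RuntimeError("no neutral cross-block pair left to draw")


def sample_theta(design: BlockDesign) -> ThetaMatrix:
    """Sample a block-structured parameter matrix, deterministic under seed."""
    rng = np.random.default_rng(design.seed)
    d = design.d
    theta = np.ones((d, d))
    blocks = describe_blocks(design)
    for k in range(1, design.n_blocks + 1):
        members = np.flatnonzero(blocks == k)
        logs = rng.normal(0.0, design.sigma_within, size=(len(members), len(members)))
        theta[np.ix_(members, members)] = np.exp(logs)
    if design.kind in ("B2", "B3"):
        for k in range(1, design.n_blocks):
            allowed = {(k, k + 1)}
            for _ in range(design.neighbor_effects):
                i, j = _draw_cross_pair(rng, theta, blocks, allowed)
                theta[i, j] = np.exp(rng.normal(0.0, design.sigma_between))
    if design.kind == "B3":
        allowed = {
            (a, b)
            for a in range(1, design.n_blocks + 1)
            for b in range(1, design.n_blocks + 1)
            if a != b
        }
        for _ in range(design.random_effects):
            i, j = _draw_cross_pair(rng, theta, blocks, allowed)
            theta[i, j] = np.exp(rng.normal(0.0, design.sigma_between))
    return ThetaMatrix(theta=theta)
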