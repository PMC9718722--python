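"""Diagnostics: effective rank, storage accounting, divergences, studies.

The experiment runners mirror the standard numerical studies for this kind
of solver: per-node singular-value spectra of the exact marginal (computed
densely at small d), mean effective approximation ranks of the low-rank
solution across designs and tolerances, and convergence curves with fitted
log-residual slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    InitialState,
    build_generator_cp,
    gamma_bound,
    generator_dense,
    mhn_to_san,
)
from .tree import DimensionTree, balanced_tree, matricize
from .httensor import HTTensor, ht_storage, ht_unit
from .solver import SolverConfig, dense_marginal, solve_marginal_lowrank
from .synthetic import BlockDesign, sample_theta

__all__ = [
    "RankReport",
    "effective_rank",
    "storage_counts",
    "dense_storage",
    "constant_rank_storage",
    "kl_divergence",
    "SpectrumStudy",
    "spectrum_study",
    "rank_study",
    "convergence_study",
]


class CutoffError(ValueError):
    """Raised when the KL cutoff leaves a nonpositive approximate probability."""


def constant_rank_storage(tree: DimensionTree, sizes: list[int], r: int) -> int:
    """Storage of an HT tensor with every node rank equal to ``r``.

    Leaves cost n_i * r, inner non-root nodes r^3, the root r^2 (root rank
    is 1 by convention).
    """
    total = 0
    for node in tree.nodes:
        if node.is_leaf:
            r_node = 1 if node.index == 0 else r
            total += sizes[node.modes[0]] * r_node
        elif node.index == 0:
            total += r * r
        else:
            total += r * r * r
    return total


def effective_rank(x: HTTensor) -> int:
    """Constant node rank with (at least) the same storage cost, rounded up.

    The smallest integer r such that a constant-rank-r representation on the
    same tree costs at least as much as the actual one; equals r when all
    node ranks are already r.
    """
    actual = ht_storage(x)
    r = 1
    while constant_rank_storage(x.tree, x.sizes, r) < actual:
        r += 1
    return r


def storage_counts(x: HTTensor) -> tuple[int, int]:
    """(HT storage, dense storage) for a tensor: sum of node arrays vs prod n_i."""
    return ht_storage(x), int(np.prod(x.sizes))


def dense_storage(d: int, n: int = 2) -> int:
    """Entries needed to store a full distribution vector (n^d)."""
    return int(n) ** int(d)


def kl_divergence(
    p_ref: np.ndarray,
    p_approx: np.ndarray,
    eps_cutoff: float = 1e-8,
) -> float:
    """KL(p_ref || p_approx) = sum_x p_ref[x] log(p_ref[x]/p_approx[x]).

    Natural logarithm.  Reference entries <= ``eps_cutoff`` are dropped
    (0 log 0 := 0), which also guards against the tiny negative entries that
    truncation can leave in the approximation; if a *surviving* index still
    has a nonpositive approximate probability a :class:`CutoffError` is
    raised (increase the cutoff).  No renormalization is applied, so slightly
    negative totals are possible and reported as-is.
    """
    p_ref = np.asarray(p_ref, dtype=float).ravel()
    p_approx = np.asarray(p_approx, dtype=float).ravel()
    mask = p_ref > eps_cutoff
    if np.any(p_approx[mask] <= 0.0):
        bad = int(np.flatnonzero(mask & (p_approx <= 0.0))[0])
        raise CutoffError(
            f"approximate probability at index {bad} is nonpositive; "
            f"eps_cutoff={eps_cutoff} is too small"
        )
    return float(np.sum(p_ref[mask] * np.log(p_ref[mask] / p_approx[mask])))


@dataclass
class SpectrumStudy:
    """Mean per-node singular-value curves of dense-solved marginals."""

    tree: DimensionTree
    mean_sigma: dict[int, np.ndarray]
    mean_zero_count: dict[int, float]
    zero_tol: float | None
    n_samples: int

    def node_modes(self, node_index: int) -> tuple[int, ...]:
        return self.tree.nodes[node_index].modes


def _dense_marginal_for_theta(theta) -> np.ndarray:
    spec = mhn_to_san(theta)
    q = generator_dense(spec)
    p0 = InitialState.all_zero(spec.d).dense(spec.sizes)
    return dense_marginal(q, p0)


def spectrum_study(
    design: BlockDesign,
    tree: DimensionTree | None = None,
    n_samples: int = 100,
    seed: int | None = None,
    zero_tol: float | None = None,
) -> SpectrumStudy:
    """Per-node singular values of the exact marginal, averaged over samples.

    For every sampled parameter matrix the marginal is solved densely, the
    tensor is matricized at every tree node, and the singular values are
    averaged arithmetically.  ``mean_zero_count`` reports, per node, the mean
    number of numerically vanishing singular values; by default "numerically
    zero" means below the standard numerical-rank threshold
    sigma_1 * max(rows, cols) * machine_eps (an explicit relative threshold
    can be passed instead).
    """
    if tree is None:
        tree = balanced_tree(design.d)
    base_seed = design.seed if seed is None else seed
    sizes = [2] * design.d
    sums: dict[int, np.ndarray] = {}
    zeros: dict[int, float] = {}
    for s in range(n_samples):
        theta = sample_theta(design.with_seed(base_seed + s))
        p = _dense_marginal_for_theta(theta).reshape(sizes)
        for node in tree.nodes:
            mat = matricize(p, node.modes)
            sv = np.linalg.svd(mat, compute_uv=False)
            if zero_tol is None:
                cut = sv[0] * max(mat.shape) * np.finfo(float).eps
            else:
                cut = zero_tol * sv[0]
            sums[node.index] = sums.get(node.index, 0.0) + sv
            zeros[node.index] = zeros.get(node.index, 0.0) + int(np.sum(sv < cut))
    mean_sigma = {k: v / n_samples for k, v in sums.items()}
    mean_zeros = {k: v / n_samples for k, v in zeros.items()}
    return SpectrumStudy(
        tree=tree,
        mean_sigma=mean_sigma,
        mean_zero_count=mean_zeros,
        zero_tol=zero_tol,
        n_samples=n_samples,
    )


def _solve_design(
    design: BlockDesign,
    tol: float,
    eps_trunc: float,
    tree: DimensionTree | None,
    residual_stride: int,
    max_iter: int,
):
    theta = sample_theta(design)
    spec = mhn_to_san(theta)
    if tree is None:
        tree = balanced_tree(spec.d)
    q = build_generator_cp(spec)
    gamma = gamma_bound(spec)
    p0 = ht_unit(tree, spec.sizes, tuple([0] * spec.d))
    cfg = SolverConfig(
        gamma=gamma,
        tol=tol,
        eps_trunc=eps_trunc,
        residual_stride=residual_stride,
        max_iter=max_iter,
    )
    return solve_marginal_lowrank(q, p0, cfg)


def rank_study(
    designs: list[BlockDesign],
    tolerances: list[float] = (1e-4,),
    eps_values: list[float] = (1e-7,),
    n_samples: int = 5,
    seed: int = 0,
    tree: DimensionTree | None = None,
    residual_stride: int = 10,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """Mean effective ranks of the low-rank solution across designs.

    One row per (design kind, d, n_blocks, tol, eps, sample) with the
    effective rank, iteration count and convergence flag.
    """
    rows = []
    for design in designs:
        for tol in tolerances:
            for eps in eps_values:
                for s in range(n_samples):
                    res = _solve_design(
                        design.with_seed(seed + design.seed + s),
                        tol,
                        eps,
                        tree,
                        residual_stride,
                        max_iter,
                    )
                    rows.append(
                        {
                            "kind": design.kind,
                            "d": design.d,
                            "n_blocks": design.n_blocks,
                            "tol": tol,
                            "eps_trunc": eps,
                            "sample": s,
                            "r_eff": effective_rank(res.p),
                            "iterations": res.iterations,
                            "residual": res.final_residual,
                            "converged": res.converged,
                        }
                    )
    return pd.DataFrame(rows)


def convergence_study(
    designs: list[BlockDesign],
    tol: float = 1e-4,
    eps_trunc: float = 1e-7,
    n_samples: int = 3,
    seed: int = 0,
    residual_stride: int = 5,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """Residual-vs-iteration curves with fitted log10 decay slopes.

    The slope is the least-squares fit of log10(residual) against the
    iteration index; linear convergence shows as a straight line with slope
    close to log10(gamma/(1+gamma)).
    """
    rows = []
    for design in designs:
        for s in range(n_samples):
            res = _solve_design(
                design.with_seed(seed + design.seed + s),
                tol,
                eps_trunc,
                None,
                residual_stride,
                max_iter,
            )
            ks = np.array([k for k, _ in res.residuals], dtype=float)
            rs = np.array([r for _, r in res.residuals], dtype=float)
            keep = rs > 0
            slope = (
                float(np.polyfit(ks[keep], np.log10(rs[keep]), 1)[0])
                if keep.sum() >= 2
                else math.nan
            )
            for k, r in res.residuals:
                rows.append(
                    {
                        "kind": design.kind,
                        "d": design.d,
                        "n_blocks": design.n_blocks,
                        "sample": s,
                        "iteration": k,
                        "residual": r,
                        "slope": slope,
                        "gamma": res.gamma,
                        "iterations": res.iterations,
                        "converged": res.converged,
                    }
                )
    return pd.DataFrame(rows)
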