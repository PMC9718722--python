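"""Hierarchical Tucker (HT) tensor engine.

An HT tensor stores, for a given dimension tree, one *leaf frame* per leaf
(an ``n_i x r_leaf`` matrix) and one *transfer tensor* per inner node (an
``r_left x r_right x r_node`` array, with rank 1 at the root).  The column
space of the matricization B^(t) is spanned nodewise, so storage and all
arithmetic are linear in the dimension d and polynomial in the node ranks,
never touching the full n^d state space.

Supported operations: CP -> HT conversion, dense reconstruction and single
entry evaluation, addition, scaling, inner product, application of a CP
operator (with optional truncation between accumulated terms),
orthogonalization, per-node singular values, and SVD-based truncation with a
computable discarded-singular-value error bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.linalg import get_lapack_funcs

from .tree import DimensionTree, balanced_tree, matricize
from .models import CPOperator

__all__ = [
    "CPTensor",
    "TruncationControl",
    "HTTensor",
    "cp_to_ht",
    "ht_unit",
    "ht_ones",
    "ht_to_dense",
    "ht_entry",
    "ht_add",
    "ht_scale",
    "ht_inner",
    "ht_norm",
    "orthogonalize",
    "gramians",
    "node_singular_values",
    "ht_truncate",
    "apply_cp_operator",
    "ht_storage",
    "random_ht",
]

DENSE_CAP_DEFAULT = 2**14


@dataclass
class CPTensor:
    """Tensor as a sum of ``r`` elementary (Kronecker) products of vectors."""

    sizes: list[int]
    terms: list[list[np.ndarray]]

    def __post_init__(self) -> None:
        self.sizes = [int(n) for n in self.sizes]
        for term in self.terms:
            if len(term) != len(self.sizes):
                raise ValueError("each CP term needs one vector per mode")
            for j, vec in enumerate(term):
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (self.sizes[j],):
                    raise ValueError(f"vector {j} has wrong length")
                term[j] = vec

    @property
    def d(self) -> int:
        return len(self.sizes)

    @property
    def rank(self) -> int:
        return len(self.terms)

    def dense(self, cap: int = DENSE_CAP_DEFAULT) -> np.ndarray:
        n = int(np.prod(self.sizes))
        if n > cap:
            raise ValueError(f"dense expansion with {n} entries exceeds cap {cap}")
        out = np.zeros(self.sizes)
        for term in self.terms:
            acc = np.ones(1)
            for vec in term:
                acc = np.kron(acc, vec)
            out += acc.reshape(self.sizes)
        return out


@dataclass(frozen=True)
class TruncationControl:
    """Truncation policy: relative tolerance per call and optional rank cap.

    ``eps`` bounds the relative error of one truncation,
    ``|x - trunc(x)| <= eps * |x|``; the discarded-singular-value budget is
    split uniformly over the non-root nodes.  ``max_rank`` caps every node
    rank regardless of the error budget.
    """

    eps: float = 1e-7
    max_rank: int | None = None

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.max_rank is not None and self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")


@dataclass
class HTTensor:
    """Hierarchical Tucker tensor on a fixed dimension tree.

    ``frames`` maps leaf node index -> (n_i, r) matrix; ``transfer`` maps
    inner node index -> (r_left, r_right, r_node) array.  Arrays are treated
    as immutable: operations return new ``HTTensor`` objects that may share
    unchanged arrays.
    """

    tree: DimensionTree
    sizes: list[int]
    frames: dict[int, np.ndarray]
    transfer: dict[int, np.ndarray]

    def rank(self, node_index: int) -> int:
        node = self.tree.nodes[node_index]
        if node.is_leaf:
            return self.frames[node_index].shape[1]
        return self.transfer[node_index].shape[2]

    @property
    def ranks(self) -> dict[int, int]:
        return {n.index: self.rank(n.index) for n in self.tree.nodes}

    def validate(self) -> None:
        if self.rank(0) != 1:
            raise ValueError("root rank must be 1")
        for node in self.tree.nodes:
            if node.is_leaf:
                n_i = self.sizes[node.modes[0]]
                if self.frames[node.index].shape[0] != n_i:
                    raise ValueError(f"leaf frame {node.index} has wrong mode size")
            else:
                b = self.transfer[node.index]
                if b.shape[0] != self.rank(node.left) or b.shape[1] != self.rank(node.right):
                    raise ValueError(f"transfer tensor {node.index} inconsistent with children")

    def copy(self) -> "HTTensor":
        return HTTensor(
            tree=self.tree,
            sizes=list(self.sizes),
            frames={k: v for k, v in self.frames.items()},
            transfer={k: v for k, v in self.transfer.items()},
        )


def _check_compatible(x: HTTensor, y: HTTensor) -> None:
    if x.sizes != y.sizes:
        raise ValueError("mode sizes differ")
    if [n.modes for n in x.tree.nodes] != [n.modes for n in y.tree.nodes]:
        raise ValueError("dimension trees differ")


def cp_to_ht(x: CPTensor, tree: DimensionTree | None = None) -> HTTensor:
    """Convert a CP tensor of rank r to HT; every node rank is <= r.

    Leaf frames stack the CP vectors as columns; transfer tensors are
    superdiagonal, so the reconstruction reproduces the CP sum exactly.
    """
    if tree is None:
        tree = balanced_tree(x.d)
    if tree.d != x.d:
        raise ValueError("tree dimension does not match tensor")
    r = max(x.rank, 1)
    frames: dict[int, np.ndarray] = {}
    transfer: dict[int, np.ndarray] = {}
    if x.d == 1:
        # the root is the single leaf and must have rank 1: sum the terms
        vec = np.zeros((x.sizes[0], 1))
        for t in x.terms:
            vec[:, 0] += t[0]
        return HTTensor(tree=tree, sizes=list(x.sizes), frames={0: vec}, transfer={})
    for node in tree.nodes:
        if node.is_leaf:
            mode = node.modes[0]
            if x.rank == 0:
                frames[node.index] = np.zeros((x.sizes[mode], 1))
            else:
                frames[node.index] = np.column_stack([t[mode] for t in x.terms])
        else:
            if node.index == 0:
                b = np.zeros((r, r, 1))
                b[np.arange(r), np.arange(r), 0] = 1.0
            else:
                b = np.zeros((r, r, r))
                b[np.arange(r), np.arange(r), np.arange(r)] = 1.0
            transfer[node.index] = b
    return HTTensor(tree=tree, sizes=list(x.sizes), frames=frames, transfer=transfer)


def ht_unit(tree: DimensionTree, sizes: list[int], z: tuple[int, ...]) -> HTTensor:
    """Rank-1 unit tensor e_z (the canonical initial distribution)."""
    term = []
    for i, n in enumerate(sizes):
        e = np.zeros(n)
        e[z[i]] = 1.0
        term.append(e)
    return cp_to_ht(CPTensor(sizes=list(sizes), terms=[term]), tree)


def ht_ones(tree: DimensionTree, sizes: list[int]) -> HTTensor:
    """Rank-1 all-ones tensor (used for mass evaluation)."""
    return cp_to_ht(
        CPTensor(sizes=list(sizes), terms=[[np.ones(n) for n in sizes]]), tree
    )


def _node_matrices(x: HTTensor) -> dict[int, np.ndarray]:
    """Per-node reconstruction matrices V_t (rows: subtree states, tree order)."""
    v: dict[int, np.ndarray] = {}
    for node in x.tree.postorder():
        if node.is_leaf:
            v[node.index] = x.frames[node.index]
        else:
            v1 = v[node.left]
            v2 = v[node.right]
            b = x.transfer[node.index]
            # V[(x1, x2), c] with the left child index varying slowest
            tmp = np.tensordot(v1, b, axes=(1, 0))  # (N1, r2, rc)
            out = np.tensordot(tmp, v2, axes=(1, 1))  # (N1, rc, N2)
            v[node.index] = out.transpose(0, 2, 1).reshape(
                v1.shape[0] * v2.shape[0], b.shape[2]
            )
            del v[node.left], v[node.right]
    return v


def ht_to_dense(x: HTTensor, cap: int = DENSE_CAP_DEFAULT) -> np.ndarray:
    """Full dense tensor with axes in natural mode order (small d only)."""
    total = int(np.prod(x.sizes))
    if total > cap:
        raise ValueError(f"dense reconstruction with {total} entries exceeds cap {cap}")
    v = _node_matrices(x)[0][:, 0]
    order = x.tree.leaf_order
    shaped = v.reshape([x.sizes[i] for i in order])
    inverse = np.argsort(order)
    return np.transpose(shaped, inverse)


def ht_entry(x: HTTensor, state: tuple[int, ...]) -> float:
    """Single entry x[state] in O(d r^3) without materializing the tensor."""
    vec: dict[int, np.ndarray] = {}
    for node in x.tree.postorder():
        if node.is_leaf:
            vec[node.index] = x.frames[node.index][state[node.modes[0]], :]
        else:
            b = x.transfer[node.index]
            tmp = np.tensordot(vec[node.left], b, axes=(0, 0))
            vec[node.index] = np.tensordot(vec[node.right], tmp, axes=(0, 0))
    return float(vec[0][0])


def ht_add(x: HTTensor, y: HTTensor) -> HTTensor:
    """Exact sum; node ranks add (block-diagonal transfer tensors)."""
    _check_compatible(x, y)
    if x.tree.n_nodes == 1:
        return HTTensor(
            tree=x.tree,
            sizes=list(x.sizes),
            frames={0: x.frames[0] + y.frames[0]},
            transfer={},
        )
    frames: dict[int, np.ndarray] = {}
    transfer: dict[int, np.ndarray] = {}
    for node in x.tree.nodes:
        if node.is_leaf:
            frames[node.index] = np.hstack(
                [x.frames[node.index], y.frames[node.index]]
            )
        else:
            bx = x.transfer[node.index]
            by = y.transfer[node.index]
            rc = 1 if node.index == 0 else bx.shape[2] + by.shape[2]
            b = np.zeros((bx.shape[0] + by.shape[0], bx.shape[1] + by.shape[1], rc))
            if node.index == 0:
                b[: bx.shape[0], : bx.shape[1], 0] = bx[:, :, 0]
                b[bx.shape[0]:, bx.shape[1]:, 0] = by[:, :, 0]
            else:
                b[: bx.shape[0], : bx.shape[1], : bx.shape[2]] = bx
                b[bx.shape[0]:, bx.shape[1]:, bx.shape[2]:] = by
            transfer[node.index] = b
    return HTTensor(tree=x.tree, sizes=list(x.sizes), frames=frames, transfer=transfer)


def ht_scale(x: HTTensor, alpha: float) -> HTTensor:
    """Scalar multiple (scales the root transfer tensor only)."""
    out = x.copy()
    if x.tree.n_nodes == 1:
        out.frames[0] = out.frames[0] * float(alpha)
    else:
        out.transfer[0] = out.transfer[0] * float(alpha)
    return out


_LAPACK_QR = get_lapack_funcs(("geqrf", "orgqr"), (np.empty((2, 2)),))
_LAPACK_SYEVD = get_lapack_funcs(("syevd",), (np.empty((2, 2)),))[0]
_TRIU_MASKS: dict[tuple[int, int], np.ndarray] = {}


def _triu_mask(k: int, n: int) -> np.ndarray:
    mask = _TRIU_MASKS.get((k, n))
    if mask is None:
        mask = np.triu(np.ones((k, n), dtype=bool))
        _TRIU_MASKS[(k, n)] = mask
    return mask


def _qr(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reduced QR via LAPACK with less wrapper overhead than np.linalg.qr."""
    m, n = a.shape
    k = min(m, n)
    geqrf, orgqr = _LAPACK_QR
    qr_, tau, _, info = geqrf(a, overwrite_a=False)
    if info != 0:  # pragma: no cover - LAPACK failure
        return np.linalg.qr(a)
    r = qr_[:k, :] * _triu_mask(k, n)
    q, _, info = orgqr(qr_[:, :k] if n > k else qr_, tau)
    if info != 0:  # pragma: no cover
        return np.linalg.qr(a)
    return q[:, :k], r


def _eigh(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition (ascending) with low wrapper overhead."""
    w, v, info = _LAPACK_SYEVD(a, lower=1)
    if info != 0:  # pragma: no cover - LAPACK failure
        return np.linalg.eigh(a)
    return w, v


def _mode0(m: np.ndarray, b: np.ndarray) -> np.ndarray:
    """out[a',b,c] = sum_a m[a',a] b[a,b,c]"""
    return (m @ b.reshape(b.shape[0], -1)).reshape(m.shape[0], b.shape[1], b.shape[2])


def _mode1(m: np.ndarray, b: np.ndarray) -> np.ndarray:
    """out[a,b',c] = sum_b m[b',b] b[a,b,c]"""
    return np.matmul(m, b)


def ht_inner(x: HTTensor, y: HTTensor) -> float:
    """Euclidean inner product <x, y> via nodewise cross-Gram matrices."""
    _check_compatible(x, y)
    m: dict[int, np.ndarray] = {}
    for node in x.tree.postorder():
        if node.is_leaf:
            m[node.index] = x.frames[node.index].T @ y.frames[node.index]
        else:
            bx = x.transfer[node.index]
            by = y.transfer[node.index]
            t = _mode0(m.pop(node.left), by)
            t = _mode1(m.pop(node.right), t)  # (a, b, c') in x's child ranks
            m[node.index] = (
                bx.reshape(-1, bx.shape[2]).T @ t.reshape(-1, t.shape[2])
            )
    return float(m[0][0, 0])


def orthogonalize(x: HTTensor) -> HTTensor:
    """Leaves-to-root orthogonalization.

    Afterwards every non-root leaf frame and every non-root transfer
    matricization (reshaped to (r_left * r_right) x r_node) has orthonormal
    columns; the tensor is unchanged.
    """
    frames: dict[int, np.ndarray] = {}
    transfer: dict[int, np.ndarray] = {}
    rfac: dict[int, np.ndarray] = {}
    for node in x.tree.postorder():
        if node.is_leaf:
            if node.index == 0:  # d = 1: the single frame is the tensor
                frames[node.index] = x.frames[node.index]
                continue
            q, r = _qr(x.frames[node.index])
            frames[node.index] = q
            rfac[node.index] = r
        else:
            b = x.transfer[node.index]
            b = _mode0(rfac.pop(node.left), b)
            b = _mode1(rfac.pop(node.right), b)
            if node.index == 0:
                transfer[node.index] = b
            else:
                k1, k2, rc = b.shape
                q, r = _qr(b.reshape(k1 * k2, rc))
                transfer[node.index] = q.reshape(k1, k2, q.shape[1])
                rfac[node.index] = r
    return HTTensor(tree=x.tree, sizes=list(x.sizes), frames=frames, transfer=transfer)


def ht_norm(x: HTTensor) -> float:
    """Euclidean norm, computed stably via orthogonalization."""
    if x.tree.n_nodes == 1:
        return float(np.linalg.norm(x.frames[0]))
    xo = orthogonalize(x)
    return float(np.linalg.norm(xo.transfer[0]))


def gramians(x_orth: HTTensor) -> dict[int, np.ndarray]:
    """Reduced Gramians G_t of an *orthogonalized* tensor, root to leaves.

    The eigenvalues of G_t are the squared singular values of the
    matricization B^(t).
    """
    g: dict[int, np.ndarray] = {0: np.ones((1, 1))}
    for node in x_orth.tree.preorder():
        if node.is_leaf:
            continue
        b = x_orth.transfer[node.index]
        r1, r2, rc = b.shape
        t = (b.reshape(-1, rc) @ g[node.index]).reshape(r1, r2, rc)
        g[node.left] = t.reshape(r1, -1) @ b.reshape(r1, -1).T
        tt = t.transpose(1, 0, 2).reshape(r2, -1)
        bt = b.transpose(1, 0, 2).reshape(r2, -1)
        g[node.right] = tt @ bt.T
    return g


def node_singular_values(x: HTTensor) -> dict[int, np.ndarray]:
    """Singular values of the matricization B^(t) for every tree node.

    Only the leading r_t values are representable (the rest are exactly
    zero); the root carries the single value |x|.  Sequences are
    nonincreasing.
    """
    xo = orthogonalize(x)
    g = gramians(xo)
    out: dict[int, np.ndarray] = {}
    for node in x.tree.nodes:
        if node.index == 0:
            out[0] = np.array([ht_norm(xo)])
        else:
            ev = _eigh(g[node.index])[0]
            out[node.index] = np.sqrt(np.clip(ev[::-1], 0.0, None))
    return out


def ht_truncate(x: HTTensor, ctrl: TruncationControl) -> HTTensor:
    """SVD-based truncation with a guaranteed relative error bound.

    The discarded-eigenvalue budget ``(eps * |x|)^2`` is split uniformly over
    the non-root nodes; per node the smallest rank is kept whose discarded
    tail stays within its share.  The total error then satisfies the
    computable bound  |x - trunc(x)|^2 <= sum_t sum_{m > r_t} sigma_{t,m}^2
    <= (eps |x|)^2.  Ranks never drop below 1; ``max_rank`` caps are honored
    even when that exceeds the error budget.
    """
    if x.tree.n_nodes == 1:
        return x.copy()
    xo = orthogonalize(x)
    norm = float(np.linalg.norm(xo.transfer[0]))
    n_nodes = xo.tree.n_nodes
    if norm == 0.0:
        budget = 0.0
    else:
        budget = (ctrl.eps * norm) ** 2 / (n_nodes - 1)
    g = gramians(xo)
    proj: dict[int, np.ndarray] = {0: np.ones((1, 1))}
    for node in xo.tree.nodes:
        if node.index == 0:
            continue
        ev, vec = _eigh(g[node.index])  # ascending
        ev = np.clip(ev, 0.0, None)
        csum = np.cumsum(ev)
        r_full = ev.shape[0]
        # smallest rank whose discarded tail (the smallest eigenvalues) fits
        keep = r_full - int(np.searchsorted(csum, budget, side="right"))
        keep = max(keep, 1)
        if ctrl.max_rank is not None:
            keep = min(keep, ctrl.max_rank)
        proj[node.index] = vec[:, ::-1][:, :keep]
    frames: dict[int, np.ndarray] = {}
    transfer: dict[int, np.ndarray] = {}
    for node in xo.tree.nodes:
        if node.is_leaf:
            frames[node.index] = xo.frames[node.index] @ proj[node.index]
        else:
            b = xo.transfer[node.index]
            b = _mode0(proj[node.left].T, b)
            b = _mode1(proj[node.right].T, b)
            if node.index != 0:
                b = (b.reshape(-1, b.shape[2]) @ proj[node.index]).reshape(
                    b.shape[0], b.shape[1], -1
                )
            transfer[node.index] = b
    return HTTensor(tree=xo.tree, sizes=list(xo.sizes), frames=frames, transfer=transfer)


def _apply_term(term: list[np.ndarray], x: HTTensor) -> HTTensor:
    """Apply one Kronecker-product operator term (leaf frames only change)."""
    out = x.copy()
    for node in x.tree.leaves():
        mode = node.modes[0]
        out.frames[node.index] = term[mode] @ x.frames[node.index]
    return out


def apply_cp_operator(
    a: CPOperator,
    x: HTTensor,
    ctrl: TruncationControl | None = None,
    mode: str = "incremental",
) -> HTTensor:
    """Apply a CP operator to an HT tensor.

    ``batch``: sum all terms exactly (node ranks grow to <= rank(a) * r_x),
    then truncate once.  ``incremental``: truncate after each accumulated
    term, keeping intermediate ranks near the working rank instead of the
    product.  With ``ctrl=None`` the application is exact (no truncation).
    """
    if list(a.sizes) != list(x.sizes):
        raise ValueError("operator and tensor mode sizes differ")
    if a.rank == 0:
        raise ValueError("operator has no terms")
    if mode not in ("batch", "incremental"):
        raise ValueError(f"unknown mode {mode!r}")
    acc = _apply_term(a.terms[0], x)
    for term in a.terms[1:]:
        acc = ht_add(acc, _apply_term(term, x))
        if mode == "incremental" and ctrl is not None:
            acc = ht_truncate(acc, ctrl)
    if mode == "batch" and ctrl is not None:
        acc = ht_truncate(acc, ctrl)
    return acc


def ht_storage(x: HTTensor) -> int:
    """Number of stored values: sum of frame and transfer tensor sizes."""
    total = sum(int(v.size) for v in x.frames.values())
    total += sum(int(v.size) for v in x.transfer.values())
    return total


def random_ht(
    tree: DimensionTree,
    sizes: list[int],
    rank: int,
    rng: np.random.Generator,
) -> HTTensor:
    """Random HT tensor with (at most) the given constant rank, for tests."""
    frames: dict[int, np.ndarray] = {}
    transfer: dict[int, np.ndarray] = {}
    for node in tree.nodes:
        if node.is_leaf:
            n_i = sizes[node.modes[0]]
            r_leaf = 1 if node.index == 0 else min(rank, n_i)
            frames[node.index] = rng.standard_normal((n_i, r_leaf))
    # child ranks may be clipped by mode sizes at the leaves
    def node_rank(idx: int) -> int:
        node = tree.nodes[idx]
        if node.is_leaf:
            return frames[idx].shape[1]
        return 1 if idx == 0 else rank

    for node in tree.nodes:
        if not node.is_leaf:
            r1 = node_rank(node.left)
            r2 = node_rank(node.right)
            rc = node_rank(node.index)
            transfer[node.index] = rng.standard_normal((r1, r2, rc))
    return HTTensor(tree=tree, sizes=list(sizes), frames=frames, transfer=transfer)
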