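"""Hierarchical Tucker arithmetic and rank truncation.

Builds a rank-4 tensor in dimension 6, runs the basic arithmetic, and
truncates it, checking the computed error against the discarded-singular-
value bound.
"""

import numpy as np

from htmarginal import (
    CPTensor,
    TruncationControl,
    balanced_tree,
    cp_to_ht,
    ht_add,
    ht_inner,
    ht_norm,
    ht_scale,
    ht_to_dense,
    ht_truncate,
    ht_storage,
    node_singular_values,
)

rng = np.random.default_rng(1)
sizes = [2] * 6
tree = balanced_tree(6)
cp = CPTensor(sizes, [[rng.standard_normal(2) for _ in sizes] for _ in range(4)])
x = cp_to_ht(cp, tree)

print(f"node ranks after CP->HT (CP rank 4): {sorted(set(x.ranks.values()))}")
print(f"norm via orthogonalization: {ht_norm(x):.6f}")
print(f"inner <x, 2x> / <x, x> = {ht_inner(x, ht_scale(x, 2.0)) / ht_inner(x, x):.6f}")

cp2 = CPTensor(sizes, [[rng.standard_normal(2) for _ in sizes] for _ in range(4)])
y = ht_add(x, ht_scale(cp_to_ht(cp2, tree), 0.05))  # ranks add: 4 + 4
print(f"max node rank after addition: {max(y.ranks.values())}")

eps = 1e-2
yt = ht_truncate(y, TruncationControl(eps=eps))
err = np.linalg.norm(ht_to_dense(yt) - ht_to_dense(y))
sv = node_singular_values(y)
bound = np.sqrt(sum(float(np.sum(sv[i][yt.rank(i):] ** 2)) for i in sv if i != 0))
print(f"truncation: storage {ht_storage(y)} -> {ht_storage(yt)}")
print(f"error {err:.3e} <= node-sv bound {bound:.3e} <= eps*|y| {eps * ht_norm(y):.3e}")
# The middle quantity is the computable bound: the root sum of squared
# discarded singular values over all tree nodes.
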