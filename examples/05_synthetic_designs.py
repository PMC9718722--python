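"""The three synthetic block designs for MHN parameters.

B1: direct effects only within blocks (log-Normal(0, 0.25), diagonal
included).  B2: plus 4 directed effects per pair of neighboring blocks
(log-Normal(0, 0.125)).  B3: plus 8 directed effects between arbitrary
distinct blocks.  Everything else is exactly 1 (neutral).
"""

import numpy as np

from htmarginal import BlockDesign, sample_theta, describe_blocks
from htmarginal.synthetic import block_separating_order

for kind in ("B1", "B2", "B3"):
    design = BlockDesign(d=12, n_blocks=3, kind=kind, seed=4)
    theta = sample_theta(design).theta
    blocks = describe_blocks(design)
    cross = (blocks[:, None] != blocks[None, :]) & (theta != 1.0)
    within = (blocks[:, None] == blocks[None, :])
    print(
        f"{kind}: {cross.sum():2d} cross-block effects, "
        f"within-block log-sd {np.log(theta[within]).std():.3f}"
        + (f", cross-block log-sd {np.log(theta[cross]).std():.3f}" if cross.any() else "")
    )

design = BlockDesign(d=8, n_blocks=2, seed=0)
print("block membership (d=8, 2 blocks):", describe_blocks(design))
print("block-separating leaf order (1-based):",
      [i + 1 for i in block_separating_order(design)])
# The separating order places members of each block in both root subtrees --
# the worst case for the achievable hierarchical ranks (see example 06).
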