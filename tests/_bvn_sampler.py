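"""Random 2x2 tables drawn from dichotomized bivariate normals.

Shared by the oracle-agreement tests: each table comes from a known
latent correlation with non-degenerate margins, so the tetrachoric MLE
is well defined away from the boundary.
"""

import numpy as np
from scipy.special import ndtri

from .oracles import bvn_quadrant_prob


def random_estimable_table(rng: np.random.Generator):
    """One multinomial 2x2 table from a random dichotomized BVN."""
    n = int(rng.integers(200, 2000))
    p1 = rng.uniform(0.2, 0.8)
    p2 = rng.uniform(0.2, 0.8)
    rho = rng.uniform(-0.85, 0.85)
    tx, ty = ndtri(1 - p1), ndtri(1 - p2)
    p11 = bvn_quadrant_prob(tx, ty, rho)
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.clip([p11, p10, p01, p00], 0.0, 1.0)
    probs /= probs.sum()
    cells = rng.multinomial(n, probs)
    return [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
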