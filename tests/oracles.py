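"""Independent reference implementations used only by the test suite.

These deliberately avoid the code paths they check: 3D connectivity via
scipy.ndimage face-adjacency labeling, the Mann-Whitney null by full
enumeration, and Benjamini-Hochberg straight from its step-up
definition.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import ndimage


def bruteforce_3d_labels(mask: np.ndarray) -> np.ndarray:
    """Face-adjacency (6-connected) 3D connected-component labels.

    Per-section 4-connectivity plus single-pixel overlap between
    consecutive sections is exactly face adjacency in 3D.
    """
    structure = ndimage.generate_binary_structure(3, 1)
    labels, _ = ndimage.label(mask, structure=structure)
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Do two label volumes partition the same foreground identically?"""
    fg = a > 0
    if not np.array_equal(fg, b > 0):
        return False
    if not fg.any():
        return True
    pairs = np.unique(np.stack([a[fg], b[fg]]), axis=1)
    return pairs.shape[1] == np.unique(a[fg]).size == np.unique(b[fg]).size


def mwu_enumeration(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney test by enumerating all C(n+m, n)
    rank assignments (untied samples only)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    u_obs = sum(1.0 for x in a for y in b if x > y)
    total = comb(n + m, n)
    center = n * m / 2.0
    dev = abs(u_obs - center)
    count = 0
    positions = range(n + m)
    # U depends only on which rank positions group A occupies
    for idx in combinations(positions, n):
        idx = np.asarray(idx)
        # ranks are 0..n+m-1; U_a = sum(ranks_a) - n(n-1)/2
        u = idx.sum() - n * (n - 1) / 2.0
        if abs(u - center) >= dev - 1e-12:
            count += 1
    return u_obs, count / total


def bh_bruteforce(p_values) -> np.ndarray:
    """BH step-up from the definition: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
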