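"""Nonparametric group statistics for response metrics.

Group comparisons follow the standard nonparametric battery: a
Mann-Whitney U (rank-sum) test for two groups, a Kruskal-Wallis H test
for more than two, and post-hoc pairwise Mann-Whitney tests with
Benjamini-Hochberg false-discovery-rate correction.  Significance is
called at a corrected p below 0.05.

The Mann-Whitney p-value is exact (full enumeration of the U null
distribution) for small untied samples — combined n <= 14 with no ties —
and otherwise uses the tie-corrected normal approximation without
continuity correction, which makes the two-group case agree with the
Kruskal-Wallis chi-square p.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
EXACT_MAX_N = 14


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U counted for ``sample_a`` using midranks
    for ties.  Exact enumeration p when the combined sample is small and
    untied, tie-corrected normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if a.size + b.size <= EXACT_MAX_N and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction.

    Accepts two or more nonempty groups; returns ``(H, p)`` with a
    chi-square p on k-1 degrees of freedom.  When every observation is
    identical the statistic is 0 and p is 1 by convention.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(
        groups[0][0]
    ):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("groups must be nonempty")
    combined = np.concatenate(arrays)
    if np.unique(combined).size == 1:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Adjusted value i = min over j >= i (rank order) of p_(j) * m / j,
    capped at 1, returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie within [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def pairwise_mwu_bh(groups: dict, alpha: float = ALPHA):
    """Post-hoc pairwise Mann-Whitney tests with BH correction.

    ``groups`` maps a group name to its sample.  Returns a list of dicts
    with the pair, U, raw and adjusted p, and the significance call at
    ``alpha``.
    """
    names = sorted(groups)
    pairs = list(combinations(names, 2))
    raw = []
    stats_u = []
    for x, y in pairs:
        u, p = mann_whitney_u(groups[x], groups[y])
        stats_u.append(u)
        raw.append(p)
    adjusted = bh_adjust(raw) if raw else np.empty(0)
    return [
        {
            "group_a": x,
            "group_b": y,
            "U": u,
            "p_raw": p,
            "p_adjusted": float(q),
            "significant": bool(q < alpha),
        }
        for (x, y), u, p, q in zip(pairs, stats_u, raw, adjusted)
    ]
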