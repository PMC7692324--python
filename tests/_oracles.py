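"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths (and numpy's quantile
routine where it matters): quartiles by hand-rolled interpolation on sorted
values, Mann-Whitney p by full enumeration of labelings, average linkage by
naive O(n^3) agglomeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

TISSUES = ("primary_tumor", "normal_tissue")
CLASSES = ("cancer_hyper", "cancer_hypo", "tissue_hyper", "tissue_hypo")


def hand_quantile(values, q):
    """Linear interpolation between order statistics (h = (n-1)q)."""
    v = sorted(x for x in values if not math.isnan(x))
    if not v:
        return float("nan")
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def classify_literal(group_values, target, cancer_codes, hyper=0.6, hypo=0.3,
                     min_group_size=2):
    """Literal evaluation of the four quartile rule sets from raw group values.

    ``group_values`` maps (cancer, tissue) -> list of beta values.  Applies
    the fixed precedence cancer_hyper > cancer_hypo > tissue_hyper >
    tissue_hypo and returns "none" when no rule fires or a group is too
    small.
    """
    q1, q3 = {}, {}
    for code in cancer_codes:
        for tissue in TISSUES:
            vals = [x for x in group_values[(code, tissue)] if not math.isnan(x)]
            if len(vals) < min_group_size:
                return "none"
            q1[(code, tissue)] = hand_quantile(vals, 0.25)
            q3[(code, tissue)] = hand_quantile(vals, 0.75)
    others = [c for c in cancer_codes if c != target]
    t, n = TISSUES
    others_low = all(q3[(o, t)] < hypo and q3[(o, n)] < hypo for o in others)
    others_high = all(q1[(o, t)] > hyper and q1[(o, n)] > hyper for o in others)
    if q1[(target, t)] > hyper and q3[(target, n)] < hypo and others_low:
        return "cancer_hyper"
    if q3[(target, t)] < hypo and q1[(target, n)] > hyper and others_high:
        return "cancer_hypo"
    if q1[(target, t)] > hyper and q1[(target, n)] > hyper and others_low:
        return "tissue_hyper"
    if q3[(target, t)] < hypo and q3[(target, n)] < hypo and others_high:
        return "tissue_hypo"
    return "none"


def mann_whitney_enumerate(x, y):
    """Exact two-sided Mann-Whitney by enumerating all C(n1+n2, n1) labelings.

    U counts (x, y) pairs with x > y (ties half).  Requires untied pooled
    values for the exact null distribution to be symmetric.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y
    u_obs = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
    u_vals = []
    for idx in itertools.combinations(range(n1 + n2), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(n1 + n2) if i not in chosen]
        u_vals.append(sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys))
    u_big = max(u_obs, n1 * n2 - u_obs)
    p = sum(u >= u_big for u in u_vals) + sum(u <= n1 * n2 - u_big for u in u_vals)
    return u_obs, min(1.0, p / len(u_vals))


def average_linkage_heights(points):
    """Naive O(n^3) average-linkage agglomeration; returns sorted merge heights.

    Distances are Euclidean between rows of ``points``; the average linkage
    between clusters is the mean of all cross-pair point distances.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a] for j in clusters[b]
                ])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def bh_stepup(p_values):
    """Hand step-up Benjamini-Hochberg in the original order."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q
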