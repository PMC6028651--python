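"""Independent brute-force oracles used to pin down feature definitions.

Everything here is written as plain exhaustive enumeration (nested Python
loops over voxels, pairs, runs and matrix cells) and shares no code with
the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def pairwise_auc(scores, labels) -> float:
    """AUC by exhaustive positive-negative pair comparison, ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def glcm_counts(levels: np.ndarray, offsets, distance: int = 1) -> np.ndarray:
    """Symmetrized pair counts by scanning every voxel against every offset."""
    n_g = int(levels.max())
    counts = np.zeros((n_g, n_g))
    shape = levels.shape
    for d in offsets:
        step = tuple(c * distance for c in d)
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    a = levels[i, j, k]
                    if a == 0:
                        continue
                    ii, jj, kk = i + step[0], j + step[1], k + step[2]
                    if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                        continue
                    b = levels[ii, jj, kk]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    return counts


def glrlm_counts(levels: np.ndarray, directions) -> np.ndarray:
    """Run counts by walking every maximal run from its start voxel."""
    n_g = int(levels.max())
    shape = levels.shape
    runs = []
    for d in directions:
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    lev = levels[i, j, k]
                    if lev == 0:
                        continue
                    pi, pj, pk = i - d[0], j - d[1], k - d[2]
                    inside = 0 <= pi < shape[0] and 0 <= pj < shape[1] and 0 <= pk < shape[2]
                    if inside and levels[pi, pj, pk] == lev:
                        continue  # not a run start
                    length = 1
                    ci, cj, ck = i + d[0], j + d[1], k + d[2]
                    while (
                        0 <= ci < shape[0]
                        and 0 <= cj < shape[1]
                        and 0 <= ck < shape[2]
                        and levels[ci, cj, ck] == lev
                    ):
                        length += 1
                        ci, cj, ck = ci + d[0], cj + d[1], ck + d[2]
                    runs.append((lev, length))
    max_len = max(length for _, length in runs)
    counts = np.zeros((n_g, max_len))
    for lev, length in runs:
        counts[lev - 1, length - 1] += 1
    return counts


def _log2(x: float) -> float:
    return math.log2(x) if x > 0 else 0.0


def glcm_feature_formulas(p: np.ndarray) -> dict[str, float]:
    """The 23 co-occurrence features evaluated formula by formula with loops."""
    n_g = p.shape[0]
    levels = range(1, n_g + 1)
    px = [sum(p[i - 1, j - 1] for j in levels) for i in levels]
    mu = sum(i * px[i - 1] for i in levels)
    sigma = math.sqrt(sum((i - mu) ** 2 * px[i - 1] for i in levels))

    p_sum = {k: 0.0 for k in range(2, 2 * n_g + 1)}
    p_diff = {k: 0.0 for k in range(0, n_g)}
    for i in levels:
        for j in levels:
            p_sum[i + j] += p[i - 1, j - 1]
            p_diff[abs(i - j)] += p[i - 1, j - 1]

    out = {}
    out["autocorrelation"] = sum(i * j * p[i - 1, j - 1] for i in levels for j in levels)
    for name, power in (("cluster_tendency", 2), ("cluster_shade", 3), ("cluster_prominence", 4)):
        out[name] = sum(
            (i + j - 2 * mu) ** power * p[i - 1, j - 1] for i in levels for j in levels
        )
    out["contrast"] = sum((i - j) ** 2 * p[i - 1, j - 1] for i in levels for j in levels)
    if sigma > 0:
        out["correlation"] = (out["autocorrelation"] - mu * mu) / sigma**2
    else:
        out["correlation"] = 1.0
    da = sum(k * v for k, v in p_diff.items())
    out["difference_entropy"] = -sum(v * _log2(v) for v in p_diff.values())
    out["dissimilarity"] = sum(abs(i - j) * p[i - 1, j - 1] for i in levels for j in levels)
    out["difference_variance"] = sum((k - da) ** 2 * v for k, v in p_diff.items())
    out["energy_c"] = sum(p[i - 1, j - 1] ** 2 for i in levels for j in levels)
    hxy = -sum(p[i - 1, j - 1] * _log2(p[i - 1, j - 1]) for i in levels for j in levels)
    out["entropy_c"] = hxy
    out["homogeneity_1"] = sum(
        p[i - 1, j - 1] / (1 + abs(i - j)) for i in levels for j in levels
    )
    out["homogeneity_2"] = sum(
        p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in levels for j in levels
    )
    hx = -sum(v * _log2(v) for v in px)
    hxy1 = -sum(
        p[i - 1, j - 1] * _log2(px[i - 1] * px[j - 1]) for i in levels for j in levels
    )
    hxy2 = -sum(
        px[i - 1] * px[j - 1] * _log2(px[i - 1] * px[j - 1])
        for i in levels
        for j in levels
    )
    out["imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["idmn"] = sum(
        p[i - 1, j - 1] / (1 + ((i - j) / n_g) ** 2) for i in levels for j in levels
    )
    out["idn"] = sum(
        p[i - 1, j - 1] / (1 + abs(i - j) / n_g) for i in levels for j in levels
    )
    out["inverse_variance"] = sum(
        p[i - 1, j - 1] / (i - j) ** 2 for i in levels for j in levels if i != j
    )
    out["maximum_probability"] = max(p[i - 1, j - 1] for i in levels for j in levels)
    sa = sum(k * v for k, v in p_sum.items())
    out["sum_average"] = sa
    out["sum_entropy"] = -sum(v * _log2(v) for v in p_sum.values())
    out["sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    out["variance_c"] = sum(
        (i - mu) ** 2 * p[i - 1, j - 1] for i in levels for j in levels
    )
    return out


def km_product_limit(times, events):
    """Hand product-limit table: list of (event_time, survival_after)."""
    table = []
    s = 1.0
    for t in sorted(set(t for t, e in zip(times, events) if e == 1)):
        n = sum(1 for u in times if u >= t)
        d = sum(1 for u, e in zip(times, events) if u == t and e == 1)
        s *= 1 - d / n
        table.append((t, s))
    return table


def logrank_observed_expected(times_a, events_a, times_b, events_b):
    """Hand risk-set table: (observed_a, expected_a) over pooled event times."""
    event_times = sorted(
        set([t for t, e in zip(times_a, events_a) if e == 1]
            + [t for t, e in zip(times_b, events_b) if e == 1])
    )
    oa = ea = 0.0
    for t in event_times:
        na = sum(1 for u in times_a if u >= t)
        nb = sum(1 for u in times_b if u >= t)
        da = sum(1 for u, e in zip(times_a, events_a) if u == t and e == 1)
        db = sum(1 for u, e in zip(times_b, events_b) if u == t and e == 1)
        oa += da
        ea += (da + db) * na / (na + nb)
    return oa, ea
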