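"""Independent brute-force oracles for the texture, selection and clustering
stages.

Everything here is written as plain double/triple loops straight from the
defining formulas, deliberately sharing no code with the package, so the
vectorized implementations can be checked against them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- co-occurrence -----------------------------------------------------------

def com_counts_brute(pixels: np.ndarray, dy: int, dx: int, levels: int) -> np.ndarray:
    h, w = pixels.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w:
                a, b = pixels[y, x], pixels[y2, x2]
                counts[a, b] += 1
                counts[b, a] += 1
    return counts


def com_features_brute(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    L = counts.shape[0]
    P = counts / total

    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(L))

    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    def ent(ps):
        return -sum(p * math.log2(p) for p in ps if p > 0)

    asm = sum(P[i][j] ** 2 for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * P[i][j] for i in range(L) for j in range(L))
    if var_x > 0:
        corr = (
            sum(i * j * P[i][j] for i in range(L) for j in range(L)) - mu_x * mu_x
        ) / var_x
    else:
        corr = 0.0
    ssq = sum((i - mu_x) ** 2 * P[i][j] for i in range(L) for j in range(L))
    idm = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    sum_avg = sum(k * p_sum[k] for k in range(2 * L - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * L - 1))
    diff_mean = sum(k * p_diff[k] for k in range(L))
    diff_var = sum((k - diff_mean) ** 2 * p_diff[k] for k in range(L))
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": corr,
        "sum_of_squares": ssq,
        "idm": idm,
        "sum_average": sum_avg,
        "sum_variance": sum_var,
        "sum_entropy": ent(p_sum),
        "entropy": ent([P[i][j] for i in range(L) for j in range(L)]),
        "difference_variance": diff_var,
        "difference_entropy": ent(p_diff),
    }


# --- run length --------------------------------------------------------------

def _lines(pixels: np.ndarray, direction: int):
    h, w = pixels.shape
    if direction == 0:
        return [list(pixels[y]) for y in range(h)]
    if direction == 90:
        return [list(pixels[:, x]) for x in range(w)]
    step = (-1, 1) if direction == 45 else (-1, -1)
    lines, seen = [], set()
    for y0 in range(h):
        for x0 in range(w):
            # walk to the start of this line, then collect it once
            y, x = y0, x0
            while 0 <= y - step[0] < h and 0 <= x - step[1] < w:
                y, x = y - step[0], x - step[1]
            if (y, x) in seen:
                continue
            seen.add((y, x))
            line = []
            while 0 <= y < h and 0 <= x < w:
                line.append(pixels[y, x])
                y, x = y + step[0], x + step[1]
            lines.append(line)
    return lines


def rlm_counts_brute(pixels: np.ndarray, direction: int, levels: int) -> np.ndarray:
    rmax = max(pixels.shape)
    counts = np.zeros((levels, rmax + 1), dtype=np.int64)
    for line in _lines(pixels, direction):
        run_val, run_len = line[0], 1
        for v in line[1:]:
            if v == run_val:
                run_len += 1
            else:
                counts[run_val, run_len] += 1
                run_val, run_len = v, 1
        counts[run_val, run_len] += 1
    return counts


def rlm_features_brute(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    L, R = counts.shape
    n_runs = counts.sum()
    sre = sum(counts[g, r] / r**2 for g in range(L) for r in range(1, R)) / n_runs
    lre = sum(counts[g, r] * r**2 for g in range(L) for r in range(1, R)) / n_runs
    gln = sum(sum(counts[g, r] for r in range(R)) ** 2 for g in range(L)) / n_runs
    rln = sum(sum(counts[g, r] for g in range(L)) ** 2 for r in range(R)) / n_runs
    return {
        "short_run_emphasis": sre,
        "long_run_emphasis": lre,
        "gray_level_nonuniformity": gln,
        "run_length_nonuniformity": rln,
        "run_percentage": n_runs / n_pixels,
    }


# --- gradient ----------------------------------------------------------------

def grm_magnitudes_brute(pixels: np.ndarray) -> np.ndarray:
    h, w = pixels.shape
    out = np.zeros((h - 2, w - 2))
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            gy = float(pixels[y + 1, x]) - float(pixels[y - 1, x])
            gx = float(pixels[y, x + 1]) - float(pixels[y, x - 1])
            out[y - 1, x - 1] = math.sqrt(gy * gy + gx * gx)
    return out


def grm_features_brute(mags: np.ndarray) -> dict[str, float]:
    vals = [float(v) for v in mags.ravel()]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    if var > 0:
        skew = (sum((v - mean) ** 3 for v in vals) / n) / var**1.5
        kurt = (sum((v - mean) ** 4 for v in vals) / n) / var**2 - 3.0
    else:
        skew = kurt = 0.0
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "nonzero_pct": 100.0 * sum(1 for v in vals if v != 0) / n,
    }


# --- selection & clustering --------------------------------------------------

def fisher_brute(groups: dict[str, list[float]]) -> float:
    n_total = sum(len(v) for v in groups.values())
    grand = sum(sum(v) for v in groups.values()) / n_total
    between = within = 0.0
    for v in groups.values():
        p = len(v) / n_total
        mu = sum(v) / len(v)
        var = sum((x - mu) ** 2 for x in v) / len(v)
        between += p * (mu - grand) ** 2
        within += p * var
    if within == 0:
        return math.inf if between > 0 else 0.0
    return between / within


def best_two_partition(Z: np.ndarray) -> frozenset[int]:
    """Exhaustive 2-means: the 2-partition minimizing within-cluster SSE.

    Returns the member set of the cluster containing sample 0 (canonical
    side).  Only feasible for small n.
    """
    n = len(Z)
    best, best_sse = None, math.inf
    for r in range(0, n - 1):
        for combo in itertools.combinations(range(1, n), r):
            a = [0] + list(combo)
            b = [i for i in range(n) if i not in a]
            if not b:
                continue
            sse = 0.0
            for side in (a, b):
                c = Z[side].mean(axis=0)
                sse += float(((Z[side] - c) ** 2).sum())
            if sse < best_sse:
                best_sse, best = sse, frozenset(a)
    return best
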