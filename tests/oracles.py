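"""Independent brute-force reference implementations used to validate the
package's statistics and rejection rules.  Everything here is written from
the textbook definitions (rank formulas, exhaustive enumeration, O(n²) pair
counting) and deliberately shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import chi2, rankdata


def friedman_oracle(table: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square with the standard tie correction, from the rank
    formula (subjects × conditions)."""
    n, k = table.shape
    ranks = np.array([rankdata(row) for row in table])
    col_sums = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    ties = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0, 1.0
    chisq /= c
    return float(chisq), float(chi2.sf(chisq, k - 1))


def wilcoxon_exact_oracle(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns
    of the absolute-difference ranks (zeros dropped)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    r = rankdata(np.abs(d))
    w_obs = float(r[d > 0].sum())
    dist = np.zeros(2 ** n)
    for s in range(2 ** n):
        dist[s] = sum(r[i] for i in range(n) if (s >> i) & 1)
    p_le = np.mean(dist <= w_obs)
    p_ge = np.mean(dist >= w_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def kendall_taub_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-b by O(n²) concordant/discordant/tie pair counting."""
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2.0
    denom = math.sqrt((n0 - _tie_pairs(x)) * (n0 - _tie_pairs(y)))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def _tie_pairs(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2.0))


def max_zscore_oracle(weights: np.ndarray) -> float:
    """Max z-score of the absolute weights (population SD), elementwise."""
    w = np.abs(np.asarray(weights, dtype=float))
    sd = w.std()
    if sd == 0:
        return 0.0
    return float(max((wi - w.mean()) / sd for wi in w))


def rejection_oracle(max_uv: np.ndarray, baseline_uv: np.ndarray,
                     conditions: np.ndarray, sd_factor: float = 3.0) -> np.ndarray:
    """Single-pass mean+k·SD rejection (disjunctive), per the documented
    rule: in-window maxima per condition, baselines per subject, sample SD,
    strict inequality."""
    n = len(max_uv)
    flags = np.zeros(n, dtype=bool)
    for cond in np.unique(conditions):
        idx = [i for i in range(n) if conditions[i] == cond]
        vals = np.array([max_uv[i] for i in idx])
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        thr = vals.mean() + sd_factor * sd
        for i, v in zip(idx, vals):
            if v > thr:
                flags[i] = True
    sd = baseline_uv.std(ddof=1) if n > 1 else 0.0
    thr = baseline_uv.mean() + sd_factor * sd
    for i in range(n):
        if baseline_uv[i] > thr:
            flags[i] = True
    return flags


def amari_index(P: np.ndarray) -> float:
    """Amari permutation error of a product unmixing·mixing matrix (0 for a
    perfect scaled permutation)."""
    P = np.abs(P)
    m = P.shape[0]
    s1 = (P / P.max(axis=1, keepdims=True)).sum() - m
    s2 = (P / P.max(axis=0, keepdims=True)).sum() - m
    return float((s1 + s2) / (2 * m * (m - 1)))
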