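"""Naive loop-based re-implementation of the MB-MDR analysis, used as oracle.

Everything here is written with explicit per-pair, per-cell, per-permutation
loops on top of scipy.stats, sharing no code with the package's vectorized
engine, so that agreement between the two is an independent check of the
analysis mathematics.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats


def naive_pair_f(g1, g2, t, cfg) -> float:
    """Step-2 statistic of one SNP pair: label cells, then max(F_H, F_L)."""
    n = t.size
    equal_var = cfg.test_kind == "student"
    labels = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in range(3):
            for b in range(3):
                in_cell = (g1 == a) & (g2 == b)
                n1 = int(in_cell.sum())
                if n1 < cfg.min_cell or n - n1 < cfg.min_cell:
                    continue
                res = stats.ttest_ind(t[in_cell], t[~in_cell], equal_var=equal_var)
                if np.isfinite(res.statistic) and res.pvalue <= cfg.alpha_label:
                    if res.statistic > 0:
                        labels[(a, b)] = "H"
                    elif res.statistic < 0:
                        labels[(a, b)] = "L"
        best = 0.0
        for lab in "HL":
            mask = np.zeros(n, dtype=bool)
            for (a, b), l in labels.items():
                if l == lab:
                    mask |= (g1 == a) & (g2 == b)
            ng = int(mask.sum())
            if ng < cfg.min_cell or n - ng < cfg.min_cell:
                continue
            res = stats.ttest_ind(t[mask], t[~mask], equal_var=equal_var)
            if np.isfinite(res.statistic):
                best = max(best, float(res.statistic) ** 2)
    return best


def naive_all_pairs(values, t, cfg) -> np.ndarray:
    m = values.shape[1]
    out = []
    for i in range(m - 1):
        for j in range(i + 1, m):
            out.append(naive_pair_f(values[:, i], values[:, j], t, cfg))
    return np.array(out)


def naive_stepdown(observed, perm) -> np.ndarray:
    """Westfall-Young step-down maxT by explicit successive maxima."""
    P, B = perm.shape
    order = sorted(range(P), key=lambda k: -observed[k])  # stable
    p_sorted = []
    for r in range(P):
        count = 0
        for b in range(B):
            mx = max(perm[order[s], b] for s in range(r, P))
            if mx >= observed[order[r]]:
                count += 1
        p_sorted.append((1 + count) / (B + 1))
    for r in range(1, P):
        p_sorted[r] = max(p_sorted[r], p_sorted[r - 1])
    adjusted = np.empty(P)
    for r, h in enumerate(order):
        adjusted[h] = p_sorted[r]
    return adjusted


def naive_single_step_top_p(observed, perm) -> float:
    """Single-step maxT p of the top-ranked hypothesis (+1 convention)."""
    top = max(observed)
    count = sum(1 for b in range(perm.shape[1]) if perm[:, b].max() >= top)
    return (1 + count) / (perm.shape[1] + 1)


def naive_mbmdr(values, t, perm_traits, cfg):
    """Full naive analysis: observed F per pair, permutation F matrix, adjusted p."""
    observed = naive_all_pairs(values, t, cfg)
    perm_F = np.column_stack([
        naive_all_pairs(values, perm_traits[:, b], cfg)
        for b in range(perm_traits.shape[1])
    ])
    return observed, perm_F, naive_stepdown(observed, perm_F)
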