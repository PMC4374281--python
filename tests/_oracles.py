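"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (string scanning, O(N^2) loops,
explicit recursion) and shares no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# feature oracle: string-scanning recomputation of the 20 features
# ---------------------------------------------------------------------------


def oracle_features(
    t_row: str,
    k_row: str,
    scores: list[float],
    target_ss: np.ndarray,  # (N,3) H,E,C
    target_burial: np.ndarray,  # (N,2) B,E
    template_ss: list[str],
    template_burial: list[str],
    n_target: int,
    I: int,
    J: int,
    d_template: float,
) -> list[float]:
    """Recompute F1..F20 for a pair of aligned target positions I < J."""
    assert I < J
    ncol = len(t_row)
    assert len(k_row) == ncol

    # per-column target/template residue numbers (None for gaps)
    t_num, k_num = [], []
    ti = ki = 0
    for c in range(ncol):
        if t_row[c] == "-":
            t_num.append(None)
        else:
            ti += 1
            t_num.append(ti)
        if k_row[c] == "-":
            k_num.append(None)
        else:
            ki += 1
            k_num.append(ki)
    score_by_col = {}
    it = iter(scores)
    for c in range(ncol):
        if t_num[c] is not None and k_num[c] is not None:
            score_by_col[c] = next(it)

    cI = t_num.index(I)
    cJ = t_num.index(J)
    K = k_num[cI]
    L = k_num[cJ]
    cK = k_num.index(K)
    cL = k_num.index(L)

    f1 = abs(I - J)
    f2 = f1 / n_target
    f3 = d_template
    f4 = score_by_col[cI] * score_by_col[cJ]

    span = [score_by_col[c] for c in range(cI, cJ + 1) if c in score_by_col]
    f5 = sum(span) / len(span)

    f6 = sum(1 for c in range(cI + 1, cJ) if t_row[c] == "-")
    f7 = f6 / f1

    def recip(row: str, col: int) -> float:
        gaps = [c for c in range(ncol) if row[c] == "-"]
        if not gaps:
            return 0.0
        return 1.0 / min(abs(col - g) for g in gaps)

    f8 = recip(t_row, cI)
    f9 = recip(t_row, cJ)
    f10 = sum(1 for c in range(cK + 1, cL) if k_row[c] == "-")
    f11 = f10 / abs(K - L)
    f12 = recip(k_row, cK)
    f13 = recip(k_row, cL)

    ss_order = ["H", "E", "C"]
    acc_order = ["B", "E"]
    f14 = target_ss[I - 1][ss_order.index(template_ss[K - 1])]
    f15 = target_ss[J - 1][ss_order.index(template_ss[L - 1])]
    f16 = target_burial[I - 1][acc_order.index(template_burial[K - 1])]
    f17 = target_burial[J - 1][acc_order.index(template_burial[L - 1])]

    f18 = f4 * f14 * f15 * f16 * f17
    f19 = f18 / (1 + f6 + f10)
    f20 = f19 / (1 + f8 + f9 + f12 + f13)
    return [f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13, f14, f15, f16, f17, f18, f19, f20]


# ---------------------------------------------------------------------------
# restraint enumeration oracle: O(N^2) all-pairs with explicit loops
# ---------------------------------------------------------------------------

ORACLE_CUTOFFS = {"CACA": 14.5, "NO": 10.0, "MS": 8.0, "SS": 5.0}
ORACLE_ROLES = {"CACA": ("CA", "CA"), "NO": ("N", "O"), "MS": ("CA", "SC"), "SS": ("SC", "SC")}


def oracle_pair_counts(aligned_pairs, template_atoms) -> dict[str, int]:
    """Count restraint instances per category.

    *aligned_pairs* is a list of (target_index, template_index);
    *template_atoms* maps template_index -> {role: (x, y, z)}.
    """
    counts = {c: 0 for c in ORACLE_CUTOFFS}
    for cat, cutoff in ORACLE_CUTOFFS.items():
        r1, r2 = ORACLE_ROLES[cat]
        ordered = cat in ("NO", "MS")
        n = len(aligned_pairs)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if not ordered and i > j:
                    continue
                _, ki = aligned_pairs[i]
                _, kj = aligned_pairs[j]
                a = template_atoms.get(ki, {}).get(r1)
                b = template_atoms.get(kj, {}).get(r2)
                if a is None or b is None:
                    continue
                if math.dist(a, b) < cutoff:
                    counts[cat] += 1
    return counts


# ---------------------------------------------------------------------------
# exhaustive-search CART oracle (exact rational arithmetic)
# ---------------------------------------------------------------------------

from fractions import Fraction


def _exact_ssd(vals) -> Fraction:
    """Sum of squared deviations, exactly: sum(y^2) - (sum y)^2 / n."""
    s = sum(vals, Fraction(0))
    s2 = sum((v * v for v in vals), Fraction(0))
    return s2 - s * s / len(vals)


def _oracle_best_split(X: np.ndarray, y: np.ndarray):
    """Best (gain, feature, threshold); gains compared exactly.

    Ties break toward the lowest feature index then the lowest threshold
    (strictly-greater comparison while scanning in that order).
    """
    yf = [Fraction(float(v)) for v in y]
    parent = _exact_ssd(yf)
    best = None
    for f in range(X.shape[1]):
        vals = sorted(set(X[:, f].tolist()))
        for a, b in zip(vals, vals[1:]):
            thr = (a + b) / 2.0
            if thr >= b:
                thr = a
            left = X[:, f] <= thr
            if not left.any() or left.all():
                continue
            yl = [v for v, m in zip(yf, left) if m]
            yr = [v for v, m in zip(yf, left) if not m]
            gain = parent - _exact_ssd(yl) - _exact_ssd(yr)
            if best is None or gain > best[0]:
                best = (gain, f, thr)
    if best is None or best[0] <= 0:
        return None
    return best


def oracle_cart_predict(
    X: np.ndarray, y: np.ndarray, X_test: np.ndarray, min_leaf: int = 1
) -> np.ndarray:
    """Fully-grown CART regression predictions by explicit recursion."""

    def fit(idx):
        yn = y[idx]
        if len(idx) <= min_leaf or np.ptp(yn) == 0:
            return float(yn.mean())
        split = _oracle_best_split(X[idx], yn)
        if split is None:
            return float(yn.mean())
        _, f, thr = split
        mask = X[idx, f] <= thr
        return (f, thr, fit(idx[mask]), fit(idx[~mask]))

    tree = fit(np.arange(len(y)))

    def predict_one(node, x):
        while isinstance(node, tuple):
            f, thr, lo, hi = node
            node = lo if x[f] <= thr else hi
        return node

    return np.array([predict_one(tree, x) for x in X_test])
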