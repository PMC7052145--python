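"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive (explicit Python loops, O(N^2) or
worse) and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_runs_along(mat, di: int, dj: int, starts) -> list[int]:
    """Lengths of maximal 1-runs along direction (di, dj) from each start."""
    n_r, n_c = mat.shape
    lengths = []
    for i0, j0 in starts:
        run = 0
        i, j = i0, j0
        while 0 <= i < n_r and 0 <= j < n_c:
            if mat[i, j]:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
            i += di
            j += dj
        if run:
            lengths.append(run)
    return lengths


def brute_diagonal_lengths(mat) -> list[int]:
    mat = np.asarray(mat, dtype=bool)
    n_r, n_c = mat.shape
    starts = [(i, 0) for i in range(n_r)] + [(0, j) for j in range(1, n_c)]
    return brute_runs_along(mat, 1, 1, starts)


def brute_vertical_lengths(mat) -> list[int]:
    mat = np.asarray(mat, dtype=bool)
    return brute_runs_along(mat, 1, 0, [(0, j) for j in range(mat.shape[1])])


def brute_crqa_metrics(mat, l_min=2, v_min=2, entropy_normalized=False):
    """Reference values for (rec, ent, lam, lmax) of a binary matrix."""
    mat = np.asarray(mat, dtype=bool)
    total = int(mat.sum())
    if total == 0:
        return 0.0, 0.0, 0.0, 0
    rec = total / mat.size

    diag = brute_diagonal_lengths(mat)
    lmax = max(diag) if diag else 0

    kept = [l for l in diag if l >= l_min]
    ent = 0.0
    if kept:
        counts = {}
        for l in kept:
            counts[l] = counts.get(l, 0) + 1
        n = sum(counts.values())
        ent = -sum((c / n) * math.log(c / n) for c in counts.values())
        if entropy_normalized:
            ent = ent / math.log(len(counts)) if len(counts) > 1 else 0.0

    vert = [l for l in brute_vertical_lengths(mat) if l >= v_min]
    lam = sum(vert) / total
    return rec, ent, lam, lmax


def brute_fnn_fractions(x, m_max, tau=1, r_tol=10.0, a_tol=2.0):
    """All-pairs false-nearest-neighbor fractions for m = 1..m_max."""
    x = np.asarray(x, dtype=float)
    sigma = x.std()
    if sigma == 0:
        return [0.0] * m_max
    fractions = []
    for m in range(1, m_max + 1):
        n_pts = len(x) - m * tau
        false = 0
        for i in range(n_pts):
            best_j, best_d = None, np.inf
            for j in range(n_pts):
                if j == i:
                    continue
                d = 0.0
                for k in range(m):
                    diff = x[i + k * tau] - x[j + k * tau]
                    d += diff * diff
                d = math.sqrt(d)
                if d < best_d:
                    best_d, best_j = d, j
            extra = abs(x[i + m * tau] - x[best_j + m * tau])
            if best_d > 0:
                ratio = extra / best_d
            else:
                ratio = 0.0 if extra == 0 else np.inf
            r_m1 = math.hypot(best_d, extra)
            if ratio > r_tol or r_m1 / sigma > a_tol:
                false += 1
        fractions.append(false / n_pts)
    return fractions


def brute_pearson(x, y):
    """Textbook two-pass Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    num = ((x - xm) * (y - ym)).sum()
    den = math.sqrt(((x - xm) ** 2).sum() * ((y - ym) ** 2).sum())
    return num / den
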