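"""Cross-recurrence plots and their line-structure (CRQA) metrics.

A cross-recurrence plot (CRP) marks cell (i, j) when the i-th embedded
state of one series lies within a threshold distance of the j-th state
of another.  Four statistics summarize its line structure:

``rec``
    recurrence rate, the fraction of recurrent cells;
``ent``
    Shannon entropy of the diagonal line-length distribution
    (complexity of the shared dynamics);
``lam``
    laminarity, the fraction of recurrent points on vertical lines
    (intermittent, slowly changing shared states);
``lmax``
    the longest diagonal line, i.e. the longest stretch during which
    the two trajectories track each other.

Distances default to the per-dimension RMS norm (Euclidean divided by
sqrt(m)), which keeps a single threshold meaningful across embedding
dimensions of z-scored series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import EmbeddedTrajectory

logger = logging.getLogger(__name__)


@dataclass
class RecurrencePlot:
    """Binary cross-recurrence matrix for an ordered pair of trajectories."""

    matrix: np.ndarray  # (N_a, N_b) bool; rows = first trajectory
    epsilon: float
    norm: str
    pair: tuple[str, str, str] = ("?", "?", "?")  # (id_a, id_b, segment)


@dataclass
class CRQAMetrics:
    rec: float  # recurrence rate in [0, 1]
    ent: float  # diagonal line-length entropy (nats; normalized optionally)
    lam: float  # laminarity in [0, 1]
    lmax: int   # longest diagonal line (samples)

    def as_dict(self) -> dict[str, float]:
        return {"rec": self.rec, "ent": self.ent,
                "lam": self.lam, "lmax": float(self.lmax)}


METRIC_NAMES = ("rec", "ent", "lam", "lmax")


def distance_matrix(
    a: EmbeddedTrajectory, b: EmbeddedTrajectory, norm: str = "rms"
) -> np.ndarray:
    if a.m != b.m or a.tau != b.tau:
        raise ValueError(
            f"mismatched embedding parameters: (m={a.m}, tau={a.tau}) vs "
            f"(m={b.m}, tau={b.tau})"
        )
    if norm == "rms":
        return cdist(a.points, b.points, metric="euclidean") / np.sqrt(a.m)
    if norm == "euclidean":
        return cdist(a.points, b.points, metric="euclidean")
    if norm == "max":
        return cdist(a.points, b.points, metric="chebyshev")
    raise ValueError(f"unknown norm {norm!r}")


def cross_recurrence(
    a: EmbeddedTrajectory,
    b: EmbeddedTrajectory,
    epsilon: float,
    norm: str = "rms",
    epsilon_mode: str = "absolute",
    pair: tuple[str, str, str] = ("?", "?", "?"),
) -> RecurrencePlot:
    """Threshold the pairwise distance matrix into a binary CRP.

    ``epsilon_mode='absolute'`` treats ``epsilon`` as a distance;
    ``'max_frac'`` as a fraction of the pair's maximal distance (the
    usual convention when a single cut-off such as 0.2 is quoted
    without units).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d = distance_matrix(a, b, norm)
    cut = epsilon * d.max() if epsilon_mode == "max_frac" else epsilon
    if epsilon_mode not in ("absolute", "max_frac"):
        raise ValueError(f"unknown epsilon_mode {epsilon_mode!r}")
    return RecurrencePlot(matrix=d <= cut, epsilon=epsilon,
                          norm=norm, pair=pair)


# ---------------------------------------------------------------------------
# line extraction

def _column_run_lengths(mat: np.ndarray) -> np.ndarray:
    """Lengths of all maximal runs of True along the columns of ``mat``."""
    if mat.size == 0 or not mat.any():
        return np.empty(0, dtype=np.int64)
    padded = np.zeros((mat.shape[0] + 1, mat.shape[1]), dtype=bool)
    padded[:-1] = mat
    flat = padded.ravel(order="F")
    idx = np.flatnonzero(flat)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    bounds = np.concatenate(([-1], breaks, [idx.size - 1]))
    return np.diff(bounds).astype(np.int64)


def _shear(mat: np.ndarray) -> np.ndarray:
    """Map diagonals of ``mat`` onto columns of a (R, R+C-1) array."""
    n_r, n_c = mat.shape
    out = np.zeros((n_r, n_r + n_c - 1), dtype=bool)
    cols = (n_r - 1 - np.arange(n_r))[:, None] + np.arange(n_c)[None, :]
    out[np.arange(n_r)[:, None], cols] = mat
    return out


def diagonal_line_lengths(matrix: np.ndarray) -> np.ndarray:
    """All maximal diagonal runs of 1s (every length, including 1)."""
    return _column_run_lengths(_shear(np.asarray(matrix, dtype=bool)))


def vertical_line_lengths(matrix: np.ndarray) -> np.ndarray:
    """All maximal vertical runs of 1s (every length, including 1)."""
    return _column_run_lengths(np.asarray(matrix, dtype=bool))


def horizontal_line_lengths(matrix: np.ndarray) -> np.ndarray:
    return _column_run_lengths(np.asarray(matrix, dtype=bool).T)


def _histogram(lengths: np.ndarray, min_len: int) -> dict[int, int]:
    kept = lengths[lengths >= min_len]
    vals, counts = np.unique(kept, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def diagonal_line_histogram(plot: RecurrencePlot, l_min: int = 2) -> dict[int, int]:
    """Counts of maximal diagonal runs of length >= ``l_min``."""
    if l_min < 2:
        raise ValueError("l_min must be >= 2")
    return _histogram(diagonal_line_lengths(plot.matrix), l_min)


def vertical_line_histogram(plot: RecurrencePlot, v_min: int = 2) -> dict[int, int]:
    """Counts of maximal vertical runs of length >= ``v_min``."""
    if v_min < 2:
        raise ValueError("v_min must be >= 2")
    return _histogram(vertical_line_lengths(plot.matrix), v_min)


# ---------------------------------------------------------------------------
# metrics

def _entropy(lengths: np.ndarray, l_min: int, normalized: bool) -> float:
    kept = lengths[lengths >= l_min]
    if kept.size == 0:
        return 0.0
    _, counts = np.unique(kept, return_counts=True)
    p = counts / counts.sum()
    ent = float(-(p * np.log(p)).sum())
    if normalized:
        return ent / np.log(len(p)) if len(p) > 1 else 0.0
    return ent


def crqa_metrics(
    plot: RecurrencePlot,
    l_min: int = 2,
    v_min: int = 2,
    entropy_normalized: bool = False,
) -> CRQAMetrics:
    """The four line-structure statistics of one recurrence plot.

    ``rec`` is reported as a fraction in [0, 1].  ``ent`` is the Shannon
    entropy (natural log) of the distribution of diagonal line lengths
    >= ``l_min``, divided by log of the number of distinct lengths when
    ``entropy_normalized`` (zero for <= 1 distinct length either way).
    ``lam`` is the fraction of recurrent points on vertical runs
    >= ``v_min``.  An empty plot scores zero on everything.
    """
    mat = np.asarray(plot.matrix, dtype=bool)
    total = int(mat.sum())
    if total == 0:
        return CRQAMetrics(rec=0.0, ent=0.0, lam=0.0, lmax=0)
    diag = diagonal_line_lengths(mat)
    vert = vertical_line_lengths(mat)
    return CRQAMetrics(
        rec=total / mat.size,
        ent=_entropy(diag, l_min, entropy_normalized),
        lam=float(vert[vert >= v_min].sum() / total),
        lmax=int(diag.max()) if diag.size else 0,
    )


def determinism(plot: RecurrencePlot, l_min: int = 2) -> float:
    """Fraction of recurrent points on diagonal lines >= ``l_min``.

    Provided for completeness; not part of the four-pipeline metrics.
    """
    mat = np.asarray(plot.matrix, dtype=bool)
    total = mat.sum()
    if total == 0:
        return 0.0
    diag = diagonal_line_lengths(mat)
    return float(diag[diag >= l_min].sum() / total)


# ---------------------------------------------------------------------------
# threshold selection

def select_threshold_pair(
    a: EmbeddedTrajectory,
    b: EmbeddedTrajectory,
    grid: np.ndarray,
    norm: str = "rms",
    mode: str = "diag_sd",
    l_min: int = 2,
) -> float:
    """Pick the grid threshold maximizing recurrence-state variability.

    ``diag_sd`` scores each candidate by the standard deviation of the
    diagonal line-length distribution (lines >= ``l_min``);
    ``matrix_sd`` by the SD of the binary matrix entries.  Ties go to
    the smallest threshold; if every candidate yields an empty plot the
    smallest grid value is returned with a warning.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    d = distance_matrix(a, b, norm)
    scores = np.empty(grid.size)
    any_recurrence = False
    for k, eps in enumerate(grid):
        mat = d <= eps
        if mat.any():
            any_recurrence = True
        if mode == "diag_sd":
            lengths = diagonal_line_lengths(mat)
            kept = lengths[lengths >= l_min]
            scores[k] = kept.std() if kept.size else 0.0
        elif mode == "matrix_sd":
            scores[k] = mat.std()
        else:
            raise ValueError(f"unknown threshold mode {mode!r}")
    if not any_recurrence:
        logger.warning(
            "no candidate threshold produced any recurrence; "
            "returning smallest grid value %.4g", grid[0],
        )
        return float(grid[0])
    return float(grid[np.argmax(scores)])  # argmax takes the first (smallest) tie


def select_threshold_global(pair_epsilons) -> float:
    """Study-level threshold: the mean of the per-pair selections."""
    eps = np.asarray(list(pair_epsilons), dtype=float)
    if eps.size == 0:
        raise ValueError("no per-pair thresholds supplied")
    return float(eps.mean())
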