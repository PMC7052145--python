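"""Time-delay embedding and false-nearest-neighbor dimension selection.

A scalar series x is embedded as points
``(x_i, x_{i+tau}, ..., x_{i+(m-1)tau})``.  The embedding dimension is
chosen per series by the false-nearest-neighbor (FNN) test — increase m
until the fraction of neighbors that separate when the next coordinate
is added stays below a cutoff — and the study-level dimension is the
maximum over all series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass
class EmbeddedTrajectory:
    """Delay-embedded phase-space points of one scalar series."""

    points: np.ndarray  # (n_points, m)
    m: int
    tau: int
    source_n: int

    def __post_init__(self) -> None:
        expected = self.source_n - (self.m - 1) * self.tau
        if self.points.shape != (expected, self.m):
            raise ValueError(
                f"embedding shape {self.points.shape} != ({expected}, {self.m})"
            )


def zscore(values: np.ndarray) -> np.ndarray:
    """Z-score a series; a constant series maps to all zeros."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def delay_embed(values: np.ndarray, m: int, tau: int = 1) -> EmbeddedTrajectory:
    """Embed a scalar series with dimension ``m`` and delay ``tau``."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    n_points = n - (m - 1) * tau
    if n_points < 1:
        raise ValueError(
            f"series of length {n} too short for m={m}, tau={tau}"
        )
    idx = np.arange(n_points)[:, None] + tau * np.arange(m)[None, :]
    return EmbeddedTrajectory(points=values[idx], m=m, tau=tau, source_n=n)


def fnn_fractions(
    values: np.ndarray,
    m_max: int = 15,
    tau: int = 1,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
) -> np.ndarray:
    """FNN fraction at m = 1..m_max (Kennel's test, both criteria).

    For each point's nearest neighbor in the m-dimensional embedding, the
    neighbor is *false* if adding the (m+1)-th coordinate either blows up
    the distance ratio beyond ``r_tol`` (criterion I) or moves the pair
    apart by more than ``a_tol`` attractor sizes (criterion II; this is
    what keeps the fraction high for noise).  Set ``a_tol`` to ``inf``
    to disable criterion II.
    """
    x = np.asarray(values, dtype=float)
    sigma = x.std()
    if sigma == 0:
        # all distances vanish at every m: no false neighbors anywhere
        return np.zeros(m_max)
    fractions = np.empty(m_max)
    for m in range(1, m_max + 1):
        n_pts = len(x) - m * tau  # points that also exist at dimension m+1
        if n_pts < 2:
            raise ValueError(
                f"series of length {len(x)} too short for FNN at m={m}"
            )
        emb = delay_embed(x, m, tau).points[:n_pts]
        tree = cKDTree(emb)
        dist, nn = tree.query(emb, k=2)
        r_m, j = dist[:, 1], nn[:, 1]
        extra = np.abs(x[np.arange(n_pts) + m * tau] - x[j + m * tau])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(r_m > 0, extra / np.where(r_m > 0, r_m, 1.0), np.inf)
        ratio[(r_m == 0) & (extra == 0)] = 0.0
        r_m1 = np.hypot(r_m, extra)
        false = (ratio > r_tol) | (r_m1 / sigma > a_tol)
        fractions[m - 1] = false.mean()
    return fractions


def fnn_dimension(
    values: np.ndarray,
    m_max: int = 15,
    tau: int = 1,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
    fnn_cutoff: float = 0.1,
) -> int:
    """Smallest m whose FNN fraction stays below ``fnn_cutoff``.

    "Consistently below" means at the candidate m and at every larger
    tested m up to ``m_max``.  If no dimension qualifies, returns
    ``m_max`` with a warning.
    """
    fractions = fnn_fractions(values, m_max=m_max, tau=tau,
                              r_tol=r_tol, a_tol=a_tol)
    below = fractions < fnn_cutoff
    # last index where the fraction is NOT below the cutoff
    above = np.flatnonzero(~below)
    if len(above) == 0:
        return 1
    if above[-1] == m_max - 1:
        logger.warning(
            "FNN fraction never settles below %.3g by m=%d (last fraction "
            "%.3g); returning m_max", fnn_cutoff, m_max, fractions[-1],
        )
        return m_max
    return int(above[-1]) + 2  # first m after the last excursion


def global_dimension(dims: dict[tuple[str, str], int] | list[int]) -> int:
    """Study-level embedding dimension: the maximum over all series."""
    values = list(dims.values()) if isinstance(dims, dict) else list(dims)
    if not values:
        raise ValueError("no per-series dimensions supplied")
    return int(max(values))
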