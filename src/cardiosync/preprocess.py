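"""Tachogram to evenly sampled RR series, per participant and segment.

RR intervals are anchored at the second peak of each interval, passed
through a natural cubic spline, and evaluated at ``fs`` = 4 Hz inside
each segment window.  Every analyzed series is trimmed symmetrically to
exactly ``n_target`` = 430 samples (the central 430 of the 480-point
two-minute grid), so that all series entering CRQA have equal length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .manifest import SEGMENTS, SessionManifest, Tachogram

logger = logging.getLogger(__name__)


@dataclass
class RRSeries:
    """Evenly resampled RR series for one participant x segment."""

    participant: str
    segment: str
    values: np.ndarray  # RR in seconds
    fs: float  # Hz

    @property
    def n(self) -> int:
        return len(self.values)

    def validate(self, n_target: int = 430) -> None:
        if self.n != n_target:
            raise ValueError(
                f"{self.participant}/{self.segment}: length {self.n} != {n_target}"
            )
        if not np.all(self.values > 0):
            raise ValueError(
                f"{self.participant}/{self.segment}: non-positive RR values"
            )


class InsufficientSupportError(ValueError):
    """A segment window falls outside the tachogram's time support."""


def tachogram_to_rr_pairs(tachogram: Tachogram) -> np.ndarray:
    """Return (time, RR) pairs, RR_i = t_{i+1} - t_i anchored at t_{i+1}.

    Shape (n_peaks - 1, 2).  Requires at least 3 R-peaks (fewer cannot
    support interpolation downstream).
    """
    t = np.asarray(tachogram.r_peak_times, dtype=float)
    if len(t) < 3:
        raise ValueError(
            f"participant {tachogram.participant!r}: need >= 3 R-peaks, "
            f"got {len(t)}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValueError(
            f"participant {tachogram.participant!r}: non-monotonic R-peak times"
        )
    rr = np.diff(t)
    return np.column_stack([t[1:], rr])


def resample_rr(
    pairs: np.ndarray,
    window: tuple[float, float],
    fs: float = 4.0,
    n_target: int = 430,
    participant: str = "?",
    segment: str = "?",
) -> RRSeries:
    """Cubic-spline resample (time, RR) pairs on an even grid in ``window``.

    The grid spans the half-open window at step 1/fs; the central
    ``n_target`` samples are kept.  The window (after trimming) must lie
    inside the pairs' time support.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
        raise ValueError("pairs must be an (n>=2, 2) array of (time, RR)")
    start, end = window
    n_grid = int(round((end - start) * fs))
    if n_grid < n_target:
        n_grid = n_target
    grid = start + np.arange(n_grid) / fs
    offset = (n_grid - n_target) // 2
    grid = grid[offset : offset + n_target]
    if offset:
        logger.debug(
            "%s/%s: trimming %d-sample grid symmetrically to %d samples",
            participant, segment, n_grid, n_target,
        )

    t, rr = pairs[:, 0], pairs[:, 1]
    if grid[0] < t[0] or grid[-1] > t[-1]:
        raise InsufficientSupportError(
            f"participant {participant!r}, segment {segment!r}: window "
            f"[{grid[0]:.2f}, {grid[-1]:.2f}] s outside RR support "
            f"[{t[0]:.2f}, {t[-1]:.2f}] s"
        )
    spline = CubicSpline(t, rr, bc_type="natural")
    return RRSeries(
        participant=participant, segment=segment,
        values=spline(grid), fs=fs,
    )


def extract_segments(
    manifest: SessionManifest,
    tachograms: list[Tachogram],
    fs: float = 4.0,
    n_target: int = 430,
    segments: tuple[str, ...] = SEGMENTS,
) -> dict[tuple[str, str], RRSeries]:
    """Resample every participant's analysis segments (all seven by default).

    A participant whose tachogram cannot support any one of the
    requested windows (or who has no tachogram) is excluded entirely —
    pairwise synchrony needs all segments — with a logged warning.
    """
    by_pid = {tg.participant: tg for tg in tachograms}
    out: dict[tuple[str, str], RRSeries] = {}
    for pid in manifest.participants:
        tg = by_pid.get(pid)
        if tg is None:
            logger.warning("participant %s: no tachogram; excluded", pid)
            continue
        try:
            pairs = tachogram_to_rr_pairs(tg)
            series = {
                label: resample_rr(
                    pairs, manifest.segments[pid][label],
                    fs=fs, n_target=n_target,
                    participant=pid, segment=label,
                )
                for label in segments
            }
        except (ValueError, KeyError) as exc:
            logger.warning("participant %s excluded: %s", pid, exc)
            continue
        for label, s in series.items():
            out[(pid, label)] = s
    return out
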