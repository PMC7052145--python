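"""Individual in-group and out-group synchrony by pairwise CRQA averaging.

Every participant is paired with their three quartet-mates (in-group)
and with three randomly drawn spectators from other quartets
(out-group, the control).  The per-pair CRQA metrics are averaged per
participant, segment and group type.  Out-group partners are drawn once
per run from a seed and reused across segments and for the
behavioral convergence scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crqa import (
    CRQAMetrics,
    _entropy,
    diagonal_line_lengths,
    distance_matrix,
    horizontal_line_lengths,
    vertical_line_lengths,
)
from .embedding import delay_embed, zscore
from .manifest import SessionManifest
from .preprocess import RRSeries

logger = logging.getLogger(__name__)


@dataclass
class Pairing:
    in_partners: tuple[str, str, str]
    out_partners: tuple[str, str, str]


@dataclass
class ParticipantSynchrony:
    """Mean CRQA metrics of one participant's three pairings."""

    participant: str
    segment: str
    group_type: str  # "in" | "out"
    metrics: CRQAMetrics
    pairing_ids: tuple[str, ...]


def build_pairings(
    manifest: SessionManifest, seed: int
) -> dict[str, Pairing]:
    """In-partners are the quartet-mates; out-partners a seeded draw.

    Out-partners are sampled uniformly without replacement from all
    participants outside the quartet.  Requires at least two quartets.
    """
    if len(manifest.quartets) < 2:
        raise ValueError("out-group pairing needs at least 2 quartets")
    rng = np.random.default_rng(seed)
    pairings: dict[str, Pairing] = {}
    for pid in sorted(manifest.participants):
        q = manifest.quartet_of[pid]
        mates = tuple(p for p in manifest.quartet_members(q) if p != pid)
        pool = sorted(p for p in manifest.participants
                      if manifest.quartet_of[p] != q)
        out = tuple(sorted(rng.choice(pool, size=3, replace=False)))
        pairings[pid] = Pairing(in_partners=mates, out_partners=out)
    return pairings


class _PairMetricsCache:
    """CRQA metrics per (unordered pair, segment), both orientations.

    rec, ent and lmax are orientation-invariant; lam of the transposed
    plot equals the horizontal-line laminarity of the original, so one
    distance matrix serves both ordered pairs.
    """

    def __init__(self, series: dict[tuple[str, str], RRSeries],
                 epsilon: float, m: int, tau: int, norm: str,
                 l_min: int, v_min: int, entropy_normalized: bool,
                 epsilon_mode: str = "absolute"):
        self.series = series
        self.epsilon = epsilon
        self.epsilon_mode = epsilon_mode
        self.m, self.tau, self.norm = m, tau, norm
        self.l_min, self.v_min = l_min, v_min
        self.entropy_normalized = entropy_normalized
        self._embeddings: dict[tuple[str, str], object] = {}
        self._metrics: dict[tuple[str, str, str], CRQAMetrics] = {}
        self._scales: dict[str, float] = {}

    def _embedding(self, pid: str, segment: str):
        key = (pid, segment)
        if key not in self._embeddings:
            rr = self.series[key]
            self._embeddings[key] = delay_embed(
                zscore(rr.values), self.m, self.tau
            )
        return self._embeddings[key]

    def _segment_scale(self, segment: str) -> float:
        """Dataset-level distance scale: the mean phase-space radius
        (largest distance from a trajectory's own centroid), averaged
        over all participants analyzed in the segment.

        One fixed cut per segment keeps in-group and out-group plots
        comparable; a per-pair adaptive cut would confound the contrast
        with each pair's own amplitude structure.
        """
        if segment not in self._scales:
            radii = []
            for (pid, seg) in self.series:
                if seg != segment:
                    continue
                pts = self._embedding(pid, segment).points
                centered = pts - pts.mean(axis=0)
                radius = np.sqrt((centered ** 2).sum(axis=1).max())
                if self.norm == "rms":
                    radius /= np.sqrt(self.m)
                radii.append(radius)
            self._scales[segment] = float(np.mean(radii))
        return self._scales[segment]

    def _cut(self, d: np.ndarray, segment: str) -> float:
        if self.epsilon_mode == "absolute":
            return self.epsilon
        if self.epsilon_mode == "max_frac":
            return self.epsilon * d.max()
        if self.epsilon_mode == "global_frac":
            return self.epsilon * self._segment_scale(segment)
        raise ValueError(f"unknown epsilon_mode {self.epsilon_mode!r}")

    def metrics(self, a: str, b: str, segment: str) -> CRQAMetrics:
        key = (a, b, segment)
        if key in self._metrics:
            return self._metrics[key]
        lo, hi = sorted((a, b))
        d = distance_matrix(
            self._embedding(lo, segment), self._embedding(hi, segment),
            self.norm,
        )
        mat = d <= self._cut(d, segment)
        total = int(mat.sum())
        if total == 0:
            forward = CRQAMetrics(0.0, 0.0, 0.0, 0)
            backward = forward
        else:
            diag = diagonal_line_lengths(mat)
            vert = vertical_line_lengths(mat)
            horiz = horizontal_line_lengths(mat)
            rec = total / mat.size
            ent = _entropy(diag, self.l_min, self.entropy_normalized)
            lmax = int(diag.max())
            lam_v = float(vert[vert >= self.v_min].sum() / total)
            lam_h = float(horiz[horiz >= self.v_min].sum() / total)
            forward = CRQAMetrics(rec, ent, lam_v, lmax)
            backward = CRQAMetrics(rec, ent, lam_h, lmax)
        self._metrics[(lo, hi, segment)] = forward
        self._metrics[(hi, lo, segment)] = backward
        return self._metrics[key]


def participant_synchrony(
    pairings: dict[str, Pairing],
    series: dict[tuple[str, str], RRSeries],
    epsilon: float,
    m: int,
    tau: int = 1,
    segments: tuple[str, ...] | None = None,
    norm: str = "rms",
    l_min: int = 2,
    v_min: int = 2,
    entropy_normalized: bool = False,
    epsilon_mode: str = "absolute",
) -> list[ParticipantSynchrony]:
    """Average CRQA metrics over each participant's three ordered pairs.

    Pairings whose partner series are missing are dropped with a
    warning; a participant x segment with fewer than two usable pairs is
    flagged and skipped.  Series are z-scored per segment before
    embedding.
    """
    if segments is None:
        segments = tuple(sorted({seg for (_, seg) in series}))
    cache = _PairMetricsCache(series, epsilon, m, tau, norm,
                              l_min, v_min, entropy_normalized,
                              epsilon_mode=epsilon_mode)
    out: list[ParticipantSynchrony] = []
    for pid in sorted(pairings):
        for segment in segments:
            if (pid, segment) not in series:
                continue
            for group_type, partners in (
                ("in", pairings[pid].in_partners),
                ("out", pairings[pid].out_partners),
            ):
                per_pair = []
                used = []
                for partner in partners:
                    if (partner, segment) not in series:
                        logger.warning(
                            "%s/%s: partner %s has no series; pairing dropped",
                            pid, segment, partner,
                        )
                        continue
                    per_pair.append(cache.metrics(pid, partner, segment))
                    used.append(partner)
                if len(per_pair) < 2:
                    logger.warning(
                        "%s/%s/%s-group: only %d usable pairing(s); flagged",
                        pid, segment, group_type, len(per_pair),
                    )
                    continue
                mean = CRQAMetrics(
                    rec=float(np.mean([p.rec for p in per_pair])),
                    ent=float(np.mean([p.ent for p in per_pair])),
                    lam=float(np.mean([p.lam for p in per_pair])),
                    lmax=float(np.mean([p.lmax for p in per_pair])),
                )
                out.append(
                    ParticipantSynchrony(
                        participant=pid, segment=segment,
                        group_type=group_type, metrics=mean,
                        pairing_ids=tuple(used),
                    )
                )
    return out


def synchrony_table(synchrony: list[ParticipantSynchrony]) -> pd.DataFrame:
    """Tidy long table: participant_id, segment, group_type, metric, value."""
    rows = [
        {"participant_id": s.participant, "segment": s.segment,
         "group_type": s.group_type, "metric": name, "value": value}
        for s in synchrony
        for name, value in s.metrics.as_dict().items()
    ]
    return pd.DataFrame(
        rows,
        columns=["participant_id", "segment", "group_type", "metric", "value"],
    )


def group_contrast(
    synchrony: list[ParticipantSynchrony],
    segments: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Descriptive per-metric summary: mean and SE per group type.

    Each participant contributes one value per metric (their mean over
    the selected segments).  SE is the standard error over participants,
    reported as missing for a single participant.
    """
    table = synchrony_table(synchrony)
    if segments is not None:
        table = table[table["segment"].isin(segments)]
        if table.empty:
            raise ValueError(f"no synchrony rows for segments {segments}")
    if table.empty:
        raise ValueError("no synchrony rows to summarize")
    if table["group_type"].nunique() < 2:
        raise ValueError("both group types are required for a contrast")
    per_participant = (
        table.groupby(["participant_id", "group_type", "metric"],
                      as_index=False)["value"].mean()
    )
    def _se(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
    summary = (
        per_participant.groupby(["group_type", "metric"])["value"]
        .agg(mean="mean", se=_se, n="count")
        .reset_index()
    )
    return summary.sort_values(["metric", "group_type"]).reset_index(drop=True)
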