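"""Rating-convergence scores and their correlation with synchrony.

A participant's convergence score for a rating item is the sum of
absolute differences between their rating and their three comparison
spectators' ratings, computed per monologue and averaged over the two
monologues.  Low scores mean high agreement; for 1-5 ratings and three
partners the score lies in [0, 12].

The scores (and, separately, the raw emotional-intensity ratings) are
correlated with the participant-level mean CRQA metrics over the
monologue segments, Pearson two-tailed, Bonferroni-corrected for the
four metrics (threshold 0.05 / 4 = 0.0125).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crqa import METRIC_NAMES
from .groups import Pairing, ParticipantSynchrony, synchrony_table
from .manifest import MONOLOGUE_SEGMENTS, RatingTable

logger = logging.getLogger(__name__)

DEFAULT_QUESTION = "emotional_intensity_performance"


@dataclass
class ConvergenceScore:
    participant: str
    group_type: str  # "in" | "out"
    score: float     # in [0, 12] for 1-5 ratings and 3 partners


@dataclass
class CorrelationResult:
    metric: str
    r: float          # NaN when undefined (zero variance)
    p_raw: float
    p_threshold: float
    n: int
    significant: bool


def convergence_score(
    ratings: RatingTable,
    participant: str,
    partners: tuple[str, str, str],
    question: str = DEFAULT_QUESTION,
    monologues: tuple[str, str] = ("AUG10", "NOV20"),
    group_type: str = "in",
) -> ConvergenceScore:
    """Sum of absolute rating differences to 3 partners, per monologue,
    averaged over the two monologues."""
    if len(partners) != 3:
        raise ValueError("exactly 3 comparison partners are required")
    per_monologue = []
    for mono in monologues:
        own = ratings.lookup(participant, mono, question)
        total = sum(
            abs(own - ratings.lookup(p, mono, question)) for p in partners
        )
        per_monologue.append(total)
    return ConvergenceScore(
        participant=participant,
        group_type=group_type,
        score=float(np.mean(per_monologue)),
    )


def convergence_scores(
    ratings: RatingTable,
    pairings: dict[str, Pairing],
    question: str = DEFAULT_QUESTION,
    monologues: tuple[str, str] = ("AUG10", "NOV20"),
) -> list[ConvergenceScore]:
    """In-group and out-group scores for every participant.

    Out-group scores reuse the same partner triples as the out-group
    CRQA pairing.
    """
    out = []
    for pid in sorted(pairings):
        for group_type, partners in (
            ("in", pairings[pid].in_partners),
            ("out", pairings[pid].out_partners),
        ):
            out.append(
                convergence_score(ratings, pid, partners, question,
                                  monologues, group_type)
            )
    return out


def _mean_metrics_over_monologues(
    synchrony: list[ParticipantSynchrony], group_type: str
) -> pd.DataFrame:
    """participant x metric means over the four monologue segments."""
    table = synchrony_table(synchrony)
    table = table[
        (table["group_type"] == group_type)
        & table["segment"].isin(MONOLOGUE_SEGMENTS)
    ]
    if table.empty:
        raise ValueError(
            f"no {group_type}-group synchrony rows on monologue segments"
        )
    return table.pivot_table(index="participant_id", columns="metric",
                             values="value", aggfunc="mean")


def _correlate(
    x_by_pid: pd.Series,
    metric_means: pd.DataFrame,
    n_tests: int,
) -> list[CorrelationResult]:
    joined = metric_means.join(x_by_pid.rename("x"), how="inner").dropna()
    n = len(joined)
    if n < 4:
        raise ValueError(f"need at least 4 joined participants, got {n}")
    threshold = 0.05 / n_tests
    results = []
    for metric in METRIC_NAMES:
        y = joined[metric].to_numpy(dtype=float)
        x = joined["x"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning(
                "correlation for metric %r undefined (zero variance); "
                "reported as missing", metric,
            )
            results.append(
                CorrelationResult(metric=metric, r=np.nan, p_raw=np.nan,
                                  p_threshold=threshold, n=n,
                                  significant=False)
            )
            continue
        r, p = stats.pearsonr(x, y)
        results.append(
            CorrelationResult(metric=metric, r=float(r), p_raw=float(p),
                              p_threshold=threshold, n=n,
                              significant=bool(p < threshold))
        )
    return results


def correlate_metrics(
    scores: list[ConvergenceScore],
    synchrony: list[ParticipantSynchrony],
    group_type: str = "in",
    n_tests: int = 4,
) -> list[CorrelationResult]:
    """Pearson correlations of convergence scores with the four metrics.

    Metrics are each participant's mean over both monologues' segments
    for the requested group type; the convergence scores must be of the
    same group type.
    """
    x = pd.Series(
        {s.participant: s.score for s in scores if s.group_type == group_type}
    )
    if x.empty:
        raise ValueError(f"no {group_type}-group convergence scores")
    return _correlate(x, _mean_metrics_over_monologues(synchrony, group_type),
                      n_tests)


def correlate_intensity(
    ratings: RatingTable,
    synchrony: list[ParticipantSynchrony],
    group_type: str = "in",
    question: str = DEFAULT_QUESTION,
    monologues: tuple[str, str] = ("AUG10", "NOV20"),
    n_tests: int = 4,
) -> list[CorrelationResult]:
    """Correlate each participant's mean intensity rating with synchrony."""
    pids = sorted({s.participant for s in synchrony
                   if s.group_type == group_type})
    x = pd.Series(
        {
            pid: np.mean([ratings.lookup(pid, mono, question)
                          for mono in monologues])
            for pid in pids
        }
    )
    return _correlate(x, _mean_metrics_over_monologues(synchrony, group_type),
                      n_tests)


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"metric": r.metric, "r": r.r, "p_raw": r.p_raw,
             "p_threshold": r.p_threshold, "n": r.n,
             "significant": r.significant}
            for r in results
        ]
    )
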