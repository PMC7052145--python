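"""Session structure: participants, quartets, segment windows, ratings.

A recording session consists of four spectators (a quartet) watching two
monologues, with three two-minute rest recordings (baseline before the
first monologue, rest1 and rest2 after each monologue).  The analysis
windows are the three rests plus the first and last two minutes (T1, T2)
of each monologue, giving seven segments per participant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: The seven analysis segments, in session order.
SEGMENTS = ("baseline", "m1_T1", "m1_T2", "rest1", "m2_T1", "m2_T2", "rest2")

#: Segments recorded while a monologue was playing.
MONOLOGUE_SEGMENTS = ("m1_T1", "m1_T2", "m2_T1", "m2_T2")

#: Segments recorded at rest.
REST_SEGMENTS = ("baseline", "rest1", "rest2")

#: The ten Likert items collected after the session.  The first one is the
#: headline emotional-intensity judgment used for convergence scoring.
RATING_QUESTIONS = (
    "emotional_intensity_performance",
    "emotional_intensity_text",
    "anger_intensity_performance",
    "anger_intensity_text",
    "fear_intensity_performance",
    "fear_intensity_text",
    "sadness_intensity_performance",
    "sadness_intensity_text",
    "emotional_involvement",
    "performance_quality",
)

QUARTET_SIZE = 4

# plausibility window for RR intervals (s) after artifact screening
RR_MIN_S = 0.25
RR_MAX_S = 3.0


class ManifestError(ValueError):
    """Raised when a session manifest violates its structural invariants."""


@dataclass
class SessionManifest:
    """Group membership and per-participant segment windows.

    Parameters
    ----------
    participants
        Participant identifiers, in canonical (sorted) order.
    quartet_of
        Map participant id -> quartet id.  Every quartet must contain
        exactly four participants.
    segments
        Map participant id -> {segment label -> (start_s, end_s)}.
        Windows are half-open ``[start, end)`` in seconds.
    monologue_order
        Map quartet id -> ordered pair of monologue labels, in the order
        the quartet watched them.
    """

    participants: list[str]
    quartet_of: dict[str, str]
    segments: dict[str, dict[str, tuple[float, float]]]
    monologue_order: dict[str, tuple[str, str]] = field(default_factory=dict)

    def quartet_members(self, quartet_id: str) -> list[str]:
        return sorted(p for p, q in self.quartet_of.items() if q == quartet_id)

    @property
    def quartets(self) -> list[str]:
        return sorted(set(self.quartet_of.values()))

    def validate(self) -> None:
        """Check structural invariants, raising :class:`ManifestError`.

        Overlapping T1/T2 windows of the same monologue (a performance
        shorter than four minutes) are legal and only logged, since both
        windows are still analyzed.
        """
        if not self.participants:
            raise ManifestError("manifest has no participants")
        if set(self.participants) != set(self.quartet_of):
            raise ManifestError("participants and quartet assignment disagree")
        for q in self.quartets:
            members = self.quartet_members(q)
            if len(members) != QUARTET_SIZE:
                raise ManifestError(
                    f"quartet {q!r} has {len(members)} members, expected {QUARTET_SIZE}"
                )
        for pid in self.participants:
            windows = self.segments.get(pid)
            if windows is None:
                raise ManifestError(f"no segment windows for participant {pid!r}")
            if set(windows) != set(SEGMENTS):
                raise ManifestError(
                    f"participant {pid!r}: segment labels {sorted(windows)} "
                    f"!= expected {sorted(SEGMENTS)}"
                )
            for label, (start, end) in windows.items():
                if end <= start:
                    raise ManifestError(
                        f"participant {pid!r} segment {label!r}: "
                        f"non-positive duration [{start}, {end})"
                    )
            for mono in ("m1", "m2"):
                t1 = windows[f"{mono}_T1"]
                t2 = windows[f"{mono}_T2"]
                if t2[0] < t1[1]:
                    logger.warning(
                        "participant %s: %s_T1 and %s_T2 overlap "
                        "(performance shorter than the two windows); "
                        "both windows are analyzed anyway",
                        pid, mono, mono,
                    )


@dataclass
class Tachogram:
    """R-peak time stamps for one participant over a whole session.

    ``r_peak_times`` must be strictly increasing; successive differences
    (RR intervals) are expected inside the plausibility window
    (0.25 s, 3 s) after artifact screening.
    """

    participant: str
    r_peak_times: "pd.Series | list[float]"

    def __post_init__(self) -> None:
        import numpy as np

        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)

    def validate(self) -> None:
        import numpy as np

        t = self.r_peak_times
        if t.ndim != 1 or len(t) < 2:
            raise ValueError(
                f"participant {self.participant!r}: need at least 2 R-peaks"
            )
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(
                f"participant {self.participant!r}: R-peak times are not "
                "strictly increasing"
            )
        bad = (dt <= RR_MIN_S) | (dt >= RR_MAX_S)
        if np.any(bad):
            logger.warning(
                "participant %s: %d RR interval(s) outside the plausibility "
                "window (%.2f, %.2f) s",
                self.participant, int(bad.sum()), RR_MIN_S, RR_MAX_S,
            )


@dataclass
class RatingTable:
    """Tidy 1-5 Likert ratings, one row per (participant, monologue, question)."""

    data: pd.DataFrame  # columns: participant_id, monologue, question, rating

    COLUMNS = ("participant_id", "monologue", "question", "rating")

    def validate(self) -> None:
        df = self.data
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"rating table lacks columns {sorted(missing)}")
        if len(df) and not df["rating"].isin([1, 2, 3, 4, 5]).all():
            bad = df.loc[~df["rating"].isin([1, 2, 3, 4, 5])].iloc[0]
            raise ValueError(
                f"rating outside 1-5 for participant {bad['participant_id']!r}, "
                f"monologue {bad['monologue']!r}, question {bad['question']!r}"
            )
        key = ["participant_id", "monologue", "question"]
        dup = df.duplicated(subset=key)
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise ValueError(
                "duplicate rating row for "
                f"({bad['participant_id']}, {bad['monologue']}, {bad['question']})"
            )

    def lookup(self, participant: str, monologue: str, question: str) -> int:
        """Return the single rating for a key, or raise ``KeyError``."""
        df = self.data
        m = (
            (df["participant_id"] == participant)
            & (df["monologue"] == monologue)
            & (df["question"] == question)
        )
        hit = df.loc[m, "rating"]
        if len(hit) != 1:
            raise KeyError(
                f"missing rating for participant {participant!r}, "
                f"monologue {monologue!r}, question {question!r}"
            )
        return int(hit.iloc[0])
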