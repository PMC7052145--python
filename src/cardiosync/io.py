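"""CSV readers and writers for tachograms, manifests, ratings and metrics.

All formats are plain CSV with a header row.  Times are seconds as
floats; floats round-trip to 12 significant digits, integers exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .manifest import RatingTable, SessionManifest, Tachogram

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


def read_tachograms(path: str | Path) -> list[Tachogram]:
    """Read R-peak times, one :class:`Tachogram` per participant.

    The file must have columns ``participant_id, r_peak_time_s``.
    Malformed rows are rejected with row-numbered diagnostics;
    non-monotonic times within a participant are a hard error.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("tachogram file %s is empty", path)
        return []
    _require_columns(df, ("participant_id", "r_peak_time_s"), path)

    times = pd.to_numeric(df["r_peak_time_s"], errors="coerce")
    bad = times.isna() | ~np.isfinite(times)
    if bad.any():
        rows = [i + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ValueError(
            f"{path}: non-numeric r_peak_time_s at file row(s) {rows}"
        )
    df = df.assign(r_peak_time_s=times)

    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        t = grp["r_peak_time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"{path}: R-peak times for participant {pid!r} are not "
                "strictly increasing"
            )
        out.append(Tachogram(participant=str(pid), r_peak_times=t))
    return out


def write_tachograms(tachograms: list[Tachogram], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"participant_id": tg.participant, "r_peak_time_s": tg.r_peak_times}
        )
        for tg in sorted(tachograms, key=lambda tg: tg.participant)
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["participant_id", "r_peak_time_s"])
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_ratings(path: str | Path) -> RatingTable:
    """Read a tidy Likert rating table and validate its invariants."""
    df = pd.read_csv(path)
    _require_columns(df, RatingTable.COLUMNS, path)
    df = df.astype({"rating": int}, errors="raise")
    table = RatingTable(data=df.reset_index(drop=True))
    table.validate()
    return table


def write_ratings(table: RatingTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_manifest(path: str | Path) -> SessionManifest:
    """Read a session manifest from its flat CSV form.

    Columns: ``participant_id, quartet_id, segment, start_s, end_s,
    monologue1, monologue2`` (monologue order repeated on every row of a
    quartet).
    """
    df = pd.read_csv(path)
    _require_columns(
        df,
        ("participant_id", "quartet_id", "segment", "start_s", "end_s",
         "monologue1", "monologue2"),
        path,
    )
    participants = sorted(df["participant_id"].astype(str).unique())
    quartet_of: dict[str, str] = {}
    segments: dict[str, dict[str, tuple[float, float]]] = {}
    monologue_order: dict[str, tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        pid = str(row.participant_id)
        quartet_of[pid] = str(row.quartet_id)
        segments.setdefault(pid, {})[str(row.segment)] = (
            float(row.start_s), float(row.end_s)
        )
        monologue_order[str(row.quartet_id)] = (
            str(row.monologue1), str(row.monologue2)
        )
    manifest = SessionManifest(
        participants=participants,
        quartet_of=quartet_of,
        segments=segments,
        monologue_order=monologue_order,
    )
    manifest.validate()
    return manifest


def write_manifest(manifest: SessionManifest, path: str | Path) -> None:
    rows = []
    for pid in sorted(manifest.participants):
        q = manifest.quartet_of[pid]
        m1, m2 = manifest.monologue_order.get(q, ("m1", "m2"))
        for label in sorted(manifest.segments[pid]):
            start, end = manifest.segments[pid][label]
            rows.append(
                {
                    "participant_id": pid,
                    "quartet_id": q,
                    "segment": label,
                    "start_s": start,
                    "end_s": end,
                    "monologue1": m1,
                    "monologue2": m2,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_metrics_table(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy metrics table.

    Expected columns: ``participant_id, segment, group_type, metric,
    value`` — one row per participant x segment x group type x metric.
    An empty frame yields a header-only file.
    """
    cols = ["participant_id", "segment", "group_type", "metric", "value"]
    if metrics.empty:
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return
    missing = set(cols) - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns {sorted(missing)}")
    metrics[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ("participant_id", "segment", "group_type", "metric", "value"), path
    )
    return df


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
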