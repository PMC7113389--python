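"""Readers and writers for the pipeline's plain-text formats.

All formats are UTF-8 text with '.' decimals and a mandatory header row:
fixation reports and interest areas as TSV, features and ratings as CSV.
Fixation-report column names can be remapped so exports from tracker
software (e.g. Data-Viewer-style fixation reports) load without editing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .gaze import Fixation, InterestArea

logger = logging.getLogger(__name__)

__all__ = [
    "read_fixation_report", "write_fixation_report",
    "read_interest_areas", "write_interest_areas",
    "read_ratings", "write_ratings",
    "read_features", "write_features",
]

FIXATION_COLUMNS = ["participant", "session", "sonnet", "fix_index",
                    "x", "y", "duration_ms"]


def read_fixation_report(
    path, column_map: Mapping[str, str] | None = None
) -> list[Fixation]:
    """Load a TSV fixation report into validated, ordered records.

    ``column_map`` maps our canonical names to the file's column names,
    e.g. ``{"participant": "RECORDING_SESSION_LABEL", ...}``. Rows with a
    non-numeric duration or position are rejected and counted in the log;
    a missing mapped column is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty fixation report")
    colmap = {c: c for c in FIXATION_COLUMNS}
    if column_map:
        colmap.update(column_map)
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    records: list[Fixation] = []
    rejected = 0
    for i, row in df.iterrows():
        try:
            records.append(
                Fixation(
                    participant_id=str(row[colmap["participant"]]),
                    session=str(row[colmap["session"]]),
                    sonnet_id=str(row[colmap["sonnet"]]),
                    order_index=int(row[colmap["fix_index"]]),
                    x=float(row[colmap["x"]]),
                    y=float(row[colmap["y"]]),
                    duration=float(row[colmap["duration_ms"]]),
                )
            )
        except (TypeError, ValueError) as exc:
            rejected += 1
            logger.warning("%s row %d rejected: %s", path, i + 2, exc)
    if rejected:
        logger.info("%s: %d malformed rows rejected", path, rejected)
    records.sort(key=lambda f: (f.participant_id, f.session, f.sonnet_id,
                                f.order_index))
    return records


def write_fixation_report(fixations: Sequence[Fixation], path) -> None:
    df = pd.DataFrame(
        {
            "participant": [f.participant_id for f in fixations],
            "session": [f.session for f in fixations],
            "sonnet": [f.sonnet_id for f in fixations],
            "fix_index": [f.order_index for f in fixations],
            "x": [f.x for f in fixations],
            "y": [f.y for f in fixations],
            "duration_ms": [f.duration for f in fixations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_interest_areas(path) -> list[InterestArea]:
    df = pd.read_csv(path, sep="\t")
    required = ["sonnet", "line_no", "word_no", "x1", "y1", "x2", "y2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        InterestArea(str(r.sonnet), int(r.line_no), int(r.word_no),
                     float(r.x1), float(r.y1), float(r.x2), float(r.y2))
        for r in df.itertuples()
    ]


def write_interest_areas(areas: Sequence[InterestArea], path) -> None:
    df = pd.DataFrame(
        {
            "sonnet": [a.sonnet_id for a in areas],
            "line_no": [a.line_no for a in areas],
            "word_no": [a.word_no for a in areas],
            "x1": [a.x1 for a in areas],
            "y1": [a.y1 for a in areas],
            "x2": [a.x2 for a in areas],
            "y2": [a.y2 for a in areas],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["participant_id", "sonnet_id", "session",
                "willingness", "appreciation", "topic_correct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for q in ("willingness", "appreciation"):
        bad = df[(df[q] < 1) | (df[q] > 5)]
        if not bad.empty:
            raise ValueError(f"{path}: {q} outside the 1..5 scale in rows "
                             f"{list(bad.index)}")
    df["topic_correct"] = df["topic_correct"].astype(bool)
    dup = df.duplicated(subset=["participant_id", "sonnet_id", "session"])
    if dup.any():
        raise ValueError(f"{path}: duplicate participant x sonnet x session rows")
    return df


def write_ratings(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["sonnet_id"] = df["sonnet_id"].astype(str)
    return df


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
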