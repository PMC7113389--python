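"""Word-level eye-tracking measures from raw fixation sequences.

Maps fixations to word interest areas, segments each word's scanpath into
a first pass and later regressions, and derives the standard word-level
measures:

- FFD  first fixation duration: duration of the first fixation on a word
- GD   gaze duration: summed fixations on the word during its first pass
- RT   regression time: summed fixations on the word after the first pass
- TRT  total reading time: GD + RT
- fixation probability: share of participants who fixated the word at all

A word's first pass is the maximal run of consecutive fixations on the
word that starts at its first fixation; the run ends at the first fixation
on any other word. Refixations after leaving and returning count wholly to
RT. Skipped words are emitted with ``fixated=False`` and missing durations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Fixation",
    "InterestArea",
    "WordMeasures",
    "assign_fixations",
    "compute_word_measures",
    "aggregate_measures",
    "skipping_rate",
    "measures_long_table",
    "MEASURE_COLUMNS",
]

WordKey = tuple[str, int, int]  # (sonnet_id, line_no, word_no)

MEASURE_COLUMNS = ["ffd", "gd", "rt", "trt", "fixation_probability"]


@dataclass(frozen=True)
class Fixation:
    """One gaze event: screen position plus duration, in temporal order."""

    participant_id: str
    session: str  # "first" | "last"
    sonnet_id: str
    order_index: int
    x: float
    y: float
    duration: float  # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"non-positive fixation duration {self.duration}")
        if self.session not in ("first", "last"):
            raise ValueError(f"session must be 'first' or 'last', got {self.session!r}")


@dataclass(frozen=True)
class InterestArea:
    """Screen rectangle owned by exactly one word token."""

    sonnet_id: str
    line_no: int
    word_no: int
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box for {self.key}")

    @property
    def key(self) -> WordKey:
        return (self.sonnet_id, self.line_no, self.word_no)

    def contains(self, x: float, y: float, slack_px: float = 0.0) -> bool:
        return (
            self.x1 <= x < self.x2
            and (self.y1 - slack_px) <= y < (self.y2 + slack_px)
        )


@dataclass
class WordMeasures:
    """The five measures for one participant x word x session."""

    participant_id: str
    session: str
    sonnet_id: str
    line_no: int
    word_no: int
    fixated: bool
    ffd: float | None = None
    gd: float | None = None
    rt: float | None = None
    trt: float | None = None

    @property
    def key(self) -> WordKey:
        return (self.sonnet_id, self.line_no, self.word_no)


def _check_no_overlap(areas: Sequence[InterestArea]) -> None:
    by_sonnet: dict[str, list[InterestArea]] = {}
    for a in areas:
        by_sonnet.setdefault(a.sonnet_id, []).append(a)
    for sid, boxes in by_sonnet.items():
        for i, a in enumerate(boxes):
            for b in boxes[i + 1 :]:
                if (
                    a.x1 < b.x2
                    and b.x1 < a.x2
                    and a.y1 < b.y2
                    and b.y1 < a.y2
                ):
                    raise ValueError(
                        f"overlapping interest areas in sonnet {sid}: {a.key} / {b.key}"
                    )


def assign_fixations(
    fixations: Sequence[Fixation],
    interest_areas: Sequence[InterestArea],
    slack_px: float = 0.0,
) -> list[tuple[Fixation, WordKey | None]]:
    """Map each fixation to the word whose box contains it, or None.

    Boxes may be expanded vertically by ``slack_px`` to absorb drift
    between lines; when the slack makes more than one box eligible, the
    vertically nearest box wins. Fixations outside all (expanded) boxes
    map to None and are ignored downstream.
    """
    _check_no_overlap(interest_areas)
    by_sonnet: dict[str, list[InterestArea]] = {}
    for a in interest_areas:
        by_sonnet.setdefault(a.sonnet_id, []).append(a)

    out: list[tuple[Fixation, WordKey | None]] = []
    last_order: dict[tuple[str, str, str], int] = {}
    for fix in fixations:
        trial = (fix.participant_id, fix.session, fix.sonnet_id)
        if trial in last_order and fix.order_index <= last_order[trial]:
            raise ValueError(
                f"order_index not strictly increasing within trial {trial}"
            )
        last_order[trial] = fix.order_index
        candidates = [
            a
            for a in by_sonnet.get(fix.sonnet_id, ())
            if a.contains(fix.x, fix.y, slack_px)
        ]
        if not candidates:
            out.append((fix, None))
        elif len(candidates) == 1:
            out.append((fix, candidates[0].key))
        else:
            # slack made several boxes eligible: vertically nearest center wins
            best = min(candidates, key=lambda a: abs((a.y1 + a.y2) / 2 - fix.y))
            out.append((fix, best.key))
    return out


def compute_word_measures(
    assigned: Sequence[tuple[Fixation, WordKey | None]],
    all_word_keys: Iterable[WordKey] = (),
) -> list[WordMeasures]:
    """Derive FFD/GD/RT/TRT for one participant x session scanpath.

    ``assigned`` is the output of :func:`assign_fixations` for a single
    participant and session (off-word fixations allowed; they end first
    passes like any other-word fixation would not — they are simply
    ignored). Words listed in ``all_word_keys`` but never fixated are
    emitted with ``fixated=False``.
    """
    if not assigned:
        raise ValueError("empty fixation sequence")
    participant = assigned[0][0].participant_id
    session = assigned[0][0].session
    for fix, _ in assigned:
        if fix.participant_id != participant or fix.session != session:
            raise ValueError("assigned sequence mixes participants or sessions")

    # keep only on-word fixations, in temporal order; off-word gaze does not
    # terminate a first pass (standard convention: the pass ends at the first
    # fixation on ANY OTHER WORD)
    path = [(key, fix.duration) for fix, key in assigned if key is not None]

    first_pass_end: dict[WordKey, int] = {}
    measures: dict[WordKey, WordMeasures] = {}
    for idx, (key, dur) in enumerate(path):
        if key not in measures:
            m = WordMeasures(
                participant_id=participant,
                session=session,
                sonnet_id=key[0],
                line_no=key[1],
                word_no=key[2],
                fixated=True,
                ffd=dur,
                gd=dur,
                rt=0.0,
            )
            measures[key] = m
            first_pass_end[key] = idx  # index of last fixation in the pass so far
        else:
            m = measures[key]
            if first_pass_end[key] == idx - 1 and m.rt == 0.0 and _still_first_pass(
                path, key, idx
            ):
                m.gd += dur
                first_pass_end[key] = idx
            else:
                m.rt += dur
    for m in measures.values():
        m.trt = m.gd + m.rt

    for key in all_word_keys:
        if key not in measures:
            measures[key] = WordMeasures(
                participant_id=participant,
                session=session,
                sonnet_id=key[0],
                line_no=key[1],
                word_no=key[2],
                fixated=False,
            )
    return sorted(measures.values(), key=lambda m: m.key)


def _still_first_pass(path, key, idx) -> bool:
    """True if no other word has been fixated between the first fixation on
    ``key`` and position ``idx``."""
    start = next(i for i, (k, _) in enumerate(path) if k == key)
    return all(path[i][0] == key for i in range(start, idx))


def aggregate_measures(
    word_measures: Iterable[WordMeasures],
    n_participants: int | None = None,
) -> pd.DataFrame:
    """Average measures over participants, per word x session.

    Duration means use fixating participants only (skips are missing
    values, not zeros). ``fixation_probability`` is the share of
    participants who fixated the word; the denominator is the number of
    participants contributing records for that sonnet x session (or the
    explicit ``n_participants`` override).
    """
    rows = [
        {
            "participant_id": m.participant_id,
            "session": m.session,
            "sonnet_id": m.sonnet_id,
            "line_no": m.line_no,
            "word_no": m.word_no,
            "fixated": m.fixated,
            "ffd": m.ffd,
            "gd": m.gd,
            "rt": m.rt,
            "trt": m.trt,
        }
        for m in word_measures
    ]
    if not rows:
        raise ValueError("no word measures to aggregate")
    df = pd.DataFrame(rows)

    group_cols = ["sonnet_id", "line_no", "word_no", "session"]
    fixated = df[df["fixated"]]
    means = fixated.groupby(group_cols)[["ffd", "gd", "rt", "trt"]].mean()

    if n_participants is None:
        denom = df.groupby(["sonnet_id", "session"])["participant_id"].nunique()
        denom_of = lambda sid, ses: denom.loc[(sid, ses)]  # noqa: E731
    else:
        denom_of = lambda sid, ses: n_participants  # noqa: E731

    counts = df.groupby(group_cols)["fixated"].sum()
    out = counts.rename("n_fixating").to_frame()
    out["n_participants"] = [
        denom_of(sid, ses) for (sid, _ln, _wn, ses) in out.index
    ]
    out["fixation_probability"] = out["n_fixating"] / out["n_participants"]
    out = out.join(means)
    return out.reset_index().sort_values(["session", "sonnet_id", "line_no", "word_no"],
                                         ignore_index=True)


def skipping_rate(word_measures: Iterable[WordMeasures]) -> dict[str, float]:
    """Share of participant-words skipped, per session."""
    counts: dict[str, list[int]] = {}
    for m in word_measures:
        tot_skip = counts.setdefault(m.session, [0, 0])
        tot_skip[0] += 1
        tot_skip[1] += 0 if m.fixated else 1
    return {ses: skip / tot for ses, (tot, skip) in counts.items()}


def measures_long_table(
    aggregated: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Join aggregated measures with the per-word feature table.

    One row per word per session, carrying the nine predictors and the
    five responses. Raises if any word key fails to match.
    """
    if features.empty:
        raise ValueError("empty feature table")
    if aggregated.empty:
        raise ValueError("empty measures table")
    key = ["sonnet_id", "line_no", "word_no"]
    feat = features.copy()
    feat["sonnet_id"] = feat["sonnet_id"].astype(str)
    agg = aggregated.copy()
    agg["sonnet_id"] = agg["sonnet_id"].astype(str)
    merged = agg.merge(feat, on=key, how="outer", indicator=True, validate="m:1")
    bad = merged[merged["_merge"] != "both"]
    if not bad.empty:
        missing = bad[key + ["_merge"]].drop_duplicates().to_dict("records")
        raise ValueError(f"unmatched word keys in join: {missing}")
    merged = merged.drop(columns="_merge")
    order = ["session", "sonnet_id", "line_no", "word_no"]
    return merged.sort_values(order, ignore_index=True)
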