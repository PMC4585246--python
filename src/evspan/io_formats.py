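"""External formats and clock synchronization.

The pipeline ingests tabular fixation reports (TSV/CSV), Praat TextGrid
word tiers in audio-clock seconds, and a trigger-sync table linking the
audio clock to the eye-tracker clock.  Word boundary times are converted
to tracker milliseconds by an affine shift: the tracker timestamp of the
recording-start trigger plus the sound card's fixed output latency
(5 ms by default).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from . import textgrid as tg

__all__ = [
    "FixationRecord",
    "TriggerSync",
    "WordInterval",
    "TrialFixations",
    "read_fixation_report",
    "read_textgrid_words",
    "write_words_textgrid",
    "sync_to_tracker",
    "write_evs_table",
    "read_sync_table",
    "write_sync_table",
]

FIXATION_COLUMNS = ["subject_id", "trial_id", "sentence_id", "t_on", "t_off", "x_px", "blink"]

#: fixed audio output delay of the recording path, in ms
DEFAULT_AUDIO_LATENCY_MS = 5.0


@dataclass(frozen=True)
class FixationRecord:
    """One fixation of a fixation report, in tracker milliseconds."""

    subject_id: str
    trial_id: str
    sentence_id: str
    t_on: float
    t_off: float
    x_px: float
    blink: bool = False

    def __post_init__(self) -> None:
        if self.t_off <= self.t_on:
            raise ValueError(f"fixation with t_off {self.t_off} <= t_on {self.t_on}")


@dataclass(frozen=True)
class TriggerSync:
    """Tracker timestamps of the audio recording start/end triggers."""

    audio_start_tracker_ms: float
    audio_end_tracker_ms: float
    audio_latency_ms: float = DEFAULT_AUDIO_LATENCY_MS

    def __post_init__(self) -> None:
        if self.audio_end_tracker_ms <= self.audio_start_tracker_ms:
            raise ValueError("audio end trigger before start trigger")
        if self.audio_latency_ms < 0:
            raise ValueError("negative audio latency")


@dataclass(frozen=True)
class WordInterval:
    """An articulated word's time interval, tagged with its clock."""

    word_index: int
    t_on_ms: float
    t_off_ms: float
    clock: str = "audio"  # "audio" or "tracker"
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_off_ms <= self.t_on_ms:
            raise ValueError(
                f"word interval with t_off {self.t_off_ms} <= t_on {self.t_on_ms}"
            )

    @property
    def duration_ms(self) -> float:
        return self.t_off_ms - self.t_on_ms


@dataclass
class TrialFixations:
    subject_id: str
    trial_id: str
    sentence_id: str
    fixations: list[FixationRecord]

    @property
    def has_blink(self) -> bool:
        return any(f.blink for f in self.fixations)


def read_fixation_report(
    source, dialect: str = "tsv"
) -> dict[tuple[str, str], TrialFixations]:
    """Read a fixation report and group it into time-sorted trials.

    ``source`` is a path or open text stream.  The header must name the
    columns ``subject_id, trial_id, sentence_id, t_on, t_off, x_px,
    blink``.  Returns a dict keyed by ``(subject_id, trial_id)``.

    Raises ``ValueError`` for missing columns, rows with
    ``t_off <= t_on`` (reported with 1-based data line numbers), or
    overlapping fixations within a trial.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(source, sep=sep, dtype={"subject_id": str, "trial_id": str,
                                             "sentence_id": str})
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixation report is missing columns: {missing}")
    bad = df.index[df["t_off"] <= df["t_on"]].tolist()
    if bad:
        lines = [i + 2 for i in bad]  # 1-based, after the header line
        raise ValueError(f"fixations with t_off <= t_on at lines {lines}")
    out: dict[tuple[str, str], TrialFixations] = {}
    for (subj, trial), g in df.groupby(["subject_id", "trial_id"], sort=False):
        g = g.sort_values("t_on", kind="stable")
        recs = [
            FixationRecord(
                subject_id=str(subj),
                trial_id=str(trial),
                sentence_id=str(r.sentence_id),
                t_on=float(r.t_on),
                t_off=float(r.t_off),
                x_px=float(r.x_px),
                blink=bool(r.blink),
            )
            for r in g.itertuples()
        ]
        overlaps = [
            (a, b) for a, b in zip(recs, recs[1:]) if b.t_on < a.t_off
        ]
        if overlaps:
            rows = [(a.t_on, a.t_off, b.t_on, b.t_off) for a, b in overlaps]
            raise ValueError(
                f"overlapping fixations in trial {(subj, trial)}: {rows}"
            )
        out[(str(subj), str(trial))] = TrialFixations(
            subject_id=str(subj),
            trial_id=str(trial),
            sentence_id=recs[0].sentence_id,
            fixations=recs,
        )
    return out


def read_textgrid_words(source, tier_name: str = "words") -> list[WordInterval]:
    """Read a word tier from a TextGrid into audio-clock WordIntervals.

    Empty-label intervals (pauses) are dropped; the remaining intervals
    are numbered ``0..n-1`` in time order and their boundary times
    converted from seconds to milliseconds.
    """
    grid = tg.read_textgrid(source)
    tier = grid.tier(tier_name)
    ivs = [iv for iv in tier.intervals if iv.label.strip() != ""]
    prev_end = None
    out = []
    for k, iv in enumerate(ivs):
        if prev_end is not None and iv.xmin < prev_end - 1e-9:
            raise ValueError(
                f"overlapping word intervals at {iv.xmin}s in tier {tier_name!r}"
            )
        prev_end = iv.xmax
        out.append(
            WordInterval(
                word_index=k,
                t_on_ms=iv.xmin * 1000.0,
                t_off_ms=iv.xmax * 1000.0,
                clock="audio",
                label=iv.label,
            )
        )
    return out


def write_words_textgrid(
    intervals: Sequence[WordInterval],
    stream,
    tier_name: str = "words",
    xmax_ms: float | None = None,
    fmt: str = "long",
) -> None:
    """Write audio-clock word intervals as a single-tier TextGrid."""
    if xmax_ms is None:
        xmax_ms = max((iv.t_off_ms for iv in intervals), default=1000.0)
    # pauses become empty-label fillers; words need non-empty labels so
    # the reader keeps them
    triples = [
        (iv.t_on_ms / 1000.0, iv.t_off_ms / 1000.0, iv.label or f"w{iv.word_index}")
        for iv in sorted(intervals, key=lambda iv: iv.t_on_ms)
    ]
    tier = tg.IntervalTier(
        name=tier_name,
        xmin=0.0,
        xmax=xmax_ms / 1000.0,
        intervals=tg.fill_gaps(triples, 0.0, xmax_ms / 1000.0),
    )
    grid = tg.TextGrid(xmin=0.0, xmax=xmax_ms / 1000.0, tiers=[tier])
    tg.write_textgrid(grid, stream, fmt=fmt)


def sync_to_tracker(
    intervals: Iterable[WordInterval], sync: TriggerSync, tolerance_ms: float = 1.0
) -> tuple[list[WordInterval], bool]:
    """Shift audio-clock word intervals onto the tracker clock.

    ``t_tracker = t_audio + audio_start_tracker_ms + audio_latency_ms``.
    Returns the shifted intervals and a warning flag that is set when a
    synced time exceeds the end trigger by more than ``tolerance_ms``
    (possible trigger drift).
    """
    shift = sync.audio_start_tracker_ms + sync.audio_latency_ms
    out = []
    warn = False
    for iv in intervals:
        if iv.clock != "audio":
            raise ValueError("sync_to_tracker expects audio-clock intervals")
        synced = replace(iv, t_on_ms=iv.t_on_ms + shift, t_off_ms=iv.t_off_ms + shift,
                         clock="tracker")
        if synced.t_off_ms > sync.audio_end_tracker_ms + tolerance_ms:
            warn = True
        out.append(synced)
    return out, warn


def write_evs_table(records: pd.DataFrame, stream) -> None:
    """Write an analysis table as TSV with stable column order and
    3-decimal floats."""
    records.to_csv(stream, sep="\t", index=False, float_format="%.3f")


def read_evs_table(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t")


SYNC_COLUMNS = [
    "subject_id",
    "trial_id",
    "sentence_id",
    "audio_start_tracker_ms",
    "audio_end_tracker_ms",
    "audio_latency_ms",
    "textgrid",
]


def write_sync_table(rows: pd.DataFrame, stream) -> None:
    rows.to_csv(stream, sep="\t", index=False)


def read_sync_table(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype={"subject_id": str, "trial_id": str,
                                              "sentence_id": str})
    missing = [c for c in SYNC_COLUMNS if c not in df.columns and c != "textgrid"]
    if missing:
        raise ValueError(f"sync table is missing columns: {missing}")
    return df
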