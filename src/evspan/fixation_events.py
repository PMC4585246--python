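"""First-pass parsing of fixation sequences into word-level reading measures.

First pass on word *w* is the maximal run of consecutive fixations on
*w* starting at the first fixation on *w*, provided no word beyond *w*
was fixated earlier.  From it derive the standard measures: FFD (first
fixation duration), SFD (single fixation duration, when first pass has
exactly one fixation), GD (gaze duration, sum of first-pass durations),
TVT (total viewing time, all fixations on the word), skipping,
refixation, and regressions in/out, plus the oculomotor covariates
(launch site, landing site, outgoing saccade amplitude) in letters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import FixationRecord
from .text_layout import SentenceLayout, gaze_to_char, locate_char

__all__ = [
    "Fixation",
    "WordGazeRecord",
    "EventSummary",
    "assign_words",
    "parse_first_pass",
    "apply_exclusions",
    "summarize_events",
    "records_to_frame",
]


@dataclass(frozen=True)
class Fixation:
    """A fixation with its character-coordinate and word assignment."""

    index: int
    t_on: float
    t_off: float
    char_coord: float
    word_index: int
    in_bounds: bool = True
    is_blink_adjacent: bool = False

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass
class WordGazeRecord:
    """Per-word first-pass measures for one trial.

    Durations are in ms (``nan`` when absent); spatial covariates in
    letters.  ``launch_site_letters`` is the distance from the previous
    fixation to the word's first letter (positive when launched from the
    left); ``landing_site_letters`` is the 1-based letter position of
    the first first-pass fixation within the word.
    """

    word_index: int
    ffd: float = math.nan
    sfd: float = math.nan
    gd: float = math.nan
    tvt: float = 0.0
    skipped_first_pass: bool = True
    refixated: bool = False
    regression_out: bool = False
    regression_in: bool = False
    launch_site_letters: float = math.nan
    landing_site_letters: float = math.nan
    outgoing_saccade_letters: float = math.nan
    first_pass_fix_indices: list[int] = field(default_factory=list)
    fp_on_ms: float = math.nan  # onset of the first first-pass fixation
    fp_off_ms: float = math.nan  # offset of the last first-pass fixation
    n_first_pass: int = 0
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class EventSummary:
    """Descriptive statistics over fixations and non-excluded words."""

    mean_fixation_duration: float
    sd_fixation_duration: float
    mean_ffd: float
    sd_ffd: float
    mean_sfd: float
    sd_sfd: float
    mean_gd: float
    sd_gd: float
    mean_tvt: float
    sd_tvt: float
    mean_saccade_length: float
    sd_saccade_length: float
    p_skip: float
    p_single_fixation: float
    p_refixation: float
    p_regression: float
    p_single_fixation_given_fixated: float
    p_refixation_given_fixated: float
    n_words: int
    n_fixations: int


def assign_words(
    fixations: list[FixationRecord], layout: SentenceLayout
) -> list[Fixation]:
    """Attach character coordinates and word indices to raw fixations."""
    out = []
    for i, f in enumerate(fixations):
        c = gaze_to_char(layout, f.x_px)
        w, in_bounds = locate_char(layout, c)
        out.append(
            Fixation(
                index=i,
                t_on=f.t_on,
                t_off=f.t_off,
                char_coord=c,
                word_index=w,
                in_bounds=in_bounds,
                is_blink_adjacent=f.blink,
            )
        )
    return out


def parse_first_pass(
    fixations: list[Fixation], n_words: int, layout: SentenceLayout | None = None
) -> list[WordGazeRecord]:
    """Apply the first-pass rules to a word-assigned fixation sequence.

    ``layout`` supplies word character spans for the spatial covariates;
    when omitted, launch/landing sites are left absent.
    """
    if fixations:
        wmax = max(f.word_index for f in fixations)
        if wmax >= n_words:
            raise ValueError(
                f"fixation on word {wmax} but sentence has {n_words} words"
            )
    words = [f.word_index for f in fixations]
    records = []
    for w in range(n_words):
        rec = WordGazeRecord(word_index=w)
        on_w = [i for i, x in enumerate(words) if x == w]
        rec.tvt = sum(fixations[i].duration for i in on_w)
        rec.regression_in = any(
            any(words[j] > w for j in range(i)) for i in on_w
        )
        run: list[int] = []
        if on_w:
            first = on_w[0]
            if not any(words[j] > w for j in range(first)):
                k = first
                while k < len(words) and words[k] == w:
                    run.append(k)
                    k += 1
        if run:
            rec.skipped_first_pass = False
            rec.first_pass_fix_indices = run
            rec.n_first_pass = len(run)
            rec.ffd = fixations[run[0]].duration
            rec.gd = sum(fixations[i].duration for i in run)
            if len(run) == 1:
                rec.sfd = rec.ffd
            rec.refixated = len(run) >= 2
            rec.fp_on_ms = fixations[run[0]].t_on
            rec.fp_off_ms = fixations[run[-1]].t_off
            nxt = run[-1] + 1
            if nxt < len(words):
                rec.regression_out = words[nxt] < w
            if layout is not None:
                tok = layout.tokens[w]
                first_fix = fixations[run[0]]
                rec.landing_site_letters = first_fix.char_coord - tok.char_start + 1.0
                if run[0] > 0:
                    rec.launch_site_letters = (
                        tok.char_start - fixations[run[0] - 1].char_coord
                    )
                if nxt < len(words):
                    rec.outgoing_saccade_letters = (
                        fixations[nxt].char_coord - fixations[run[-1]].char_coord
                    )
        records.append(rec)
    return records


def apply_exclusions(
    records: list[WordGazeRecord], blink_trial: bool = False
) -> list[WordGazeRecord]:
    """Flag excluded words: whole trial on a blink, plus the sentence's
    first and last word always."""
    n = len(records)
    out = []
    for rec in records:
        r = replace(rec, first_pass_fix_indices=list(rec.first_pass_fix_indices))
        if blink_trial:
            r.excluded = True
            r.exclusion_reason = "blink"
        elif rec.word_index in (0, n - 1):
            r.excluded = True
            r.exclusion_reason = "sentence_edge"
        out.append(r)
    return out


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if arr.size == 0:
        return math.nan, math.nan
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return float(arr.mean()), sd


def summarize_events(
    records_by_trial: list[list[WordGazeRecord]],
    fixations_by_trial: list[list[Fixation]],
) -> EventSummary:
    """Pool per-word records and fixation sequences into descriptives.

    Probabilities are computed over non-excluded words; the
    ``_given_fixated`` variants condition on first-pass fixated words.
    Saccade length is |Δ char| between successive fixations of a trial.
    """
    fixdur: list[float] = []
    sacc: list[float] = []
    for fixes in fixations_by_trial:
        fixdur.extend(f.duration for f in fixes)
        sacc.extend(
            abs(b.char_coord - a.char_coord) for a, b in zip(fixes, fixes[1:])
        )
    recs = [r for trial in records_by_trial for r in trial if not r.excluded]
    ffd, sfd, gd, tvt = [], [], [], []
    for r in recs:
        ffd.append(r.ffd)
        sfd.append(r.sfd)
        gd.append(r.gd)
        tvt.append(float(r.tvt) if r.tvt > 0 else math.nan)
    n = len(recs)
    fixated = [r for r in recs if not r.skipped_first_pass]

    def prob(flags: list[bool], denom: int) -> float:
        return sum(flags) / denom if denom else math.nan

    m_fd, s_fd = _mean_sd(fixdur)
    m_ffd, s_ffd = _mean_sd(ffd)
    m_sfd, s_sfd = _mean_sd(sfd)
    m_gd, s_gd = _mean_sd(gd)
    m_tvt, s_tvt = _mean_sd(tvt)
    m_sac, s_sac = _mean_sd(sacc)
    return EventSummary(
        mean_fixation_duration=m_fd,
        sd_fixation_duration=s_fd,
        mean_ffd=m_ffd,
        sd_ffd=s_ffd,
        mean_sfd=m_sfd,
        sd_sfd=s_sfd,
        mean_gd=m_gd,
        sd_gd=s_gd,
        mean_tvt=m_tvt,
        sd_tvt=s_tvt,
        mean_saccade_length=m_sac,
        sd_saccade_length=s_sac,
        p_skip=prob([r.skipped_first_pass for r in recs], n),
        p_single_fixation=prob([r.n_first_pass == 1 for r in recs], n),
        p_refixation=prob([r.refixated for r in recs], n),
        p_regression=prob([r.regression_out for r in recs], n),
        p_single_fixation_given_fixated=prob(
            [r.n_first_pass == 1 for r in fixated], len(fixated)
        ),
        p_refixation_given_fixated=prob(
            [r.refixated for r in fixated], len(fixated)
        ),
        n_words=n,
        n_fixations=len(fixdur),
    )


def records_to_frame(
    records_by_trial: dict[tuple[str, str], list[WordGazeRecord]],
    sentence_ids: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Flatten per-trial word records into a tidy table (one row per
    word per trial)."""
    rows = []
    for key, recs in records_by_trial.items():
        subj, trial = key
        sent = sentence_ids.get(key, "") if sentence_ids else ""
        for r in recs:
            d = {k: v for k, v in vars(r).items() if k != "first_pass_fix_indices"}
            d.update(subject_id=subj, trial_id=trial, sentence_id=sent)
            rows.append(d)
    return pd.DataFrame(rows)
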