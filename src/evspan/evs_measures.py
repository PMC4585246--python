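"""Temporal and spatial eye-voice span (EVS) and their descriptives.

Sign convention: positive EVS means the eye is ahead of the voice.

* Temporal onset-EVS of a word: articulation onset minus the onset of
  its first first-pass fixation.  Temporal offset-EVS: articulation
  onset minus the offset of its last first-pass fixation (the voice can
  catch up during a word's fixations, so offset-EVS is smaller and may
  go negative on catch-up fixations; negatives are kept and flagged).
* Spatial EVS of a fixation: the fixated character coordinate minus the
  currently articulated character coordinate, in letters, evaluated at
  fixation onset and offset; ΔEVS = onset − offset is the voice advance
  during the fixation (the eye is stationary within a fixation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats

from .fixation_events import Fixation, WordGazeRecord
from .voice_timeline import VoiceTimeline, articulation_onset, voice_char_at

__all__ = [
    "WordEVS",
    "FixationEVS",
    "EVSDescriptives",
    "LeveneResult",
    "temporal_evs",
    "spatial_evs",
    "evs_descriptives",
    "levene_test",
]


@dataclass(frozen=True)
class WordEVS:
    word_index: int
    onset_temporal_evs: float = math.nan  # ms
    offset_temporal_evs: float = math.nan  # ms

    @property
    def negative_offset(self) -> bool:
        return not math.isnan(self.offset_temporal_evs) and self.offset_temporal_evs < 0


@dataclass(frozen=True)
class FixationEVS:
    fixation_index: int
    valid: bool
    onset_spatial_evs: float = math.nan  # letters
    offset_spatial_evs: float = math.nan
    word_index: int = -1
    t_on: float = math.nan
    t_off: float = math.nan

    @property
    def delta_evs(self) -> float:
        return self.onset_spatial_evs - self.offset_spatial_evs


@dataclass(frozen=True)
class EVSDescriptives:
    mean: float
    sd: float
    n: int
    sd_between_subjects: float = math.nan
    sd_within_subjects: float = math.nan


class LeveneResult(NamedTuple):
    F: float
    p: float
    degenerate: bool = False


def temporal_evs(
    word_records: Sequence[WordGazeRecord], vt: VoiceTimeline
) -> list[WordEVS]:
    """Per-word temporal EVS; words skipped in first pass, excluded, or
    never articulated get absent values."""
    out = []
    for rec in word_records:
        onset = articulation_onset(vt, rec.word_index)
        if rec.excluded or rec.skipped_first_pass or onset is None:
            out.append(WordEVS(word_index=rec.word_index))
            continue
        out.append(
            WordEVS(
                word_index=rec.word_index,
                onset_temporal_evs=onset - rec.fp_on_ms,
                offset_temporal_evs=onset - rec.fp_off_ms,
            )
        )
    return out


def spatial_evs(fixations: Sequence[Fixation], vt: VoiceTimeline) -> list[FixationEVS]:
    """Per-fixation spatial EVS, valid only once articulation has
    started by the fixation's onset."""
    out = []
    for f in fixations:
        v_on = voice_char_at(vt, f.t_on)
        if v_on is None:
            out.append(
                FixationEVS(fixation_index=f.index, valid=False,
                            word_index=f.word_index, t_on=f.t_on, t_off=f.t_off)
            )
            continue
        v_off = voice_char_at(vt, f.t_off)
        out.append(
            FixationEVS(
                fixation_index=f.index,
                valid=True,
                onset_spatial_evs=f.char_coord - v_on,
                offset_spatial_evs=f.char_coord - v_off,
                word_index=f.word_index,
                t_on=f.t_on,
                t_off=f.t_off,
            )
        )
    return out


def evs_descriptives(
    values: Sequence[float], subject_ids: Sequence | None = None
) -> EVSDescriptives:
    """Grand mean/SD plus a between/within-subject SD decomposition.

    Between-subject SD is the SD of subject means; within-subject SD is
    the pooled SD of deviations from subject means (n−1 denominator per
    subject).  With fewer than two subjects the decomposition is absent
    but the grand statistics are still returned.
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    arr = arr[mask]
    n = arr.size
    if n == 0:
        return EVSDescriptives(mean=math.nan, sd=math.nan, n=0)
    mean = float(arr.mean())
    sd = float(np.std(arr, ddof=1)) if n > 1 else math.nan
    if subject_ids is None:
        return EVSDescriptives(mean=mean, sd=sd, n=n)
    subj = np.asarray(subject_ids)[mask]
    uniq = np.unique(subj)
    if uniq.size < 2:
        return EVSDescriptives(mean=mean, sd=sd, n=n)
    subj_means = np.array([arr[subj == s].mean() for s in uniq])
    sd_between = float(np.std(subj_means, ddof=1))
    ss_within = 0.0
    df_within = 0
    for s in uniq:
        x = arr[subj == s]
        if x.size > 1:
            ss_within += float(((x - x.mean()) ** 2).sum())
            df_within += x.size - 1
    sd_within = math.sqrt(ss_within / df_within) if df_within > 0 else math.nan
    return EVSDescriptives(
        mean=mean, sd=sd, n=n, sd_between_subjects=sd_between,
        sd_within_subjects=sd_within,
    )


def levene_test(group_a: Sequence[float], group_b: Sequence[float]) -> LeveneResult:
    """Classic mean-centered Levene test for equality of variances.

    One-way ANOVA F on absolute deviations from the group means, with
    (1, n_a + n_b − 2) degrees of freedom.  Degenerate zero-variance
    inputs return F = 0 (equal spread) or F = inf (one group has
    spread, the other none) with the ``degenerate`` flag set.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    n_a, n_b = a.size, b.size
    zbar = (za.sum() + zb.sum()) / (n_a + n_b)
    ss_between = n_a * (za.mean() - zbar) ** 2 + n_b * (zb.mean() - zbar) ** 2
    ss_within = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    df2 = n_a + n_b - 2
    if ss_within == 0.0:
        if ss_between == 0.0:
            return LeveneResult(F=0.0, p=1.0, degenerate=True)
        return LeveneResult(F=math.inf, p=0.0, degenerate=True)
    F = float((ss_between / 1.0) / (ss_within / df2))
    p = float(scipy.stats.f.sf(F, 1, df2))
    return LeveneResult(F=F, p=p)
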