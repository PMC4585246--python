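"""End-to-end orchestration: files in, tidy EVS tables out.

Wires the modules together: read a fixation report, per-trial TextGrid
word tiers and the trigger-sync table; synchronize clocks; assign
fixations to letters and words; parse first-pass measures; build the
voice timeline; and compute temporal (per word) and spatial (per
fixation) eye-voice spans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .evs_measures import FixationEVS, WordEVS, spatial_evs, temporal_evs
from .fixation_events import (
    Fixation,
    WordGazeRecord,
    apply_exclusions,
    assign_words,
    parse_first_pass,
)
from .io_formats import (
    TrialFixations,
    TriggerSync,
    WordInterval,
    read_fixation_report,
    read_sync_table,
    read_textgrid_words,
    sync_to_tracker,
)
from .synthetic_data import layouts_from_corpus
from .text_layout import SentenceLayout
from .voice_timeline import VoiceTimeline

__all__ = [
    "TrialResult",
    "process_trial",
    "analyze_dataset",
    "analyze_experiment",
    "build_saccade_frame",
]


@dataclass
class TrialResult:
    subject_id: str
    trial_id: str
    sentence_id: str
    fixations: list[Fixation]
    word_records: list[WordGazeRecord]
    word_evs: list[WordEVS]
    fixation_evs: list[FixationEVS]
    sync_warning: bool
    blink_trial: bool


def process_trial(
    trial: TrialFixations,
    word_intervals_audio: list[WordInterval],
    sync: TriggerSync,
    layout: SentenceLayout,
) -> TrialResult:
    """Run the full measurement chain on one trial."""
    fixations = assign_words(trial.fixations, layout)
    tracker_ivs, warn = sync_to_tracker(word_intervals_audio, sync)
    vt = VoiceTimeline(tracker_ivs, layout)
    records = parse_first_pass(fixations, layout.n_words, layout)
    records = apply_exclusions(records, blink_trial=trial.has_blink)
    return TrialResult(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        sentence_id=trial.sentence_id,
        fixations=fixations,
        word_records=records,
        word_evs=temporal_evs(records, vt),
        fixation_evs=spatial_evs(fixations, vt),
        sync_warning=warn,
        blink_trial=trial.has_blink,
    )


def _word_rows(res: TrialResult) -> list[dict]:
    evs_by_word = {e.word_index: e for e in res.word_evs}
    # spatial EVS of a word's single first-pass fixation (for SFD models)
    fevs_by_index = {e.fixation_index: e for e in res.fixation_evs}
    rows = []
    for rec in res.word_records:
        e = evs_by_word.get(rec.word_index)
        onset_sp = delta_sp = math.nan
        if rec.n_first_pass == 1:
            fe = fevs_by_index.get(rec.first_pass_fix_indices[0])
            if fe is not None and fe.valid:
                onset_sp = fe.onset_spatial_evs
                delta_sp = fe.delta_evs
        d = {k: v for k, v in vars(rec).items() if k != "first_pass_fix_indices"}
        d.update(
            subject_id=res.subject_id,
            trial_id=res.trial_id,
            sentence_id=res.sentence_id,
            onset_temporal_evs=e.onset_temporal_evs if e else math.nan,
            offset_temporal_evs=e.offset_temporal_evs if e else math.nan,
            onset_evs=onset_sp,
            delta_evs=delta_sp,
        )
        rows.append(d)
    return rows


def _fixation_rows(res: TrialResult) -> list[dict]:
    rows = []
    for f, e in zip(res.fixations, res.fixation_evs):
        rows.append(
            {
                "subject_id": res.subject_id,
                "trial_id": res.trial_id,
                "sentence_id": res.sentence_id,
                "fix_index": f.index,
                "t_on": f.t_on,
                "t_off": f.t_off,
                "char": f.char_coord,
                "word_index": f.word_index,
                "duration": f.duration,
                "valid": e.valid,
                "onset_spatial_evs": e.onset_spatial_evs,
                "offset_spatial_evs": e.offset_spatial_evs,
                "delta_evs": e.delta_evs,
                "blink_trial": res.blink_trial,
            }
        )
    return rows


def analyze_dataset(
    fixations_path: str | Path,
    sync_path: str | Path,
    corpus_path: str | Path,
    textgrid_dir: str | Path | None = None,
    tier: str = "words",
    origin_px: float = 100.0,
    px_per_char: float = 14.0,
    dialect: str = "tsv",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a whole dataset from files.

    The sync table names each trial's TextGrid (``textgrid`` column,
    relative to ``textgrid_dir`` or to the sync table's directory).
    Returns ``(word_table, fixation_table)``: one row per word per
    trial and one row per fixation.
    """
    sync_path = Path(sync_path)
    base = Path(textgrid_dir) if textgrid_dir is not None else sync_path.parent
    trials = read_fixation_report(str(fixations_path), dialect=dialect)
    sync_df = read_sync_table(str(sync_path))
    corpus = pd.read_csv(corpus_path, sep="\t",
                         dtype={"sentence_id": str})
    layouts = layouts_from_corpus(corpus, origin_px, px_per_char)
    word_rows: list[dict] = []
    fix_rows: list[dict] = []
    for srow in sync_df.itertuples():
        key = (str(srow.subject_id), str(srow.trial_id))
        if key not in trials:
            continue
        trial = trials[key]
        tg_path = base / str(srow.textgrid)
        if not tg_path.exists() and str(srow.textgrid).startswith("textgrids/"):
            tg_path = base / Path(str(srow.textgrid)).name
        intervals = read_textgrid_words(str(tg_path), tier_name=tier)
        sync = TriggerSync(
            audio_start_tracker_ms=float(srow.audio_start_tracker_ms),
            audio_end_tracker_ms=float(srow.audio_end_tracker_ms),
            audio_latency_ms=float(srow.audio_latency_ms),
        )
        res = process_trial(trial, intervals, sync, layouts[trial.sentence_id])
        word_rows.extend(_word_rows(res))
        fix_rows.extend(_fixation_rows(res))
    return pd.DataFrame(word_rows), pd.DataFrame(fix_rows)


def analyze_experiment(exp) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the measurement chain on an in-memory simulated experiment
    (no file round trip); returns ``(word_table, fixation_table)``."""
    from .io_formats import FixationRecord

    layouts = layouts_from_corpus(exp.corpus, exp.origin_px, exp.px_per_char)
    word_rows: list[dict] = []
    fix_rows: list[dict] = []
    for subj, trial_id, sid, st in exp.trials:
        trial = TrialFixations(
            subj,
            trial_id,
            sid,
            [
                FixationRecord(subj, trial_id, sid, f.t_on, f.t_off, f.x_px, f.blink)
                for f in st.fixations
            ],
        )
        res = process_trial(trial, st.word_intervals_audio, st.sync, layouts[sid])
        word_rows.extend(_word_rows(res))
        fix_rows.extend(_fixation_rows(res))
    return pd.DataFrame(word_rows), pd.DataFrame(fix_rows)


def build_saccade_frame(fixation_table: pd.DataFrame) -> pd.DataFrame:
    """Per-fixation outcomes for the regulation GLMs.

    For every fixation with a successor in the same trial:
    ``regression`` = the next fixation lands on an earlier word;
    ``refixation`` = it lands on the same word.  Only rows with a valid
    (post-articulation-onset) EVS are kept.
    """
    parts = []
    for _, g in fixation_table.groupby(["subject_id", "trial_id"], sort=False):
        g = g.sort_values("fix_index").copy()
        nxt = g["word_index"].shift(-1)
        g["regression"] = (nxt < g["word_index"]).astype(float)
        g["refixation"] = (nxt == g["word_index"]).astype(float)
        g = g.iloc[:-1]
        parts.append(g)
    out = pd.concat(parts, ignore_index=True)
    out = out[out["valid"] & ~out["blink_trial"]]
    return out.reset_index(drop=True)
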