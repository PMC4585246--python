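"""Synthetic oral-reading data generator.

Produces corpora and simulated trials (fixation reports, word-tier
TextGrids in audio clock, trigger-sync tables, and ground-truth EVS
traces) with the descriptive statistics the analysis pipeline assumes:
sentences of 7–13 words; word lengths on {2..13} with mean 5.26 and SD
2.59 (maximum-entropy pmf); articulated word durations linear in word
length (mean 293 ms, SD 150 ms, duration–length correlation 0.86, from
which the intercept/slope/noise of the linear model are derived by
moment matching); a head start of the eye before speech onset (first
word pronounced ~877 ms after trial start); and oculomotor behaviour
with fixation durations ~253/96 ms and base skipping/refixation/
regression rates 0.14/0.18/0.06.

The simulator is a statistical test harness, not a cognitive model.
Optionally, oculomotor behaviour is *coupled* to the eye-voice span:
fixation durations lengthen with onset-EVS, regressions become more
likely with offset-EVS, refixations with onset-EVS — the generative
counterpart of EVS regulation, used to power the regulation analyses'
recovery tests.

All randomness flows from explicit ``numpy`` Generators; the same seed
reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import expit, logit

from .io_formats import (
    DEFAULT_AUDIO_LATENCY_MS,
    TriggerSync,
    WordInterval,
    write_sync_table,
    write_words_textgrid,
)
from .text_layout import SentenceLayout, build_layout, gaze_to_char

__all__ = [
    "CorpusConfig",
    "ArticulationConfig",
    "OculomotorConfig",
    "SimTrial",
    "SimExperiment",
    "make_length_pmf",
    "generate_corpus",
    "articulation_params_from_moments",
    "sample_word_durations",
    "simulate_articulation",
    "simulate_trial",
    "simulate_experiment",
    "ground_truth_exits",
    "layouts_from_corpus",
    "calibrate_skip_intercept",
]

LENGTH_SUPPORT = np.arange(2, 14)  # letters


@dataclass(frozen=True)
class CorpusConfig:
    """Corpus statistics: word lengths, frequencies, predictabilities."""

    n_sentences: int = 144
    words_per_sentence_min: int = 7
    words_per_sentence_max: int = 13
    length_mean: float = 5.26
    length_sd: float = 2.59
    log10_freq_mean: float = 2.37  # log10 of ~234 per million
    log10_freq_sd: float = 1.0
    freq_min_per_million: float = 0.008
    freq_max_per_million: float = 26530.0
    pred_mean_initial: float = 0.063  # sentence-initial words
    pred_mean_final: float = 0.435  # sentence-final words
    pred_concentration: float = 1.5


@dataclass(frozen=True)
class ArticulationConfig:
    """Spoken-word timing model.

    Word duration = a + b·length + N(0, σ), truncated at 50 ms, with
    (a, b, σ) derived from the target duration moments, the target
    duration–length correlation, and the corpus length moments (see
    :func:`articulation_params_from_moments`).
    """

    duration_mean_ms: float = 293.0
    duration_sd_ms: float = 150.0
    duration_length_corr: float = 0.86
    length_mean: float = 5.26
    length_sd: float = 2.59
    min_duration_ms: float = 50.0
    first_word_delay_mean_ms: float = 877.0
    first_word_delay_sd_ms: float = 191.0
    subject_delay_sd_ms: float = 73.0  # between-subject speech-onset spread
    pause_mean_ms: float = 10.0  # exponential inter-word pauses

    @property
    def derived_params(self) -> tuple[float, float, float]:
        return articulation_params_from_moments(
            self.duration_mean_ms,
            self.duration_sd_ms,
            self.duration_length_corr,
            self.length_mean,
            self.length_sd,
        )


@dataclass(frozen=True)
class OculomotorConfig:
    """Eye-movement model with optional EVS coupling.

    Base rates are the *measured* per-word targets; the internal
    refixation hazard is inflated by 1/(1−p_regression) because the
    regression draw precedes the refixation draw at each fixation exit,
    and the skip-hazard intercept is calibrated against the length pmf
    so the average skip probability hits its target despite the
    length-dependent slope.
    """

    fixation_duration_mean_ms: float = 253.0
    fixation_duration_sd_ms: float = 96.0
    min_fixation_ms: float = 25.0
    saccade_duration_ms: float = 30.0
    landing_sd_letters: float = 1.2
    p_skip: float = 0.14
    p_refixation: float = 0.18
    p_regression: float = 0.06
    skip_length_slope: float = 0.3  # logit per letter below the mean length
    coupling_enabled: bool = False
    gamma_dur_ms_per_letter: float = 6.0  # duration shift per onset-EVS letter
    gamma_reg_per_letter: float = 0.25  # logit slope on offset-EVS
    gamma_refix_per_letter: float = 0.12  # logit slope on onset-EVS
    evs_onset_reference_letters: float = 16.2
    evs_offset_reference_letters: float = 9.7
    subject_fixdur_sd_ms: float = 25.0
    blink_trial_prob: float = 0.05
    max_fixations: int = 200

    @property
    def lognormal_params(self) -> tuple[float, float]:
        m, s = self.fixation_duration_mean_ms, self.fixation_duration_sd_ms
        sigma2 = math.log(1.0 + (s / m) ** 2)
        return math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass
class SimFixation:
    t_on: int  # tracker ms, quantized
    t_off: int
    x_px: float  # quantized to 0.01 px
    blink: bool = False


@dataclass
class SimTrial:
    """One simulated trial plus its ground truth."""

    fixations: list[SimFixation]
    word_intervals_audio: list[WordInterval]
    sync: TriggerSync
    ground_truth: pd.DataFrame
    layout: SentenceLayout
    truncated: bool = False


def make_length_pmf(
    mean: float = 5.26, sd: float = 2.59, tol: float = 1e-8
) -> np.ndarray:
    """Maximum-entropy pmf on word lengths {2..13} with given moments.

    The solution has the exponential-family form
    ``p_k ∝ exp(λ1·k + λ2·k²)``; the multipliers are found by minimizing
    the convex dual ``log Z − λ1·m1 − λ2·m2``.
    """
    k = LENGTH_SUPPORT.astype(float)
    lo, hi = k.min(), k.max()
    if not lo < mean < hi:
        raise ValueError(f"mean {mean} outside support ({lo}, {hi})")
    var = sd * sd
    if var <= 0 or var >= (hi - mean) * (mean - lo):
        raise ValueError(f"infeasible variance {var} for mean {mean} on support")
    m1, m2 = mean, var + mean * mean
    k2 = k * k

    def dual(lam: np.ndarray) -> tuple[float, np.ndarray]:
        eta = lam[0] * k + lam[1] * k2
        c = eta.max()
        z = np.exp(eta - c)
        logZ = c + math.log(z.sum())
        p = z / z.sum()
        grad = np.array([(p * k).sum() - m1, (p * k2).sum() - m2])
        return logZ - lam[0] * m1 - lam[1] * m2, grad

    res = scipy.optimize.minimize(dual, x0=np.zeros(2), jac=True, method="BFGS",
                                  options={"gtol": tol * 1e-2, "maxiter": 500})
    eta = res.x[0] * k + res.x[1] * k2
    p = np.exp(eta - eta.max())
    p /= p.sum()
    if abs((p * k).sum() - m1) > 1e-6 or abs((p * k2).sum() - m2) > 1e-4:
        raise RuntimeError("max-entropy moment matching failed to converge")
    return p


def articulation_params_from_moments(
    duration_mean: float = 293.0,
    duration_sd: float = 150.0,
    corr: float = 0.86,
    length_mean: float = 5.26,
    length_sd: float = 2.59,
) -> tuple[float, float, float]:
    """Intercept a (ms), slope b (ms/letter), noise SD σ (ms) of the
    linear articulation model, matched to the target moments:
    b = r·sd_dur/sd_len; a = mean_dur − b·mean_len; σ = sd_dur·√(1−r²).
    """
    b = corr * duration_sd / length_sd
    a = duration_mean - b * length_mean
    sigma = duration_sd * math.sqrt(1.0 - corr * corr)
    return a, b, sigma


def sample_word_durations(
    lengths: np.ndarray, config: ArticulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Articulated durations (ms) for the given word lengths."""
    a, b, sigma = config.derived_params
    d = a + b * np.asarray(lengths, dtype=float) + rng.normal(0.0, sigma, len(lengths))
    return np.maximum(d, config.min_duration_ms)


def _random_word(length: int, rng: np.random.Generator) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    return "".join(letters[i] for i in rng.integers(0, 26, length))


def generate_corpus(
    config: CorpusConfig, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Sample a corpus table: one row per word with text, frequency per
    million, and cloze predictability (mean increasing with sentence
    position)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmf = make_length_pmf(config.length_mean, config.length_sd)
    rows = []
    for s in range(config.n_sentences):
        sid = f"s{s:03d}"
        n_words = int(
            rng.integers(config.words_per_sentence_min, config.words_per_sentence_max + 1)
        )
        lengths = rng.choice(LENGTH_SUPPORT, size=n_words, p=pmf)
        for i, L in enumerate(lengths):
            freq = 10.0 ** rng.normal(config.log10_freq_mean, config.log10_freq_sd)
            freq = float(np.clip(freq, config.freq_min_per_million,
                                 config.freq_max_per_million))
            frac = i / (n_words - 1) if n_words > 1 else 0.0
            m = config.pred_mean_initial + frac * (
                config.pred_mean_final - config.pred_mean_initial
            )
            kappa = config.pred_concentration
            pred = float(rng.beta(m * kappa, (1.0 - m) * kappa))
            rows.append(
                {
                    "sentence_id": sid,
                    "word_index": i,
                    "word": _random_word(int(L), rng),
                    "frequency_per_million": freq,
                    "predictability": pred,
                }
            )
    return pd.DataFrame(rows)


def simulate_articulation(
    layout: SentenceLayout,
    config: ArticulationConfig,
    rng: np.random.Generator,
    subject_delay_offset_ms: float = 0.0,
) -> list[WordInterval]:
    """Word articulation intervals for one trial, in *tracker* (trial)
    milliseconds; the trial clock starts at 0."""
    lengths = np.array([tok.length_letters for tok in layout.tokens])
    durations = sample_word_durations(lengths, config, rng)
    t = max(
        config.min_duration_ms,
        rng.normal(config.first_word_delay_mean_ms, config.first_word_delay_sd_ms)
        + subject_delay_offset_ms,
    )
    out = []
    for tok, dur in zip(layout.tokens, durations):
        out.append(
            WordInterval(
                word_index=tok.index,
                t_on_ms=t,
                t_off_ms=t + dur,
                clock="tracker",
                label=tok.text,
            )
        )
        t += dur
        if config.pause_mean_ms > 0:
            t += rng.exponential(config.pause_mean_ms)
    return out


def calibrate_skip_intercept(
    config: OculomotorConfig, pmf: np.ndarray, length_mean: float = 5.26
) -> float:
    """Logit intercept c such that the pmf-average of
    ``expit(c + slope·(length_mean − length))`` equals the target skip
    probability."""
    k = LENGTH_SUPPORT.astype(float)

    def f(c: float) -> float:
        return float((pmf * expit(c + config.skip_length_slope * (length_mean - k))).sum()
                     ) - config.p_skip

    return float(scipy.optimize.brentq(f, -20.0, 20.0))


def _voice_char(
    intervals: list[WordInterval], layout: SentenceLayout, t: float
) -> float | None:
    """Voice position in char coordinates (tracker clock); the simulator's
    own copy of per-letter interpolation with the pause hold rule."""
    if not intervals or t < intervals[0].t_on_ms:
        return None
    pos = None
    for iv in intervals:
        if t < iv.t_on_ms:
            break
        tok = layout.tokens[iv.word_index]
        if t < iv.t_off_ms:
            frac = (t - iv.t_on_ms) / (iv.t_off_ms - iv.t_on_ms)
            return tok.char_start + tok.length_letters * frac
        pos = float(tok.char_end)
    return pos


def _quantize_audio(intervals_tracker: list[WordInterval], sync: TriggerSync
                    ) -> list[WordInterval]:
    """Convert tracker-clock intervals to the audio clock and quantize
    the boundaries to 0.001 ms (µs when written as TextGrid seconds)."""
    shift = sync.audio_start_tracker_ms + sync.audio_latency_ms
    out = []
    for iv in intervals_tracker:
        out.append(
            replace(
                iv,
                t_on_ms=round((iv.t_on_ms - shift) * 1000.0) / 1000.0,
                t_off_ms=round((iv.t_off_ms - shift) * 1000.0) / 1000.0,
                clock="audio",
            )
        )
    return out


def simulate_trial(
    layout: SentenceLayout,
    oculo: OculomotorConfig,
    artic: ArticulationConfig,
    rng: np.random.Generator,
    subject_fixdur_offset_ms: float = 0.0,
    subject_delay_offset_ms: float = 0.0,
    skip_intercept: float | None = None,
) -> SimTrial:
    """Simulate one trial: an articulation stream plus an EVS-aware
    fixation event loop.

    At each fixation the ground-truth onset-EVS is computed; when
    coupling is enabled the fixation duration is shifted by
    γ_dur·(onset-EVS − reference) and the exit hazards (regression on
    offset-EVS, refixation on onset-EVS) get logit shifts.  Forward
    moves may skip the next word with probability decreasing in its
    length.  The trial ends when the eye moves forward off the last
    word, or is truncated (with a flag) at ``max_fixations``.
    """
    if skip_intercept is None:
        pmf = make_length_pmf(artic.length_mean, artic.length_sd)
        skip_intercept = calibrate_skip_intercept(oculo, pmf, artic.length_mean)
    intervals_tracker = simulate_articulation(
        layout, artic, rng, subject_delay_offset_ms
    )
    sync = TriggerSync(
        audio_start_tracker_ms=0.0,
        audio_end_tracker_ms=intervals_tracker[-1].t_off_ms + 500.0,
        audio_latency_ms=DEFAULT_AUDIO_LATENCY_MS,
    )
    audio = _quantize_audio(intervals_tracker, sync)
    # tracker-clock intervals as the pipeline will reconstruct them
    shift = sync.audio_start_tracker_ms + sync.audio_latency_ms
    tracker_q = [
        replace(iv, t_on_ms=iv.t_on_ms + shift, t_off_ms=iv.t_off_ms + shift,
                clock="tracker")
        for iv in audio
    ]
    mu_ln, sigma_ln = oculo.lognormal_params
    refix_hazard = oculo.p_refixation / (1.0 - oculo.p_regression)
    ref_on = oculo.evs_onset_reference_letters
    ref_off = oculo.evs_offset_reference_letters
    n_words = layout.n_words
    last = n_words - 1

    def land(word: int) -> float:
        tok = layout.tokens[word]
        center = tok.char_start + tok.length_letters / 2.0
        c = center + rng.normal(0.0, oculo.landing_sd_letters)
        return float(np.clip(c, tok.char_start + 0.1, tok.char_end - 0.1))

    fixations: list[SimFixation] = []
    moves: list[str] = []
    w = 0
    char = land(0)
    t = 0.0
    truncated = False
    while True:
        if len(fixations) >= oculo.max_fixations:
            truncated = True
            break
        onset_evs = None
        v = _voice_char(intervals_tracker, layout, t)
        if v is not None:
            onset_evs = char - v
        dur = rng.lognormal(mu_ln, sigma_ln) + subject_fixdur_offset_ms
        if oculo.coupling_enabled and onset_evs is not None:
            dur += oculo.gamma_dur_ms_per_letter * (onset_evs - ref_on)
        dur = max(oculo.min_fixation_ms, dur)
        t_off = t + dur
        v_off = _voice_char(intervals_tracker, layout, t_off)
        offset_evs = char - v_off if v_off is not None else None
        # quantize as the tracker would record it
        x_px = round(layout.char_to_px(char) * 100.0) / 100.0
        t_on_q = int(round(t))
        t_off_q = max(t_on_q + 1, int(round(t_off)))
        fixations.append(SimFixation(t_on=t_on_q, t_off=t_off_q, x_px=x_px))

        p_reg = oculo.p_regression
        p_rf = refix_hazard
        if oculo.coupling_enabled:
            if offset_evs is not None:
                p_reg = float(expit(logit(oculo.p_regression)
                                    + oculo.gamma_reg_per_letter * (offset_evs - ref_off)))
            if onset_evs is not None:
                p_rf = float(expit(logit(refix_hazard)
                                   + oculo.gamma_refix_per_letter * (onset_evs - ref_on)))
        u = rng.random()
        if u < p_reg and w > 0:
            moves.append("regression")
            w = w - 1
            char = land(w)
        elif rng.random() < p_rf:
            moves.append("refixation")
            char = land(w)
        else:
            if w == last:
                moves.append("end")
                break
            nxt = w + 1
            tok_next = layout.tokens[nxt]
            p_skip = float(expit(skip_intercept + oculo.skip_length_slope
                                 * (artic.length_mean - tok_next.length_letters)))
            if rng.random() < p_skip and nxt < last:
                moves.append("skip_forward")
                w = nxt + 1
            else:
                moves.append("forward")
                w = nxt
            char = land(w)
        t = t_off + oculo.saccade_duration_ms
    # blink trials: one fixation flagged, trial excluded downstream
    if rng.random() < oculo.blink_trial_prob and fixations:
        k = int(rng.integers(0, len(fixations)))
        fixations[k] = replace(fixations[k], blink=True)
    # ground truth recomputed from the quantized records
    gt_rows = []
    from .text_layout import locate_char

    for i, f in enumerate(fixations):
        c = gaze_to_char(layout, f.x_px)
        v_on = _voice_char(tracker_q, layout, float(f.t_on))
        v_off = _voice_char(tracker_q, layout, float(f.t_off))
        valid = v_on is not None
        gt_rows.append(
            {
                "fix_index": i,
                "t_on": f.t_on,
                "t_off": f.t_off,
                "char": c,
                "word_index": locate_char(layout, c)[0],
                "onset_evs": c - v_on if valid else math.nan,
                "offset_evs": c - v_off if v_off is not None else math.nan,
                "valid": valid,
                "move": moves[i] if i < len(moves) else "truncated",
            }
        )
    return SimTrial(
        fixations=fixations,
        word_intervals_audio=audio,
        sync=sync,
        ground_truth=pd.DataFrame(gt_rows),
        layout=layout,
        truncated=truncated,
    )


def ground_truth_exits(ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Fixation-exit frame from a ground-truth trace: binary regression/
    refixation outcomes plus the EVS covariates.  Callers filter on the
    covariate they model (``onset_evs``/``offset_evs`` non-missing) and
    on ``regression_possible`` (word 0 has no earlier word to regress
    to, so its exits carry no regression hazard)."""
    g = ground_truth[ground_truth["move"] != "truncated"].copy()
    g["regression"] = (g["move"] == "regression").astype(float)
    g["refixation"] = (g["move"] == "refixation").astype(float)
    g["regression_possible"] = g["word_index"] > 0
    return g.reset_index(drop=True)


@dataclass
class SimExperiment:
    """A simulated multi-subject dataset with export helpers."""

    trials: list[tuple[str, str, str, SimTrial]]  # subject, trial, sentence, data
    corpus: pd.DataFrame
    oculo: OculomotorConfig
    artic: ArticulationConfig
    origin_px: float = 100.0
    px_per_char: float = 14.0

    def fixation_frame(self) -> pd.DataFrame:
        rows = []
        for subj, trial, sent, st in self.trials:
            for f in st.fixations:
                rows.append(
                    {
                        "subject_id": subj,
                        "trial_id": trial,
                        "sentence_id": sent,
                        "t_on": f.t_on,
                        "t_off": f.t_off,
                        "x_px": f.x_px,
                        "blink": f.blink,
                    }
                )
        return pd.DataFrame(rows)

    def sync_frame(self) -> pd.DataFrame:
        rows = []
        for subj, trial, sent, st in self.trials:
            rows.append(
                {
                    "subject_id": subj,
                    "trial_id": trial,
                    "sentence_id": sent,
                    "audio_start_tracker_ms": st.sync.audio_start_tracker_ms,
                    "audio_end_tracker_ms": st.sync.audio_end_tracker_ms,
                    "audio_latency_ms": st.sync.audio_latency_ms,
                    "textgrid": f"textgrids/{subj}_{trial}.TextGrid",
                }
            )
        return pd.DataFrame(rows)

    def ground_truth_frame(self) -> pd.DataFrame:
        parts = []
        for subj, trial, sent, st in self.trials:
            g = st.ground_truth.copy()
            g.insert(0, "subject_id", subj)
            g.insert(1, "trial_id", trial)
            g.insert(2, "sentence_id", sent)
            parts.append(g)
        return pd.concat(parts, ignore_index=True)

    def write_dataset(self, outdir: str | Path) -> None:
        """Write fixations.tsv, sync.tsv, corpus.tsv, ground_truth.tsv
        and one TextGrid per trial under ``textgrids/``."""
        outdir = Path(outdir)
        (outdir / "textgrids").mkdir(parents=True, exist_ok=True)
        self.fixation_frame().to_csv(outdir / "fixations.tsv", sep="\t", index=False)
        with open(outdir / "sync.tsv", "w", encoding="utf-8") as fh:
            write_sync_table(self.sync_frame(), fh)
        self.corpus.to_csv(outdir / "corpus.tsv", sep="\t", index=False)
        self.ground_truth_frame().to_csv(
            outdir / "ground_truth.tsv", sep="\t", index=False
        )
        for subj, trial, sent, st in self.trials:
            path = outdir / "textgrids" / f"{subj}_{trial}.TextGrid"
            with open(path, "w", encoding="utf-8") as fh:
                write_words_textgrid(
                    st.word_intervals_audio,
                    fh,
                    xmax_ms=st.sync.audio_end_tracker_ms
                    - st.sync.audio_start_tracker_ms,
                )


def layouts_from_corpus(
    corpus: pd.DataFrame, origin_px: float = 100.0, px_per_char: float = 14.0
) -> dict[str, SentenceLayout]:
    """Build one layout per sentence from a corpus table."""
    layouts = {}
    for sid, g in corpus.groupby("sentence_id", sort=True):
        g = g.sort_values("word_index")
        text = " ".join(g["word"].astype(str))
        layouts[sid] = build_layout(
            text, g.reset_index(drop=True), origin_px=origin_px,
            px_per_char=px_per_char,
        )
    return layouts


def simulate_experiment(
    n_subjects: int,
    corpus: pd.DataFrame,
    oculo: OculomotorConfig | None = None,
    artic: ArticulationConfig | None = None,
    seed: int = 0,
    n_sentences: int | None = None,
    origin_px: float = 100.0,
    px_per_char: float = 14.0,
) -> SimExperiment:
    """Simulate ``n_subjects`` reading (a subset of) the corpus.

    Per-subject random offsets are applied to the speech-onset delay
    (between-subject SD of the temporal EVS) and to fixation durations.
    Deterministic for a given seed: every subject×sentence trial has its
    own child RNG spawned from the seed.
    """
    oculo = oculo or OculomotorConfig()
    artic = artic or ArticulationConfig()
    layouts = layouts_from_corpus(corpus, origin_px, px_per_char)
    sentence_ids = sorted(layouts)
    if n_sentences is not None:
        sentence_ids = sentence_ids[:n_sentences]
    pmf = make_length_pmf(artic.length_mean, artic.length_sd)
    skip_c = calibrate_skip_intercept(oculo, pmf, artic.length_mean)
    root = np.random.SeedSequence(seed)
    subj_ss, trial_ss = root.spawn(2)
    subj_rng = np.random.default_rng(subj_ss)
    delay_offsets = subj_rng.normal(0.0, artic.subject_delay_sd_ms, n_subjects)
    fixdur_offsets = subj_rng.normal(0.0, oculo.subject_fixdur_sd_ms, n_subjects)
    trial_seeds = trial_ss.spawn(n_subjects * len(sentence_ids))
    trials = []
    k = 0
    for s in range(n_subjects):
        subj = f"subj{s:02d}"
        for j, sid in enumerate(sentence_ids):
            rng = np.random.default_rng(trial_seeds[k])
            k += 1
            st = simulate_trial(
                layouts[sid],
                oculo,
                artic,
                rng,
                subject_fixdur_offset_ms=float(fixdur_offsets[s]),
                subject_delay_offset_ms=float(delay_offsets[s]),
                skip_intercept=skip_c,
            )
            trials.append((subj, f"t{j:03d}", sid, st))
    return SimExperiment(
        trials=trials, corpus=corpus, oculo=oculo, artic=artic,
        origin_px=origin_px, px_per_char=px_per_char,
    )
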