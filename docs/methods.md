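# Methods

## Coordinate system and geometry

Sentences are assumed displayed in a fixed-width font, so horizontal gaze
position maps affinely to a continuous character coordinate: coordinate 0
is the left edge of the first letter, one unit is one letter cell
(default 14 px per letter). Inter-word spaces are counted in the
coordinate system but owned by no word — spatial EVS values are therefore
display-line distances that include intervening spaces, which is what a
"distance in letters" along the printed line physically means.

Fixations landing on a separating space or outside the sentence are
assigned to the nearest word by letter-cell distance, ties going to the
*following* word (a reading-direction prior; there is no universally
agreed convention). Off-screen fixations clamp to the first/last word and
carry an out-of-bounds flag.

## Clock synchronization

Word boundaries are annotated on the audio clock (TextGrid seconds). The
recording-start trigger's tracker timestamp anchors the affine map
`t_tracker = t_audio + audio_start_tracker_ms + audio_latency_ms`. The
sound card's fixed output latency (default 5 ms) delays the audio path
relative to the trigger, so synced times *add* the latency; the sign is
isolated in this one constant. A constant offset is applied per trial;
boundary times past the end trigger (possible trigger drift) only raise a
warning flag.

## First-pass parsing

First pass on word *w* is the maximal run of consecutive fixations on *w*
starting at its first fixation, provided no word beyond *w* was fixated
earlier; any fixation off *w* (in either direction) terminates the run,
and re-entries count only toward total viewing time. A word with no
first-pass fixation is coded as skipped (including words never reached in
a truncated trial). Regression-out is coded per word on the saccade that
exits the first pass; regression-in on any fixation that arrives after a
later word was fixated. Launch site is the letter distance from the
previous fixation to the word's first letter (positive when launched from
the left); landing site is the 1-based letter position of the first
first-pass fixation within the word; the outgoing saccade amplitude is
the signed character-coordinate difference. All saccade metrics are in
letters, not pixels.

Blink trials are excluded wholly; the first and last word of every
sentence are always excluded. Probabilities are reported over
non-excluded words, with `_given_fixated` variants conditioning on
first-pass fixated words, since the conditioning convention for
refixation and single-fixation probabilities varies across studies.

## Voice interpolation and EVS

Within an articulated word the voice position advances linearly — the
per-letter duration is the articulated duration divided by the letter
count — so the advance over a word's interval is exactly its length.
During inter-word pauses the position *holds* at the completed word's
end: nothing is articulated, and interpolating across the space would
manufacture spurious voice motion. Before the first word's onset the
voice position is undefined and spatial EVS rows are flagged invalid.

Sign convention: positive EVS means the eye leads the voice. Temporal
offset-EVS pairs with gaze duration (articulation onset minus the last
*first-pass* fixation offset; re-readings are excluded) and may be
negative on catch-up fixations — negatives are kept and flagged, not
dropped. The between/within-subject decomposition uses the SD of subject
means and the pooled SD of deviations from subject means with n−1
denominators per subject.

## Regulation models

Binned probability curves use equal-count (quantile) bins with Wilson 95%
intervals. Polynomial covariates use an orthonormal basis over the
observed values (QR of the Vandermonde matrix; columns unit-norm,
mutually orthogonal and orthogonal to the constant, sign fixed by a
positive leading coefficient) — the standard orthogonal-contrast coding
up to that sign choice. Logistic models are fitted by IRLS with
convergence on relative deviance change < 1e-10 within 50 iterations and
standard errors from the final weighted least-squares system; fitted
probabilities within 1e-8 of 0/1 (|η| > 18) raise a non-convergence flag
with a separation diagnostic instead of returning silently huge
coefficients. Log-SFD models are ordinary least squares (via statsmodels)
on the natural log of SFD with quadratic trends for all covariates except
the fixated word's frequency (cubic), frequencies log10-transformed,
predictabilities entering linearly in [0,1], covariates mean-centered,
and optional EVS × covariate interaction columns. Effects with |t| or |z|
above 2.0 are flagged.

Random effects for subjects and sentences are deliberately **not**
estimated: crossed mixed models are a solved problem in dedicated
packages, and the frames exported here carry the grouping columns needed
to fit them externally. The in-package fits are fixed-effects analogues,
adequate for the simulation-based calibration and power checks.

## Synthetic generator

The generator is a statistical test harness that reproduces descriptive
statistics; it makes no claim of cognitive fidelity (no parafoveal
preview, no lexical processing dynamics).

* **Corpus**: sentence lengths uniform on 7–13 words; word lengths on
  {2..13} from the maximum-entropy pmf matching mean 5.26 and SD 2.59
  (exponential tilt in k and k², multipliers solved to 1e-8);
  frequencies log10-normal (median ≈ 234 per million, SD 1 dex, clipped
  to the corpus range 0.008–26,530); predictabilities Beta with mean
  rising linearly from 0.063 (sentence-initial) to 0.435
  (sentence-final) at concentration 1.5, giving a strongly right-skewed
  distribution with many near-zero values.
* **Articulation**: duration = a + b·length + N(0, σ) truncated at
  50 ms, with b = r·sd_dur/sd_len, a = mean_dur − b·mean_len,
  σ = sd_dur·√(1−r²) derived from the targets (mean 293 ms, SD 150 ms,
  r = 0.86, length moments 5.26/2.59), i.e. a ≈ 31 ms, b ≈ 49.8
  ms/letter, σ ≈ 76.5 ms. First-word onset ~ N(877, 191) ms after trial
  start; exponential inter-word pauses (mean 10 ms). Word boundaries are
  written in audio-clock seconds (µs precision) so the pipeline's sync
  path is exercised end-to-end.
* **Oculomotor event loop**: fixation durations lognormal targeting
  253/96 ms (floor 25 ms); landings Gaussian (SD 1.2 letters) around
  word centers, clamped within the word; constant 30 ms saccade
  duration. At each fixation exit the hazards are: regression (to the
  previous word), else refixation, else a forward move that may skip the
  next word with probability decreasing in its length (logit slope 0.3
  per letter). Because the regression draw precedes the refixation draw,
  the internal refixation hazard is 0.18/(1−0.06); the skip intercept is
  solved numerically so the pmf-averaged skip probability equals 0.14.
  Saccade-length statistics are emergent from the layout (≈5.5 letters
  mean), not targeted directly.
* **EVS coupling** (off by default): duration shift of 6 ms per letter
  of onset-EVS above the 16.2-letter reference; logit shifts of 0.25 per
  letter of offset-EVS (regressions, 9.7-letter reference) and 0.12 per
  letter of onset-EVS (refixations). Regressions trigger on
  *end-of-fixation* EVS by design, making offset-EVS the more predictive
  covariate — a recoverable property used in the tests.
* **Subjects**: per-subject offsets on the speech-onset delay (SD 73 ms,
  the between-subject component of the temporal EVS) and on fixation
  durations (SD 25 ms).
* **Determinism and quantization**: every trial draws from a child RNG
  spawned from the experiment seed; the same seed reproduces all
  artifacts bit-for-bit. Fixation times are quantized to integer tracker
  ms, pixel positions to 0.01 px, audio boundaries to 1 µs, and the
  ground-truth EVS trace is recomputed from the *quantized* values, so
  the pipeline-vs-ground-truth identity is exact rather than
  tolerance-absorbed.

What passing tests do *not* show about real data: the generator has no
parafoveal preview, no word-property effects on fixation durations
(unless injected), stationary speech rate, and fluent error-free
articulation; real datasets additionally need manual boundary scoring
and error-trial exclusion upstream of this pipeline.

## Calibration and problem sizes

The test suite runs the statistical calibration at sizes chosen for a
single CPU: the coupling test's type-I error uses 1000 replicates of
30-trial simulations (~320 analyzable fixation exits each), with the
likelihood-ratio test rather than the Wald test because with ~20
regression events per replicate the Wald test is noticeably conservative
while the LR statistic holds its 5% level; the acceptance band is
0.05 ± 0.02. Slope recovery uses one 400-trial coupled simulation
(Wald 95% CI covering the generating coefficient). The exhaustive parser
check enumerates all 5,461 fixation sequences of length ≤ 6 over 4
words against an independent brute-force implementation. The end-to-end
identity check runs 100 trials through the full file round trip
(TextGrid + TSV + sync) at 1e-9-letter tolerance. The steady-state
eye/voice advance balance is evaluated on the second half of each
coupled trial, excluding the initial head-start transient, with a 12%
relative tolerance.

## Known limitations

* Regression targets in the generator are always the immediately
  preceding word; long-range regressions are not simulated.
* The fixed-effects fits understate standard errors relative to crossed
  mixed models when subject/sentence clustering is strong; use the
  exported frames with a mixed-model package for inference on real data.
* Trigger drift between start and end triggers is flagged but not
  corrected.
* The per-letter interpolation ignores pauses *within* a word's
  annotated interval (none are generated; manual annotations may differ).
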