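# Methods

`melodytrf` implements an end-to-end pipeline for quantifying how melodic
expectations are encoded in continuous neural responses to music, exercised
on synthetic data with known ground truth.  This note documents the models,
the choices made where the design was genuinely open, and what the synthetic
validation does and does not show.

## 1. Melodic expectation model

### Sequence model

Expectations are computed per note for two viewpoints: **pitch** (MIDI
number) and **onset time**, the latter represented as quantized
inter-onset-interval (IOI) classes on a tatum grid (each class is the
integer multiple of the smallest note value; the first note of a piece has
no preceding interval and carries a dedicated initial class that is excluded
from summary statistics).

Each viewpoint is predicted by a variable-order Markov model with
prediction-by-partial-matching (PPM) smoothing, escape method C: after a
context seen `n` times with `t` distinct continuations, the observed
continuations share `n/(n+t)` of the probability mass in proportion to their
counts and `t/(n+t)` escapes to the next-shorter context, terminating in the
uniform distribution over the alphabet.  The recursion is *interpolated*
(every context length contributes; unseen contexts are transparent), which
guarantees strictly positive probability for every symbol — surprise is
always finite.  Context length is unbounded by default: the model conditions
on as much history as exists.

Two instances are consulted per prediction:

* **LTM** (long-term model), trained on a corpus that never includes the
  analyzed piece — schematic knowledge;
* **STM** (short-term model), grown online over the preceding notes of the
  current piece only, updated strictly *after* each prediction, so the
  series is causal: note *j* can never influence the scores of an earlier
  note.

Their distributions are merged by an entropy-weighted geometric mean: each
model gets weight `w = 1/(1 + H_rel)` with `H_rel = H(d)/log2|E|` its
entropy relative to the uniform maximum, and the combination is
`p ∝ p_LTM^(w_L/W) · p_STM^(w_S/W)`, renormalized.  Probabilities are floored
at 1e-12 before the geometric step.  Two design points worth flagging:

* Within a model, order combination is the PPM-C escape recursion itself
  (which is an order mixture); the entropy weighting applies only across
  the LTM/STM pair.  This keeps the single-model predictor exactly equal to
  the plain PPM-C recursion, which the tests verify against a brute-force
  implementation to 1e-12.
* The exact weighting scheme of the original IDyOM-style implementations is
  not reproduced here; ours is a documented stand-in from the same family.
  Absolute surprise values will differ from other implementations even when
  orderings agree.

The observed note is then scored by its **surprise** `S = -log2 p(e | context)`
and the pre-observation **entropy** `H = Σ p·(-log2 p)` of the predictive
distribution, in bits, yielding four per-note features: `S_p`, `H_p` (pitch)
and `S_o`, `H_o` (onset time).

### Memory restriction and shuffle control

`memory_restricted_series` rebuilds the STM from scratch at every chunk
boundary of 1, 2, 4, 8, 16 or 32 musical bars (the LTM untouched); infinite
memory reproduces the standard series exactly.  All restricted feature sets
have identical dimensionality, so downstream model comparisons isolate
expectation *quality* from model *capacity*.  `shuffle_series` permutes the
four value columns by one shared random permutation while keeping note
onsets fixed — a dimensionality- and distribution-matched control that
carries timing but no expectation information.

## 2. Synthetic data generator

The generator defines the study conditions; everything downstream is
validated against it.

* **Markov source.** Explicit conditional probability tables (Dirichlet
  draws, concentration 0.5 by default — peaked, melody-like rows) over a
  12-pitch alphabet and 4 IOI classes, order 1.  Because the tables are
  known, per-note surprise and entropy have closed forms
  (`true_expectations`), the oracle for criterion-level checks.
* **Phrase structure.** Optionally a motif spanning `bars_per_phrase` bars
  is generated once and cycled with sporadic perturbations (probability
  0.05–0.1).  Local order-k statistics still follow the tables, but the
  long-range repetition is only exploitable by an STM whose memory spans
  several bars — the construction behind the memory-sweep analysis.  For
  that analysis the local rows are flattened (concentration 2.0) so that
  motif repetition carries most of the learnable structure.
* **Bar/tempo convention.** 4/4 at 100 bpm (2.4 s bars); the tatum is a
  16th note (150 ms).
* **Acoustic envelope.** One kernel per note: 10 ms linear attack, 100 ms
  exponential decay (piano-like); overlapping notes superpose.
* **Forward model.** Each neural channel is the sum over features of the
  feature train convolved with a known kernel, plus 1/f noise.  Acoustic
  kernels peak at 50 ms; expectation kernels at 200 ms — the latency
  separation the lag analyses must resolve.  Driving feature trains are
  standardized before convolution so each component's variance share is set
  by its kernel amplitude alone; expectation kernels have amplitude 0.5
  relative to acoustic ones (a minority share, as in real recordings).
* **Noise and cohorts.** 1/f Gaussian noise, rescaled so the realized
  signal/noise variance ratio equals the requested SNR exactly.  The default
  SNR of 0.005 places acoustic envelope tracking at r ≈ 0.05–0.15, the range
  reported for low-rate scalp recordings of naturalistic listening; lowering
  it further degrades detection, raising it makes every effect trivially
  large.  A cohort shares its stimuli (10 pieces × ~150 s × 3 repetitions =
  30 trials) across 20 subjects in two groups of 10; subjects differ by
  noise seed, smooth random channel gains, and a log-uniform SNR jitter
  (factor 2) modeling recording-quality variability.  One group's
  expectation kernels can be scaled (`expectation_gain`), modeling stronger
  expectation encoding with musical training; gain 0 silences the
  expectation response entirely (a null cohort).

What the generator does **not** emulate: volume conduction and sensor
topography, artifacts (blinks, line noise), non-stationarity, nonlinear
responses, and any realistic pitch content of actual repertoire.  Passing
tests therefore demonstrate that the pipeline recovers what it is designed
to recover under its own assumptions — not that real recordings contain
these signals.

## 3. Encoding analysis

### TRF estimation

The temporal response function is a lagged linear filter: a stimulus sample
at time *t* contributes to the predicted response at *t + lag* for every lag
in the window.  Design columns are feature-major, lag-minor, zero-padded at
trial edges (keeping trials aligned across feature sets, so score
differences are attributable to features, not samples).  Ridge regression
with an unpenalized intercept is solved on columns standardized with
training-fold statistics (all-zero training columns are skipped and receive
zero weight); reported weights are mapped back to raw units.

* **Windows.** Weights are inspected over −150..750 ms; prediction uses the
  compact 0..350 ms window.
* **Cross-validation.** Leave-one-out across trials; the ridge parameter is
  chosen per held-out fold by an inner leave-one-out over the training
  trials only, over the grid 1e−3..1e6 (10 log-spaced values), shared across
  channels.  Held-out quality is Pearson's r per channel.
* **Implementation.** All fold statistics (Gram matrices, cross-products,
  moments) are accumulated per trial and combined algebraically, and
  held-out r is computed from sufficient statistics, so no O(time) work is
  repeated inside the λ search.  For cohorts sharing stimuli, every ridge
  system is factorized once with all subjects' channels stacked as
  right-hand sides (`crossval_predict_cohort`) — bit-identical to the
  per-subject path.

### Feature-set comparison and the detection rule

The headline contrast is acoustic-only (**A**: envelope + half-wave
rectified derivative) versus acoustic+expectation (**AM**: + the four
expectation impulse trains).  Per subject, held-out r is averaged over
channels and trials; the group-level difference is tested with a paired
sign-flip permutation test (exhaustive when 2^n is affordable, hence exact).

"Expectation encoding detected" requires **both** a significant test and a
*positive* mean enhancement.  The direction matters: a richer but
uninformative feature set (the shuffle control, or a zero-gain cohort)
carries a small, highly consistent *negative* out-of-sample cost
(≈ −0.0005 in r, the honest price of 92 nuisance columns), which a
two-tailed test will flag in essentially every well-powered cohort.  That is
a dimensionality effect, not evidence of encoding, so it does not count as a
detection; the raw two-tailed p-value is reported alongside.

### Lag relevance (backward elimination)

For each 50 ms window tiling −150..750 ms, the TRF is refit without that
window's lags (all features) and the loss `r_LOSS = r_full − r_without` is
measured on leave-one-out predictions; only this first elimination pass is
run.  Significance is one-sided (relevance means loss > 0; removing an
irrelevant window slightly *improves* held-out r) against a null built by
circularly shifting each trial's response by at least 2 s — destroying
stimulus–response coupling while preserving autocorrelation — with the
entire leave-one-out loss computation replayed on every surrogate, and
Bonferroni correction over windows × channels.  Sign-flip tests across
leave-one-out trials were rejected for this purpose: fold scores share
training data, violating exchangeability and inflating the family-wise error
(measured ~7% at nominal 5%); the shift null is calibrated by construction
(measured ~3.5%).

### ERP contrast

Epochs are cut around note onsets (window −100..+400 ms by default; epochs
crossing trial edges are dropped and counted).  Before any surprise split,
notes are restricted to those whose peak envelope (maximum within
onset..+150 ms) lies within ±5% of the median peak — the acoustic confound
control; the realized retained fraction is reported rather than fixed.  The
survivors are split into top/bottom 20% by pitch surprise (stable ties) and
compared by (a) per-latency two-tailed permutation tests, FDR-corrected
across latencies, and (b) total 0–200 ms power, by permutation across
epochs.  Pre-stimulus activity is retained (short inter-note intervals leak
into the baseline; an optional filter on preceding IOI > 200 ms removes it).
No baseline correction is applied by default.

## 4. Statistics toolkit

* Permutation tests use the add-one convention `p = (1+k)/(n+1)` (never
  exactly zero); paired tests switch to exhaustive sign-flip enumeration
  when `2^n ≤ n_perm`, making them exact.
* Benjamini–Hochberg FDR and Bonferroni corrections; BH is backed by
  statsmodels.
* Cohen's d: pooled-SD (unpaired) or SD-of-differences (paired); zero
  variance yields signed infinity with a warning, never silently.
* Topographic dissimilarity is computed exactly as `DISS = 2(1−r)` with r
  the Pearson correlation between two channel maps (identities: 0 for
  identical, 2 for uncorrelated, 4 for anti-correlated maps); the
  conventional `sqrt(2(1−r))` is available as an option.  Its one-sided
  randomization swaps the two maps' values channel-wise at random (null of
  no topographic difference), 100 permutations by default.
* Repeated-measures ANOVA (one-way) is backed by pingouin; Mauchly's test
  gates the Greenhouse–Geisser correction (applied when p < 0.05), and the
  F statistic is cross-checked in the tests against explicit sums of
  squares.
* Spearman correlations use tie-corrected ranks (scipy) with permutation
  p-values.

## 5. Problem sizes and Monte-Carlo tolerances

The validation suite uses these sizes (chosen to exercise each property
decisively while keeping a full run to a few minutes):

| analysis | size |
|---|---|
| PPM oracle equivalence | exhaustive ≤ length 6 / alphabet 3; 250 sampled corpora ≤ length 12 / alphabet 4 |
| sampling consistency | 20 000 symbols |
| kernel recovery | 6 features, 64 Hz, 10 × 150 s trials, snr 1 (independent 1/f feature trains — see below) |
| detection cohort | 20 subjects, 10 pieces × 330 notes × 3 repetitions, 8 channels, snr 0.005 |
| null-control replicates | 20 cohorts of 6 subjects, 4 pieces × 180 notes |
| memory sweep | 8 subjects, 6 pieces × 240 notes × 2 repetitions, snr 0.02; 10 flat replicates of 5 subjects |
| lag relevance | 10 × 40 s trials; 100 pure-noise runs at 500 permutations |
| ERP | 200 notes (effect); 200 null replicates of 120 notes at 500 permutations |

Kernel recovery uses independently varying 1/f-noise feature trains rather
than the music features: the envelope and its rectified derivative are
strongly collinear and the four expectation trains share onset support, so
per-feature kernel attribution from naturalistic stimuli is bounded
(~0.92 for the envelope) by the stimulus itself, regardless of estimator.

Rejection-rate checks (FDR, family-wise error, ERP null) compare the
observed rate against the nominal level plus two binomial standard errors:
a correctly calibrated test rejects at ~α, so a finite-replicate estimate
fluctuates by ~sqrt(α(1−α)/R).

## 6. Known limitations

* The LTM for synthetic runs is trained on a corpus from the same Markov
  source as the stimuli — intentionally well-specified.  Real corpora are
  not generated by the listener's model; transfer effects are untested.
* The entropy-weighted LTM/STM combination is one member of a family; no
  claim is made that it matches any specific reference implementation
  numerically.
* The forward model is linear and time-invariant by construction, matching
  the TRF's assumptions; it cannot reveal how the analyses behave under
  model misspecification beyond the additive 1/f noise.
* Channel "topographies" are random gain patterns; no spatial claims
  (lateralization, source location) are meaningful in this framework.
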