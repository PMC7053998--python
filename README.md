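# melodytrf

Melodic-expectation features and temporal response function (TRF) encoding
models for continuous neural recordings, with a synthetic forward-model
simulation framework that supplies ground truth for every analysis stage.

## The problem

When people listen to music, cortical activity tracks not only the sound's
acoustics but also how *expected* each note is.  A listener's expectations
can be modeled statistically: a variable-order Markov model over note
sequences assigns each note a probability given its context, from which two
information-theoretic quantities follow —

* **surprise** (information content) `S(e_i) = -log2 p(e_i | e_1..i-1)`,
* **entropy** (pre-observation uncertainty) `H = Σ_e p(e)·(-log2 p(e))`,

each computed for two viewpoints, pitch and note onset-time, giving four
per-note features: `S_p`, `H_p`, `S_o`, `H_o` (bits).  If cortical responses
encode expectations, then regressors carrying these values should predict
neural recordings *beyond* what acoustics alone (envelope `Env` and its
half-wave rectified derivative `Env'`) can.

The package implements that entire argument as testable code:

1. **Sequence model** (`melodytrf.ppm`, `melodytrf.expectation`) —
   prediction-by-partial-matching (PPM, escape method C) with unbounded
   context; a long-term model (LTM) trained on a held-out corpus combined
   with an online, strictly causal short-term model (STM) by
   entropy-weighted geometric mixing; memory-restricted STM variants
   (1–32 bars) and a value-shuffle control.
2. **Feature encoding** (`melodytrf.features`) — feature sets `A` (Env,
   Env'), `AM` (+ four expectation impulse trains), `AM_shu`, `AM_p`,
   `AM_o` at the neural sampling rate.
3. **Encoding models** (`melodytrf.trf`) — lagged ridge-regression TRFs,
   leave-one-out cross-validation with nested regularization choice,
   feature-set comparison, backward elimination of 50 ms lag windows
   (`r_LOSS`), and weight contrasts (surprise vs entropy, pitch vs onset).
4. **ERP analysis** (`melodytrf.erp`) — note-locked epochs, envelope-matched
   note selection (±5% of the median peak), top/bottom-20% surprise splits,
   0–200 ms power contrasts.
5. **Preprocessing** (`melodytrf.preprocessing`) — 1–8 Hz zero-phase
   Butterworth band for low-rate streams, 70–150 Hz Hilbert high-gamma
   power for intracranial-like streams, mastoid re-referencing, variance
   outlier channel repair, music-responsive electrode selection (Cohen's
   d > 0.5 vs silence).
6. **Statistics** (`melodytrf.stats`) — exact/randomized permutation tests,
   Benjamini–Hochberg FDR, Cohen's d, topographic dissimilarity
   `DISS = 2(1-r)`, Spearman correlations, repeated-measures ANOVA with
   Greenhouse–Geisser correction.
7. **Synthetic data** (`melodytrf.markov`, `melodytrf.synth`) — melodies
   from explicit Markov tables (closed-form per-note surprise/entropy),
   optional phrase-level motif repetition, attack–decay note envelopes, and
   multichannel recordings built by convolving feature trains with known
   kernels (acoustic ~50 ms latency, expectation ~200 ms) plus 1/f noise;
   simulated cohorts with per-subject noise, gains and SNR spread.
8. **Orchestration** (`melodytrf.pipeline`, `melodytrf.midi`) — end-to-end
   configured runs, standard-MIDI reading/writing for monophonic melodies.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
tidy tables under `results/`.  The headline analysis:

```bash
python analysis/02_fit_encoding_models.py --seed 1
```

prints

```
cohort: 20 subjects, 30 trials each
  mean held-out r (A): 0.0775
  mean held-out r (AM): 0.0841
  mean held-out r (AM_shu): 0.0769
expectation enhancement (AM - A): 0.0066 (p = 0.0001, d = 3.30, 20/20 subjects positive)
shuffle control (AM_shu - A): -0.00060 (p = 0.0001; detected = False)
```

Reading this: acoustic envelope tracking alone predicts held-out recordings
at r ≈ 0.08 (the realistic low-rate range).  Adding the four expectation
features raises prediction for every one of the 20 simulated subjects
(Δr = +0.0066, paired permutation p = 1e-4) — the expectation signal placed
in the simulation at 200 ms latency is recovered.  The shuffle control has
the same dimensionality and value distribution but carries no expectation
information: its Δr is slightly *negative* (the out-of-sample cost of six
uninformative regressor blocks), so no enhancement is detected — the
comparison is specific, not a dimensionality artifact.

The memory-restriction control (`analysis/03_memory_sweep.py --seed 1`), on
melodies with phrase-level repetition:

```
median enhancement by STM memory span:
   1.0 bars: +0.0005
   2.0 bars: +0.0001
   4.0 bars: +0.0004
   8.0 bars: +0.0035
  16.0 bars: +0.0131
  32.0 bars: +0.0207
   inf bars: +0.0324
per-subject rank trend: mean rho = 0.82, p = 0.00781
RM-ANOVA across memory levels: F = 65.09, p = 3.29e-06 (greenhouse-geisser)
```

The enhancement grows with the short-term model's memory span: expectations
computed with more local context describe the responses better, because the
melodies' cross-bar structure only becomes predictable with enough memory.

The other drivers: `01_simulate_stimuli.py` (melodies, MIDI, expectation
tables), `04_lag_relevance.py` (backward elimination localizing a response
kernel to its true 200–250 ms support), `05_erp_contrast.py`
(envelope-matched high-vs-low surprise ERP power, p ≈ 5e-4 with the groups'
mean peak envelopes within 2%), `06_piece_trend.py` (per-piece mean onset
surprise vs envelope tracking, Spearman rho = 1.00 under graded response
gain).

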