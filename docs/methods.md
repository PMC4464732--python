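# Methods

## The experimental design being modelled

Each *sequence* comprises eight trials: five audiovisual (AV) trials,
one auditory probe, two visual trials. Every AV trial is independently
matching or discrepant; in discrepant trials the sound is offset from
the light by `discrepancy_deg` (default 12°, the value at which
aftereffects are reliably observable). Stimulus base positions are
drawn uniformly within one of three azimuth areas ([−5°, +5°],
[−20°, −10°], [+10°, +20°]); all eight trials of a sequence share one
area. Each subject sees all 32 sequence types `reps_per_type` times
(default 9, hence 288 sequences, 288 auditory probes and 576 visual
trials per subject) in uniformly shuffled order. Counterbalancing is by
*mirror group*: for half the subjects (the extra subject of an odd
cohort included) the light of discrepant trials sits right of the
sound, for the other half left; analyses negate the left group's shifts
so both pool.

Design choices where the protocol is underdetermined, made once and
kept:

* **Base positions are continuous** within an area (the apparatus pans
  sounds between speakers); only *responses* are quantized to the 1°
  LED grid of the response display.
* **Areas are assigned to sequences uniformly at random**, not balanced
  (9 repetitions do not divide by 3 areas; every analysis pools areas,
  so exact balance is irrelevant).
* Inter-trial timing, fixation, breaks and the familiarization block
  are not modelled; no analysis depends on them.

## The synthetic observer

The observer generates responses with the statistical structure the
paradigm reports, so every downstream stage is testable without human
data:

| parameter | default | meaning |
|---|---|---|
| `sigma_V` | 0.73° | visual response SD |
| `sigma_A` | 2.5° | auditory response SD |
| `capture_fraction` | 0.35 | fraction of the AV discrepancy pulling the AV auditory response toward the light (0.35 × 12° = 4.2°, matching the observed ≈ 4.16° bias) |
| `baseline_shift` | 0° | constant long-term shift toward the light side |
| `w_SQ5`, `w_D` | 0.88°, 3.42° | generative aftereffect weights of the probe |
| `quantize` | true | round responses to the 1° LED grid |

The probe response mean is
`auditory_pos + s·(baseline_shift + w_SQ5·SQ5 + w_D·D)` with `s = ±1`
toward the light side of the subject's group; noise is i.i.d. Gaussian.
Modelling decisions:

* **No intercept in the aftereffect** (`baseline_shift` defaults to 0).
  Real cohorts show a residual ≈ 1.5° shift even after all-matching
  sequences, which an intercept-free weighted sum cannot produce; the
  parameter exists to explore that, but no fitted value is available,
  so it is not guessed.
* **No memory beyond the current sequence and no time trend** — the
  paradigm finds no block effect, and the block ANOVA in
  `shift_analysis` is the tool that would detect one.
* AV visual responses share `sigma_V` with unimodal trials; the higher
  AV visual variance seen in humans (attributed to divided attention)
  is not modelled.

What passing tests on this observer do **not** show: real responses are
not exactly Gaussian, real subjects have idiosyncratic biases and a
long-term recalibration component, and co-localization judgments have
large individual variability. The generator demonstrates that the
*pipeline* recovers what it should under the stated noise model, not
that the model is true of humans.

## Shift statistics

The probe shift is `resp − pos`, multiplied by −1 for the
light-left-of-sound group. Per-sequence-type means pool subjects and
areas (a per-subject variant is exposed via
`shifts_by_sequence_type(..., per_subject=True)`). The property/shift
Pearson screen operates on the 32 type means — the same system the
modelling stage uses; per-trial correlation is a possible alternative
reading that is deliberately not the default. Time-course ANOVA blocks
are contiguous in presentation order (288 probes → 4 blocks of 72).
Co-localization equality is exact on the integer LED grid, which is
why response quantization is on by default. `one_sample_t` works from
printed summary statistics (mean, SD, n) so published condition tables
can be re-tested without raw data.

## Weighted-sum model and model selection

The fit is ordinary least squares without intercept via the normal
equations `W = (PᵀP)⁻¹PᵀSH`; an intercept-free model predicts exactly
zero shift after an all-matching sequence, a documented consequence,
not patched. Both squared Pearson and squared Spearman correlations
between prediction and observation are reported, as both appear in
practice for this quantity; neither includes an intercept.

Rank deficiency: `D` is an exact linear combination of `SQ1…SQ5`, so
two of the seven canonical candidate sets are collinear.
`PropertyWeightRegressor` refuses such designs by default, naming the
collinear columns, because non-unique weights are scientifically
meaningless. Model *comparison*, however, only needs the residual sum
of squares, which is unique regardless; `compare_models` therefore fits
collinear candidates by minimum-norm least squares and counts K as the
number of *named* properties, keeping all seven canonical candidates
comparable.

Information criteria use `n = 32` (the number of per-type equations —
the only n consistent with `n/K < 40` for K up to 7) and
`AICc = AIC + 2K(K+1)/(n−K−1)`. A perfect fit (RSS ≈ 0, which happens
on noiseless synthetic data) makes `ln(RSS/n)` diverge; it is reported
as a degenerate benchmark (`PerfectFitError`) rather than mapped to
−∞. Akaike weights are reported at full precision and rounded to three
decimals in tabular output.

## Numerical choices

* Quantization uses `numpy.round` (ties to even); ties occur with
  probability zero under continuous noise.
* Rank is assessed by `numpy.linalg.matrix_rank`'s default tolerance;
  full-rank systems are solved through the normal equations, matching
  the pseudo-inverse definition, and cross-checked against
  `numpy.linalg.lstsq` in the tests.
* `compare_models` treats RSS ≤ 1e−10 as a perfect fit.
* The auditory limit check in `apply_discrepancy` is inclusive (a
  20° base with 12° discrepancy lands exactly on the ±32° limit).

## Problem sizes

The replicate studies used by the tests and the acceptance script are
full-scale cohorts (11 subjects × 288 sequences): 50 replicates for
parameter recovery and 200 for selection consistency, enough for the
Monte-Carlo standard errors to be well below the effects being checked
(~0.01° on recovered weights; binomial SE ≈ 3.5 % on the selection
rate).

## Known limitations

* The observer cannot reproduce empirical quantities that depend on
  human idiosyncrasies: the ≈ 1.48° shift after all-matching sequences
  (no intercept), the 5 % co-localization rate in discrepant trials,
  or the exact empirical AICc values — those enter only as reference
  inputs to the weight arithmetic.
* Generalized sequence lengths are supported by the feature extractor
  and enumeration, but the schedule builder is fixed at five AV trials
  per sequence.
* No causal-inference observer, psychometric-curve fitting, normality
  testing, regularization or per-subject random effects.
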