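# Methods

This note documents the statistical procedures `itpopcode` implements, the
generative model behind its synthetic data, the numerical choices made where
the mathematics leaves room, and what the package's tests do and do not
establish about real recordings.

## Data model

A dataset is a table of trials, one per stimulus presentation per neuron.
Each trial carries spike times in milliseconds relative to stimulus onset,
restricted to [−500, 600] ms, plus task (passive fixation vs active
two-alternative categorization), stimulus identity, category (body /
non-body) and subcategory, absolute signal level (90, 70, 55, 40% of pixels
intact, or 0% = full noise), behavioural outcome and choice, and the
category of the preceding stimulus in the block. Spike-count windows are
half-open `[start, end)` so that a tiling partition counts every spike
exactly once; a spike exactly at a window's end belongs to the next window.

Fixed analysis windows: evoked responses for selectivity use [70, 420) ms;
the categorization index, decoder, and choice probability use [150, 350) ms;
sliding time courses use 100-ms windows every 5 ms, plotted at bin centres,
offset by the mean over windows centred in [−400, 0] ms; window-based
significance compares against a [−200, 0) ms baseline. The two baseline
conventions are deliberately distinct.

Full-noise stimuli contain no category, but the trial schema requires one;
they are assigned balanced nominal labels with subcategory `"noise"`. No
analysis interprets those labels: full-noise trials are excluded from CI
and decoding conditions and used only for choice probability, where trials
are grouped by *choice*, not category.

## Selectivity index

`SI = (μ(B) − μ(O)) / (μ(B) + μ(O))` over evoked spike counts, computed per
signal level on correct trials of the active task and then averaged across
the four levels (so each difficulty contributes equally despite unequal
correct-trial survival); a pooled mode is available. Neurons with SI > 0
are body selective; SI strictly inside (−0.037, 0.037) is labelled
non-selective. SI is antisymmetric under category relabelling and invariant
to rescaling all rates — both property-tested.

Two matching controls accompany the grouping. Mean-|SI| matching
iteratively removes the highest-|SI| neuron from whichever group has the
larger mean |SI| until the means agree within 0.005 (floor: 10 neurons).
Rate matching pairs stimuli across tasks by identity and removes the
stimulus with the largest active response until a two-sided signed-rank
test on the per-stimulus (passive, active) response pairs exceeds p = 0.05;
whole stimuli, not individual trials, are removed, and the procedure can
legitimately fail (with a diagnostic) for strongly task-modulated neurons.
All-zero difference vectors are treated as p = 1 (no detectable effect),
which is also what the stopping rule requires.

## Pseudo-populations

Neurons recorded non-simultaneously are combined per condition (task ×
signal level × outcome filter): the common per-category trial count is the
floored mean of per-neuron per-category counts, neurons with at least that
many trials in both categories are eligible, and each repetition samples
that many trials per category per neuron without replacement, concatenating
counts column-wise so row k of a category joins the k-th sampled trial of
every neuron. Row alignment is arbitrary — non-simultaneous data carry no
trial correspondence — which implies zero noise correlation in expectation.
Sampling and the downstream statistic are repeated (1000× by default) to
form the bootstrap distribution; the reported SD is the SD of those
repetitions and p-values are percentile-based with an add-one correction,
`p = (count + 1)/(n_reps + 1)`, so no p-value can fall below `1/(n_reps+1)`.
Eligibility is established once per condition, not re-drawn per repetition.

A caveat the implementation makes visible: when a neuron's available trial
count equals the required count, "sampling" returns the same trials every
repetition, and with many such neurons the bootstrap distribution is
unrealistically narrow. Sparse conditions (wrong trials at high signal)
live near this regime; their percentile tests should be read with that in
mind.

## Categorization index

For pseudo-trial points x ∈ R^N with category sets C_i (sizes n_i, means
m_i, grand mean m):

- per-category scatter `S_i = Σ_{x∈C_i} (x − m_i)(x − m_i)ᵗ`
- within-category scatter `S_W = Σ_i S_i`
- between-category scatter `S_B = Σ_i n_i (m_i − m)(m_i − m)ᵗ`
- `CI = Σ_k λ_k`, the eigenvalues of `S_W⁻¹ S_B`.

`S_W + S_B` equals the total scatter (tested as an algebraic identity);
CI is invariant under invertible linear maps of the neural space; for two
categories exactly one eigenvalue is nonzero and CI equals the closed form
`(n₁n₂/n) dᵗS_W⁻¹d`, `d = m₁ − m₂`; in one dimension CI equals
`SS_between/SS_within = F (c−1)/(n−c)`. These three independent routes are
cross-checked in the tests at 1e−10/1e−8 tolerances.

**Inversion.** The single biggest numerical decision. When the number of
pseudo-trials comfortably exceeds the dimension, S_W is inverted through a
ridge, `S_W + ε·(tr S_W / N)·I` with ε = 1e−6 (configurable); the ridge
perturbs CI by a relative 1e−6 and is ignorable. When S_W is numerically
rank-deficient — fewer pseudo-trials than neurons, the regime of sparse
wrong-trial conditions — ridge inversion would scale CI by 1/ε, so the
implementation switches to a pseudo-inverse (rcond 1e−10), which restricts
the ratio to the subspace the data span and keeps CI finite, at the cost of
high variance. Eigenvalues below −1e−10 (relative) are clipped to zero;
larger negative eigenvalues raise an error instead of being hidden.

CI is computed on raw spike counts (the formulas operate on responses
directly); no z-scoring is applied. Two-category labelling is the default;
the scatter machinery accepts any number of classes, so six-subcategory
decompositions are available.

**Bias and contrasts.** Like any Fisher-style ratio, CI carries a
dimension- and trial-count-dependent small-sample inflation (roughly
N/(n−N) for two balanced categories). Raw per-condition values are reported
as-is, matching the convention of reporting un-offset window values; the
evoked-vs-baseline difference cancels the bias for significance testing.
For *between-condition* contrasts — the enhancement index
`(CI_correct − CI_passive)/(CI_correct + CI_passive)` and its decoding
analogue — the two conditions are built over the intersection of their
eligible neuron sets and a shared per-category trial count (the smaller of
the two mean-rule counts), because both the signal content and the bias
would otherwise differ mechanically between numerator terms. Enhancement is
computed per bootstrap repetition (independent samples of each condition,
paired by repetition index) and summarized by its mean ± SD.

## Decoding

A linear-kernel SVM (regularization C = 1, the conventional default; the
choice is recorded in the result objects) with stratified fivefold
cross-validation, shuffled with a seeded generator. Features are the window
spike counts, z-scored using training-fold statistics only — this prevents
high-rate neurons dominating the margin and makes the decoder exactly
invariant to per-neuron affine rescaling (tested). Accuracy is the mean
over folds; the confusion matrix is summed over held-out folds, and
per-category accuracy is per-true-class recall from its rows. Bootstrap
distributions, time courses, and the enhancement index mirror the CI
machinery; significance is tested against the 0.5 chance level.

## Choice probability

Responses on full-noise trials are split by choice; CP is the probability
that a random body-choice response exceeds a random non-body-choice
response, ties counted half — computed from average ranks
(`U/(n₁n₂)`), which equals the trapezoidal area under the empirical ROC
curve (cross-checked against an independent implementation). CP is
invariant under strictly monotone transforms of the responses, and the two
orientations sum to 1 on tie-free data.

The null shuffles choice labels preserving class counts, 1000 permutations
by default, vectorized through a single rank computation. A neuron is
flagged when its CP exceeds the 90th percentile of its null (one-tailed);
under the null this flags ~10% of neurons, which the calibration test
verifies. Orientation is toward the neuron's preferred category by default
(so informative neurons of either polarity score above 0.5), with raw
body-choice orientation available; the CP response window is [150, 350) ms,
matched to the CI window for comparability. Within flagged neurons,
single-unit CI is compared between correct-active and passive trials by a
two-sided signed-rank test.

## Geometry

Per-stimulus mean responses (stimuli × neurons) are centred and projected
onto the top two eigenvectors of the neural covariance; the explained
variance share of the plane is reported. Component signs are fixed
deterministically (largest-magnitude loading positive). Each category's
projected points are summarized by an ellipse centred at their mean with
semi-axes twice the square roots of the 2-D covariance eigenvalues; for a
Gaussian cloud this contains 1 − e⁻² ≈ 86.5% of points (the coverage test
asserts this value). Projections are fit per condition.

## Ensemble curves

Neurons are ordered (by SI ascending or descending, or by single-unit CI
descending — the default for the units-per-fraction analysis, since the
most informative units are added first), and CI is evaluated on every
prefix of the order within each bootstrap repetition, sharing trials and
ridge across prefix sizes so the curve is comparable across dimensionality.
The number of units explaining a fraction f of the ultimate CI is the
smallest k with `CI(k) ≥ f · CI(N)`, evaluated inside each repetition
against that repetition's own all-units value, then averaged (mean ± SD);
non-integer reported values arise from this averaging. The estimator
inherits CI's dimension-dependent inflation: with few trials the curve
keeps rising mechanically as units are added, so carrier counts are only
recoverable when the per-unit signal dominates the bias ramp — the tests
demonstrate both the recovery (with ample trials) and, implicitly, the
regime where it degrades.

## The synthetic generator

The generator produces the full factorial design: 90 stimuli per category
(30 per subcategory) at each of four signal levels plus 90 full-noise
stimuli, presented once per task per neuron in 90-trial blocks with a
per-neuron random order (presentation order fills `preceding_category`).
Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `n_neurons` | 123 | population size; 75 body-/48 non-body-selective in expectation, 36 with near-zero SI |
| `baseline_rate_mean` | 10 sp/s | gamma-distributed across neurons (shape 4); yields ~2 spikes per 200-ms window, the observed range for IT under these stimuli |
| `si_spread` | 0.15 | half-normal spread of target |SI| outside the non-selective band; tuning strengths (sp/s at 100% signal) are solved from the targets by bisection given each baseline |
| `gain_strength`, `gain_curvature` | 2.2, 1.5 | attended-trial task gain `1 + 2.2·(1−s/100)^1.5` on the tuning component; strength and curvature set so the resulting enhancement-index profile spans ≈ 0.55 → 0.05 from 40% to 90% signal, the magnitude a difficulty-dependent enhancement of this kind exhibits |
| `attention_reliability`, `attention_session_sd` | 0.7, 0.18 | probability a trial is attended; beta-distributed across sessions, the dominant source of across-session performance differences |
| `unattended_gain` | 0.3 | tuning multiplier on unattended active trials: attention diverted from the stimulus suppresses encoding below the passive-viewing level |
| `readout_alignment` | 0.45 | cosine between the choice readout and the signed-tuning axis; the rest of the readout is a random direction, so choices are informed but suboptimal |
| `decision_noise` | 0.5 | SD of additive evidence noise, in units of the neural evidence SD (lognormally jittered across sessions, σ = 0.3) |
| `lapse_rate` | 0.005 | probability of replacing the choice with a coin flip |
| `dispersion` | 1.0 | count noise is Poisson; values > 1 switch to gamma-mixed (over-dispersed) counts |

Rates are piecewise constant: baseline on [−500, 70), baseline plus
`(s/100) · tuning · gain` for the preferred category on [70, 420), baseline
after; spike times are uniform within segments. Choices arise from a linear
readout of the whole population's evoked counts for that presentation (the
recorded neuron contributes its own sampled count; unrecorded neurons'
counts are drawn from the same rate model) plus decision noise. The readout
pools are balanced by subtracting, from the weight vector, the component of
the unsigned-tuning direction orthogonal to the signed-tuning axis — this
zeroes the category bias of the criterion in every attention state without
changing the evidence separation, so per-category accuracy is equalized by
construction and the 0%-signal choice rate is one half. Full-noise trials
are rewarded by a fair coin.

This architecture makes the study's qualitative phenomena *mechanistic*
rather than imposed: correct trials are enriched in attended
(gain-enhanced) responses, so category information is enhanced most where
attention matters most (low signal); wrong trials are enriched in
unattended or noise-dominated responses, so their category information
degrades by selection, not relabelling; and because each neuron's own count
enters the evidence, neurons coupled to the readout show above-chance
choice probability on full-noise trials.

**What the generator does not emulate.** Stimulus-identity variability
(every image of a category at a level shares one rate, so per-stimulus
response PCA lacks the strong shared "stimulus effectiveness" axis real IT
data show, and the two-component variance share is correspondingly lower);
response latency jitter and temporal dynamics beyond a boxcar; inter-neuron
noise correlations (off by default and irrelevant to pseudo-populations,
which destroy them anyway); reaction times and eye movements; session
truncation (every simulated neuron completes all 810 trials per task,
whereas real sessions vary). Passing tests therefore certify the analysis
chain and its statistical calibration on a faithful *design*, not parameter
estimates for any real neural population.

**Variability at desk scale.** A single 123-neuron dataset carries
irreducible trial noise: per-level enhancement indices wobble by ±0.05–0.1,
and sparse wrong-trial conditions flirt with the degenerate-bootstrap
regime. With default parameters the full battery of qualitative checks
(passive CI ordering, enhancement–signal correlation below −0.9, wrong-trial
non-significance at all four levels) held in 7 of 8 random generator seeds
examined during development; the packaged tests fix the dataset seed.

## Reporting conventions

Bootstrap results carry the estimate, the samples, their SD (labelled SD of
bootstrap samples — the quantity plotted as error bars), percentile 95%
intervals, and the add-one percentile p-value; where a figure-style "SEM"
or "SE" is wanted, it can be derived from the samples, and the objects
expose all three rather than guessing which convention a reader expects.
No multiple-testing correction is applied anywhere. All randomness flows
from explicit integer seeds through counter-derived substreams
(`SeedSequence((seed, key...))`), so bootstrap repetitions are
order-independent and every reported number is bit-reproducible.
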