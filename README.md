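# itpopcode

Population-coding analysis of inferior temporal (IT) cortex spiking data
recorded — or simulated — during passive viewing and active categorization
of degraded body/non-body images.

Visual object categories are encoded by the joint activity of many IT
neurons. When the images are degraded (a fraction of pixels replaced by
noise), single neurons carry little category information, and the question
becomes how the *population* code behaves: how much category structure it
holds at each signal level, whether performing the categorization task
enhances that structure, and whether the enhancement tracks the animal's
choices. `itpopcode` implements the full analysis chain for this question,
aimed at systems neuroscientists working with trial-wise single-unit
recordings:

- **Selectivity indexing** — per neuron, `SI = (μ(B) − μ(O)) / (μ(B) + μ(O))`
  over evoked spike counts (70–420 ms), with polarity and non-selective-band
  grouping, top-K / threshold selection, mean-|SI| matching, and
  rate-matching controls.
- **Pseudo-population construction** — neurons recorded in different
  sessions are combined by the mean-rule trial matching, per-neuron random
  sampling without replacement, and column-wise concatenation into
  pseudo-trials in R^N, repeated 1000× as a bootstrap.
- **Categorization index (CI)** — the core statistic: with within-category
  scatter `S_W = Σ_i Σ_{x∈C_i} (x−m_i)(x−m_i)ᵗ` and between-category scatter
  `S_B = Σ_i n_i (m_i−m)(m_i−m)ᵗ`,

  `CI = Σ λ_i`,  the sum of the eigenvalues of `S_W⁻¹ S_B`

  — a Fisher-discriminant-style ratio of between- to within-category
  variability, equal to `(n₁n₂/n) dᵗS_W⁻¹d` for two categories and to
  `SS_between/SS_within = F·(c−1)/(n−c)` in one dimension. Time courses
  (100-ms windows, 5-ms steps), baseline offsets, evoked-vs-baseline
  significance, and the task-enhancement index `(CI_c − CI_p)/(CI_c + CI_p)`
  are built on top.
- **Linear decoding** — linear-kernel SVM, stratified fivefold
  cross-validation, per-category (confusion-matrix) accuracy, and the
  matching enhancement index for classification accuracy.
- **Choice probability** — ROC area separating a neuron's full-noise-trial
  responses by the model's (or animal's) choice, with a 1000-permutation
  one-tailed null and the CI comparison within high-CP neurons.
- **Geometry and ensemble curves** — two-component projections with 2-SD
  category ellipses; neuron-adding curves and the number of units explaining
  25/50/75/95% of the ultimate CI.
- **Synthetic data** — a generator that emulates the experiment end to end
  (90 stimuli per category at signal levels 90/70/55/40% plus 90 full-noise
  images, 70-ms presentations, passive and active tasks in 90-trial blocks)
  with category tuning scaled by signal level, an attention-gated
  difficulty-dependent task gain, and a mechanistic linear-readout choice
  model, so the whole chain runs and is testable without any recordings.

## Worked example

`examples/04_task_enhancement.py` generates the default synthetic
experiment (123 neurons, 810 trials per task per neuron), computes CI in
correct-active vs passive trials over the body-selective neurons, and prints:

```
enhancement index (C - P)/(C + P), 200 bootstrap reps:
   40% signal: CI_correct =  2.37  CI_passive =  1.02  index = +0.395 +/- 0.082
   55% signal: CI_correct =  2.28  CI_passive =  1.78  index = +0.123 +/- 0.096
   70% signal: CI_correct =  2.27  CI_passive =  1.85  index = +0.102 +/- 0.086
   90% signal: CI_correct =  3.39  CI_passive =  3.87  index = -0.066 +/- 0.102
index vs signal level: Pearson r = -0.945

wrong trials (evoked minus baseline CI):
   40% signal: delta-CI =   6.49  p = 0.507
   ...
```

Reading the numbers: category information in the population is *enhanced*
during correctly categorized active trials relative to passive viewing, and
the enhancement grows as the stimulus gets harder (the index rises from
≈ 0 at 90% signal to ≈ 0.4 at 40%, hence the strong negative correlation
with signal level), while wrong trials carry no significant category
information at any level — the qualitative signature the pipeline is built
to measure. Each `± value` is the SD of the statistic across bootstrap
pseudo-populations, and p-values are percentile-based (the fraction of
bootstrap repetitions contradicting the claim).

The other scripts in `examples/` walk through one capability each:
dataset generation and psychometrics, selectivity grouping, the CI from a
hand-checkable four-point example up to population scale, decoding, choice
probability, projection geometry, and neuron-adding curves.

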