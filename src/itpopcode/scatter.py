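"""Scatter-matrix category separability: the categorization index (CI).

For pseudo-trial points x in R^N with category labels, define per-category
means m_i, the total mean m, per-category scatters
S_i = sum_{x in C_i} (x - m_i)(x - m_i)^t, the within-category scatter
S_W = sum_i S_i, and the between-category scatter
S_B = sum_i n_i (m_i - m)(m_i - m)^t.  The categorization index is the sum
of the eigenvalues of S_W^{-1} S_B -- a Fisher-discriminant-style ratio of
between- to within-category variability that is invariant to invertible
linear maps of the neural space.  For two categories exactly one
eigenvalue is nonzero and CI equals the closed form
(n1 n2 / n) d^t S_W^{-1} d with d = m1 - m2; in one dimension CI equals
SS_between / SS_within = F (c-1)/(n-c).

S_W is inverted with a small ridge, S_W + eps (tr S_W / N) I, eps = 1e-6 by
default; when S_W is numerically rank-deficient (fewer pseudo-trials than
neurons, as happens for sparse wrong-trial conditions) a pseudo-inverse is
used instead, which restricts the ratio to the subspace the data actually
span rather than letting the ridge term dominate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .core import (
    CI_WINDOW,
    SIGNIFICANCE_BASELINE,
    TIMECOURSE_BASELINE,
    AnalysisWindow,
    WindowLike,
    as_window,
    counts_in_window,
    sliding_windows,
)
from .population import Condition, PopulationMatrix, PopulationSampler
from .stats import BootstrapResult, rng_stream, summarize_bootstrap

RIDGE_EPSILON = 1e-6
_NEG_EIG_TOL = 1e-10


@dataclass
class ScatterDecomposition:
    """All intermediate quantities of the three-step CI construction."""

    category_labels: list
    category_means: np.ndarray  # (c, N)
    total_mean: np.ndarray  # (N,)
    per_category_scatters: np.ndarray  # (c, N, N)
    within_scatter: np.ndarray  # (N, N)
    between_scatter: np.ndarray  # (N, N)
    eigenvalues: np.ndarray
    ci: float
    counts: np.ndarray  # n_i per category
    n: int
    c: int
    ridge: float

    @property
    def total_scatter(self) -> np.ndarray:
        return self.within_scatter + self.between_scatter


def _regularized(s_w: np.ndarray, ridge: float) -> np.ndarray:
    if ridge <= 0:
        return s_w
    n_dim = s_w.shape[0]
    return s_w + ridge * (np.trace(s_w) / n_dim) * np.eye(n_dim)


def separability_eigenvalues(
    s_w: np.ndarray, s_b: np.ndarray, n_rows: int, c: int, ridge: float = RIDGE_EPSILON
) -> np.ndarray:
    """Eigenvalues of S_W^{-1} S_B, descending, tiny negatives clipped.

    Uses the symmetric-definite generalized eigenproblem when the
    (regularized) S_W is positive definite and enough pseudo-trials exist;
    otherwise falls back to a pseudo-inverse.
    """
    n_dim = s_w.shape[0]
    rank_ok = (n_rows - c) >= n_dim
    if rank_ok:
        s_wr = _regularized(s_w, ridge)
        try:
            vals = sla.eigh(s_b, s_wr, eigvals_only=True)
        except (sla.LinAlgError, np.linalg.LinAlgError):
            rank_ok = False
    if not rank_ok:
        vals = np.linalg.eigvals(np.linalg.pinv(s_w, rcond=1e-10) @ s_b)
        vals = np.real(vals)
    vals = np.sort(vals)[::-1]
    top = np.max(np.abs(vals)) if vals.size else 0.0
    if top > 0 and np.min(vals) < -_NEG_EIG_TOL * max(top, 1.0) * 1e4:
        # far-negative eigenvalues indicate a numerically singular problem
        raise np.linalg.LinAlgError(
            "within-category scatter is numerically singular beyond "
            "regularization; use fewer neurons or more trials"
        )
    return np.clip(vals, 0.0, None)


def scatter_decomposition(
    x: np.ndarray | PopulationMatrix,
    labels: np.ndarray | None = None,
    ridge: float = RIDGE_EPSILON,
) -> ScatterDecomposition:
    """Means, scatters, and eigenvalues of one labelled population matrix."""
    if isinstance(x, PopulationMatrix):
        if labels is None:
            labels = x.labels()
        x = x.counts
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2:
        raise ValueError("population matrix must be 2-D (rows x neurons)")
    cats = sorted(pd.unique(labels).tolist())
    if len(cats) < 2:
        raise ValueError("at least 2 categories required")
    n, n_dim = x.shape
    means, scatters, counts = [], [], []
    for cat in cats:
        rows = x[labels == cat]
        if rows.shape[0] < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 rows")
        mi = rows.mean(axis=0)
        centered = rows - mi
        means.append(mi)
        scatters.append(centered.T @ centered)
        counts.append(rows.shape[0])
    means = np.array(means)
    counts = np.array(counts)
    total_mean = (counts[:, None] * means).sum(axis=0) / n
    s_w = np.sum(scatters, axis=0)
    dev = means - total_mean
    s_b = (counts[:, None, None] * dev[:, :, None] * dev[:, None, :]).sum(axis=0)
    vals = separability_eigenvalues(s_w, s_b, n, len(cats), ridge)
    return ScatterDecomposition(
        category_labels=cats,
        category_means=means,
        total_mean=total_mean,
        per_category_scatters=np.array(scatters),
        within_scatter=s_w,
        between_scatter=s_b,
        eigenvalues=vals,
        ci=float(vals.sum()),
        counts=counts,
        n=n,
        c=len(cats),
        ridge=ridge,
    )


def categorization_index(decomposition: ScatterDecomposition) -> float:
    """CI = sum of the eigenvalues of S_W^{-1} S_B (nonnegative)."""
    return float(np.sum(decomposition.eigenvalues))


def ci_of_matrix(
    x: np.ndarray | PopulationMatrix,
    labels: np.ndarray | None = None,
    ridge: float = RIDGE_EPSILON,
) -> float:
    """Convenience: CI of one labelled matrix."""
    return scatter_decomposition(x, labels, ridge=ridge).ci


def closed_form_ci_two_class(
    x: np.ndarray, labels: np.ndarray, ridge: float = RIDGE_EPSILON
) -> float:
    """Rank-1 closed form (n1 n2 / n) d^t S_W^{-1} d for two categories.

    Independent of the eigenvalue path; used as an internal oracle.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    cats = sorted(pd.unique(labels).tolist())
    if len(cats) != 2:
        raise ValueError("closed form applies to exactly two categories")
    a = x[labels == cats[0]]
    b = x[labels == cats[1]]
    s_w = (a - a.mean(0)).T @ (a - a.mean(0)) + (b - b.mean(0)).T @ (b - b.mean(0))
    d = a.mean(0) - b.mean(0)
    n1, n2 = len(a), len(b)
    s_wr = _regularized(s_w, ridge)
    return float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(s_wr, d))


def ci_1d(values: np.ndarray, labels: np.ndarray) -> float:
    """Exact one-dimensional CI = SS_between / SS_within (no ridge).

    Equals F (c-1)/(n-c) for the one-way ANOVA F statistic.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    cats = pd.unique(labels)
    grand = values.mean()
    ss_b = ss_w = 0.0
    for cat in cats:
        g = values[labels == cat]
        ss_b += g.size * (g.mean() - grand) ** 2
        ss_w += float(np.sum((g - g.mean()) ** 2))
    if ss_w == 0:
        raise ZeroDivisionError("zero within-category variability")
    return ss_b / ss_w


def _maybe_permute(labels: np.ndarray, rng: np.random.Generator, permute: bool):
    return rng.permutation(labels) if permute else labels


def ci_window(
    df: pd.DataFrame,
    condition: Condition,
    window: WindowLike = CI_WINDOW,
    n_reps: int = 1000,
    seed: int = 0,
    neurons: list[str] | None = None,
    ridge: float = RIDGE_EPSILON,
    permute_labels: bool = False,
) -> BootstrapResult:
    """Bootstrap distribution of CI in one window for one condition.

    The estimate is the mean over repetitions (sampling pseudo-populations
    is itself the estimator).  ``permute_labels`` shuffles category labels
    within each repetition -- the permutation null.
    """
    sampler = PopulationSampler(df, condition, windows=[window], neurons=neurons)
    samples = np.empty(n_reps)
    for rep in range(n_reps):
        rng = rng_stream(seed, rep)
        mat = sampler.sample(rng)[0]
        labels = _maybe_permute(mat.categories, rng, permute_labels)
        samples[rep] = ci_of_matrix(mat.counts, labels, ridge=ridge)
    return summarize_bootstrap(samples, alternative="greater")


def ci_significance(
    df: pd.DataFrame,
    condition: Condition,
    window: WindowLike = CI_WINDOW,
    baseline: WindowLike = SIGNIFICANCE_BASELINE,
    n_reps: int = 1000,
    seed: int = 0,
    neurons: list[str] | None = None,
    ridge: float = RIDGE_EPSILON,
    permute_labels: bool = False,
) -> BootstrapResult:
    """Bootstrap of delta-CI = CI(evoked) - CI(pre-stimulus baseline).

    Both windows use the same sampled trials within a repetition.  The
    p-value is the (add-one) fraction of repetitions with delta-CI <= 0:
    significant category information means the evoked window beats its own
    baseline across the bootstrap distribution.  ``permute_labels``
    shuffles category labels per repetition (shared by both windows), the
    permutation null under which delta-CI is centred at zero.
    """
    sampler = PopulationSampler(
        df, condition, windows=[window, baseline], neurons=neurons
    )
    samples = np.empty(n_reps)
    for rep in range(n_reps):
        rng = rng_stream(seed, rep)
        evoked, base = sampler.sample(rng)
        labels = _maybe_permute(evoked.categories, rng, permute_labels)
        samples[rep] = ci_of_matrix(evoked.counts, labels, ridge=ridge) - ci_of_matrix(
            base.counts, labels, ridge=ridge
        )
    return summarize_bootstrap(samples, alternative="greater")


def ci_timecourse(
    df: pd.DataFrame,
    condition: Condition,
    span: WindowLike = (-400.0, 500.0),
    width_ms: float = 100.0,
    step_ms: float = 5.0,
    n_reps: int = 200,
    seed: int = 0,
    neurons: list[str] | None = None,
    ridge: float = RIDGE_EPSILON,
    offset: bool = True,
    baseline_span: tuple[float, float] = TIMECOURSE_BASELINE,
    permute_labels: bool = False,
) -> tuple[np.ndarray, list[BootstrapResult]]:
    """Sliding-window CI time course (window centres, one result per window).

    With ``offset=True`` each repetition's mean CI over the windows centred
    inside ``baseline_span`` is subtracted from that repetition's whole
    trace, so the time course reads as change from pre-stimulus.
    """
    windows = sliding_windows(span, width_ms=width_ms, step_ms=step_ms)
    centers = np.array([w.center_ms for w in windows])
    sampler = PopulationSampler(df, condition, windows=windows, neurons=neurons)
    traces = np.empty((n_reps, len(windows)))
    for rep in range(n_reps):
        rng = rng_stream(seed, rep)
        mats = sampler.sample(rng)
        labels = _maybe_permute(mats[0].categories, rng, permute_labels)
        for k, mat in enumerate(mats):
            traces[rep, k] = ci_of_matrix(mat.counts, labels, ridge=ridge)
    if offset:
        base = (centers >= baseline_span[0]) & (centers <= baseline_span[1])
        if not base.any():
            raise ValueError("no window centres fall inside the baseline span")
        traces = traces - traces[:, base].mean(axis=1, keepdims=True)
    results = [
        summarize_bootstrap(traces[:, k], alternative="greater")
        for k in range(len(windows))
    ]
    return centers, results


@dataclass
class EnhancementResult:
    """Task enhancement of a statistic: (C - P) / (C + P)."""

    value_correct: float
    value_passive: float
    index: float
    bootstrap: BootstrapResult


def normalized_contrast(c: float, p: float) -> float:
    """(C - P) / (C + P); undefined when the denominator is not positive."""
    denom = c + p
    if denom <= 0:
        raise ZeroDivisionError("enhancement index undefined: C + P <= 0")
    return (c - p) / denom


def paired_bootstrap_contrast(
    sampler_correct,
    sampler_passive,
    stat_fn,
    n_reps: int = 1000,
    seed: int = 0,
) -> EnhancementResult:
    """Per-repetition (C-P)/(C+P) of any matrix statistic, paired by rep."""
    c_samples = np.empty(n_reps)
    p_samples = np.empty(n_reps)
    idx = np.empty(n_reps)
    for rep in range(n_reps):
        c_samples[rep] = stat_fn(sampler_correct.sample(rng_stream(seed, 2 * rep))[0])
        p_samples[rep] = stat_fn(sampler_passive.sample(rng_stream(seed, 2 * rep + 1))[0])
        idx[rep] = normalized_contrast(c_samples[rep], p_samples[rep])
    boot = summarize_bootstrap(idx, alternative="greater")
    return EnhancementResult(
        value_correct=float(c_samples.mean()),
        value_passive=float(p_samples.mean()),
        index=boot.estimate,
        bootstrap=boot,
    )


def matched_condition_samplers(
    df: pd.DataFrame,
    cond_a: Condition,
    cond_b: Condition,
    window: WindowLike,
    neurons: list[str] | None = None,
) -> tuple[PopulationSampler, PopulationSampler]:
    """Samplers for two conditions over common neurons and trial counts.

    CI and decoding accuracy scale with the number of neurons, and their
    small-sample bias depends on the pseudo-trial count, so a
    between-condition contrast is only meaningful over the same neuron set
    and the same per-category trial count: the intersection of the two
    eligible sets and the smaller of the two mean-rule counts.
    """
    from .population import eligible_neurons

    elig_a = eligible_neurons(df, cond_a, neurons)
    elig_b = eligible_neurons(df, cond_b, neurons)
    common = sorted(set(elig_a.neuron_ids) & set(elig_b.neuron_ids))
    if len(common) < 2:
        raise ValueError(
            f"fewer than 2 neurons eligible under both ({cond_a.describe()}) "
            f"and ({cond_b.describe()})"
        )
    n_shared = min(elig_a.n_per_category, elig_b.n_per_category)
    samp_a = PopulationSampler(
        df, cond_a, windows=[window], neurons=common, n_per_category=n_shared
    )
    samp_b = PopulationSampler(
        df, cond_b, windows=[window], neurons=common, n_per_category=n_shared
    )
    return samp_a, samp_b


def enhancement_index(
    df: pd.DataFrame,
    signal_level: int,
    window: WindowLike = CI_WINDOW,
    n_reps: int = 1000,
    seed: int = 0,
    neurons: list[str] | None = None,
    ridge: float = RIDGE_EPSILON,
) -> EnhancementResult:
    """CI enhancement in correct active vs passive trials at one level.

    Both conditions are built over their common eligible neurons so the
    contrast is not confounded by population dimensionality.
    """
    cond_c = Condition("active", signal_level, outcome="correct")
    cond_p = Condition("passive", signal_level)
    samp_c, samp_p = matched_condition_samplers(df, cond_c, cond_p, window, neurons)
    return paired_bootstrap_contrast(
        samp_c,
        samp_p,
        lambda m: ci_of_matrix(m.counts, m.categories, ridge=ridge),
        n_reps=n_reps,
        seed=seed,
    )


def ci_group_difference(
    df: pd.DataFrame,
    condition: Condition,
    neurons_a: list[str],
    neurons_b: list[str],
    window: WindowLike = CI_WINDOW,
    n_reps: int = 1000,
    seed: int = 0,
    ridge: float = RIDGE_EPSILON,
) -> BootstrapResult:
    """Bootstrap of CI(group A) - CI(group B) under one condition.

    Used for body-vs-nonbody group comparisons; the p-value asks whether
    the difference exceeds zero across repetitions.
    """
    samp_a = PopulationSampler(df, condition, windows=[window], neurons=neurons_a)
    samp_b = PopulationSampler(df, condition, windows=[window], neurons=neurons_b)
    samples = np.empty(n_reps)
    for rep in range(n_reps):
        ma = samp_a.sample(rng_stream(seed, 2 * rep))[0]
        mb = samp_b.sample(rng_stream(seed, 2 * rep + 1))[0]
        samples[rep] = ci_of_matrix(ma.counts, ma.categories, ridge=ridge) - ci_of_matrix(
            mb.counts, mb.categories, ridge=ridge
        )
    return summarize_bootstrap(samples, alternative="greater")


@dataclass
class SingleUnitCI:
    """Single-neuron CI with its evoked-vs-baseline significance."""

    neuron_id: str
    ci: float
    ci_baseline: float
    p_value: float
    delta: BootstrapResult


def ci_single_unit(
    neuron_trials: pd.DataFrame,
    condition: Condition,
    window: WindowLike = CI_WINDOW,
    baseline: WindowLike = SIGNIFICANCE_BASELINE,
    n_reps: int = 200,
    seed: int = 0,
) -> SingleUnitCI:
    """One-dimensional CI of a single neuron's responses under a condition.

    CI is the exact SS_between / SS_within ratio of the evoked-window
    counts.  Significance compares evoked against the pre-stimulus baseline
    window: trials are resampled with replacement, the CI difference is
    recomputed per repetition, and the p-value is the add-one fraction of
    repetitions with difference <= 0.
    """
    sub = neuron_trials[condition.mask(neuron_trials)]
    if sub.empty:
        raise ValueError(f"no trials under condition ({condition.describe()})")
    neuron_id = str(sub["neuron_id"].iloc[0])
    spikes = list(sub["spike_times"])
    labels = sub["category"].to_numpy()
    ev = counts_in_window(spikes, window).astype(float)
    ba = counts_in_window(spikes, baseline).astype(float)

    def safe_ci(vals, labs):
        try:
            return ci_1d(vals, labs)
        except ZeroDivisionError:
            return 0.0

    ci_ev = safe_ci(ev, labels)
    ci_ba = safe_ci(ba, labels)
    n = len(labels)
    samples = np.empty(n_reps)
    for rep in range(n_reps):
        rng = rng_stream(seed, rep)
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            samples[rep] = 0.0
            continue
        samples[rep] = safe_ci(ev[idx], labels[idx]) - safe_ci(ba[idx], labels[idx])
    delta = summarize_bootstrap(samples, estimate=ci_ev - ci_ba, alternative="greater")
    return SingleUnitCI(
        neuron_id=neuron_id,
        ci=ci_ev,
        ci_baseline=ci_ba,
        p_value=delta.p_value,
        delta=delta,
    )
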