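"""Pseudo-population construction from non-simultaneous recordings.

Neurons recorded in different sessions are combined by sampling, for each
neuron independently, an equal number of body and non-body trials of a
matched condition (task x signal level x outcome) and concatenating the
spike counts column-wise: row k of a category combines the k-th sampled
trial of every neuron, so each row is a point in R^N.  Row alignment across
neurons is arbitrary -- non-simultaneous data carry no trial
correspondence -- which implies zero noise correlation in expectation.

Trial matching follows the mean rule: the common per-category trial count
is the floored mean across neurons, and only neurons with at least that
many trials in both categories enter the population.  Sampling is without
replacement, repeated (1000 times by default) as a bootstrap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .core import (
    CATEGORIES,
    CI_WINDOW,
    FULL_NOISE_LEVEL,
    AnalysisWindow,
    WindowLike,
    as_window,
    counts_at_edges,
)
from .stats import rng_stream


@dataclass(frozen=True)
class Condition:
    """Trial filter: task, signal level(s), and behavioural outcome.

    ``signal_level`` may be a single level, a tuple of levels, or None (all
    noisy levels; full-noise trials are reserved for choice probability and
    excluded unless level 0 is requested explicitly).  ``outcome`` is
    "correct", "wrong", or None (no filter).
    """

    task: str
    signal_level: int | tuple[int, ...] | None = None
    outcome: str | None = None

    def levels(self) -> tuple[int, ...] | None:
        if self.signal_level is None:
            return None
        if isinstance(self.signal_level, (int, np.integer)):
            return (int(self.signal_level),)
        return tuple(int(s) for s in self.signal_level)

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = (df["task"] == self.task).to_numpy()
        levels = self.levels()
        if levels is None:
            m &= (df["signal_level"] != FULL_NOISE_LEVEL).to_numpy()
        else:
            m &= df["signal_level"].isin(levels).to_numpy()
        if self.outcome is not None:
            m &= (df["outcome"] == self.outcome).to_numpy()
        return m

    def describe(self) -> str:
        return (
            f"task={self.task}, signal={self.signal_level}, outcome={self.outcome}"
        )


PASSIVE = Condition("passive")


@dataclass
class PopulationMatrix:
    """Pseudo-trials x neurons spike-count matrix with row labels."""

    counts: np.ndarray
    categories: np.ndarray  # category per row
    neuron_ids: list[str]
    window: AnalysisWindow
    subcategories: np.ndarray | None = None

    @property
    def n_per_category(self) -> int:
        return int(np.sum(self.categories == CATEGORIES[0]))

    def labels(self, by: str = "category") -> np.ndarray:
        if by == "category":
            return self.categories
        if by == "subcategory":
            if self.subcategories is None:
                raise ValueError("matrix was built without subcategory labels")
            return self.subcategories
        raise ValueError(f"unknown label {by!r}")


@dataclass
class Eligibility:
    """Outcome of the trial-matching rule for one condition."""

    neuron_ids: list[str]
    n_per_category: int
    per_neuron_counts: pd.DataFrame  # neurons x categories trial counts

    def __repr__(self) -> str:  # compact log line
        return (
            f"Eligibility(n_neurons={len(self.neuron_ids)}, "
            f"n_per_category={self.n_per_category})"
        )


def eligible_neurons(
    df: pd.DataFrame, condition: Condition, neurons: list[str] | None = None
) -> Eligibility:
    """Apply the mean rule: common trial count and the neurons meeting it.

    ``n_per_category`` is the floored mean of the per-neuron per-category
    trial counts under the condition; a neuron is eligible when it has at
    least that many trials in *both* categories.
    """
    sub = df[condition.mask(df)]
    if neurons is not None:
        sub = sub[sub["neuron_id"].isin(neurons)]
    if sub.empty:
        raise ValueError(f"no trials under condition ({condition.describe()})")
    counts = (
        sub.groupby(["neuron_id", "category"], sort=True)
        .size()
        .unstack("category", fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    n_per_category = int(np.floor(counts.to_numpy().mean()))
    ok = (counts >= n_per_category).all(axis=1)
    ids = list(counts.index[ok])
    if len(ids) < 2:
        raise ValueError(
            f"fewer than 2 eligible neurons under condition "
            f"({condition.describe()}); counts mean gave n={n_per_category}"
        )
    return Eligibility(ids, n_per_category, counts)


class PopulationSampler:
    """Repeated pseudo-population construction for one condition.

    Spike counts are precomputed for every requested window, so each
    bootstrap repetition only samples trial indices.  All windows of one
    repetition share the same sampled trials, which is what paired
    evoked-vs-baseline statistics require.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        condition: Condition,
        windows: list[WindowLike] | None = None,
        neurons: list[str] | None = None,
        n_per_category: int | None = None,
        with_subcategories: bool = False,
    ):
        self.condition = condition
        self.windows = [as_window(w) for w in (windows or [CI_WINDOW])]
        if neurons is not None and n_per_category is not None:
            # caller fixed both: take the set as-is (the per-neuron trial
            # check below still guards against infeasible requests)
            self.eligibility = None
            self.neuron_ids = sorted(neurons)
            self.n_per_category = int(n_per_category)
        else:
            elig = eligible_neurons(df, condition, neurons)
            self.eligibility = elig
            self.neuron_ids = elig.neuron_ids
            self.n_per_category = (
                elig.n_per_category if n_per_category is None else int(n_per_category)
            )
        if self.n_per_category < 2:
            raise ValueError(
                f"n_per_category={self.n_per_category} too small for scatter "
                f"statistics under condition ({condition.describe()})"
            )
        sub = df[condition.mask(df) & df["neuron_id"].isin(self.neuron_ids).to_numpy()]
        edges = np.array([w.as_tuple() for w in self.windows])
        # per (neuron, category): counts array (n_trials, n_windows)
        self._counts: dict[tuple[str, str], np.ndarray] = {}
        self._subcats: dict[tuple[str, str], np.ndarray] = {}
        for (nid, cat), g in sub.groupby(["neuron_id", "category"], sort=True):
            avail = len(g)
            if avail < self.n_per_category:
                raise ValueError(
                    f"neuron {nid} has only {avail} {cat} trials, needs "
                    f"{self.n_per_category}"
                )
            self._counts[(nid, cat)] = counts_at_edges(list(g["spike_times"]), edges)
            if with_subcategories:
                self._subcats[(nid, cat)] = g["subcategory"].to_numpy()
        self.with_subcategories = with_subcategories

    def sample(self, rng: np.random.Generator) -> list[PopulationMatrix]:
        """One pseudo-population per window (same sampled trials throughout)."""
        n = self.n_per_category
        n_windows = len(self.windows)
        n_neurons = len(self.neuron_ids)
        counts = np.empty((2 * n, n_neurons, n_windows), dtype=np.int64)
        subcats = (
            np.empty((2 * n, n_neurons), dtype=object)
            if self.with_subcategories
            else None
        )
        for j, nid in enumerate(self.neuron_ids):
            for c, cat in enumerate(CATEGORIES):
                arr = self._counts[(nid, cat)]
                idx = rng.choice(arr.shape[0], size=n, replace=False)
                counts[c * n : (c + 1) * n, j, :] = arr[idx]
                if subcats is not None:
                    subcats[c * n : (c + 1) * n, j] = self._subcats[(nid, cat)][idx]
        categories = np.repeat(list(CATEGORIES), n)
        out = []
        for k, w in enumerate(self.windows):
            out.append(
                PopulationMatrix(
                    counts=counts[:, :, k],
                    categories=categories,
                    neuron_ids=list(self.neuron_ids),
                    window=w,
                    # subcategory of the first neuron's sampled trial is not
                    # shared across columns; expose per-row labels only when a
                    # single neuron is present, otherwise None
                    subcategories=subcats[:, 0] if subcats is not None and n_neurons == 1 else None,
                )
            )
        return out


def build_population(
    df: pd.DataFrame,
    condition: Condition,
    neurons: list[str] | None = None,
    n_per_category: int | None = None,
    window: WindowLike = CI_WINDOW,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> PopulationMatrix:
    """One pseudo-population matrix (single window convenience wrapper)."""
    sampler = PopulationSampler(
        df, condition, windows=[window], neurons=neurons, n_per_category=n_per_category
    )
    if rng is None:
        rng = rng_stream(seed, 0)
    return sampler.sample(rng)[0]


def bootstrap_populations(
    df: pd.DataFrame,
    condition: Condition,
    n_reps: int = 1000,
    seed: int = 0,
    windows: list[WindowLike] | None = None,
    neurons: list[str] | None = None,
    n_per_category: int | None = None,
) -> Iterator[list[PopulationMatrix]]:
    """Stream of pseudo-populations; eligibility is established once.

    Each repetition samples from an order-independent substream of ``seed``.
    """
    sampler = PopulationSampler(
        df, condition, windows=windows, neurons=neurons, n_per_category=n_per_category
    )
    for rep in range(n_reps):
        yield sampler.sample(rng_stream(seed, rep))
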