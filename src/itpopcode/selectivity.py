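"""Single-neuron category selectivity and the neuron-matching controls.

The selectivity index of a neuron is

    SI = (mu(B) - mu(O)) / (mu(B) + mu(O))

where mu(B) and mu(O) are its mean evoked spike counts (70-420 ms after
stimulus onset) to body and non-body images.  SI is computed per signal
level on correct trials of the active task and averaged across the four
levels, so each difficulty contributes equally even though fewer trials
survive the correct-only filter at low signal.  Neurons with SI > 0 are
body selective; SIs strictly inside (-0.037, 0.037) are labelled
non-selective.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    EVOKED_WINDOW,
    NONSELECTIVE_BAND,
    SIGNAL_LEVELS,
    WindowLike,
    as_window,
    counts_in_window,
)
from .stats import paired_rank_test


@dataclass
class NeuronSelectivity:
    """Selectivity summary of one neuron."""

    neuron_id: str
    mu_body: float  # mean evoked count, pooled over levels
    mu_object: float
    si: float
    polarity: str  # "body" iff si > 0
    band: str  # "selective" or "nonselective"
    per_level: dict[int, float] = field(default_factory=dict)


def _band_label(si: float, band: tuple[float, float] = NONSELECTIVE_BAND) -> str:
    return "nonselective" if band[0] < si < band[1] else "selective"


def selectivity_index(
    neuron_trials: pd.DataFrame,
    window: WindowLike = EVOKED_WINDOW,
    levels: tuple[int, ...] = SIGNAL_LEVELS,
    mode: str = "per_level",
) -> NeuronSelectivity:
    """SI of one neuron from correct active trials.

    ``mode='per_level'`` (default) averages the per-signal-level SIs;
    ``mode='pooled'`` computes a single SI from all correct trials pooled.
    Levels where mu(B) + mu(O) = 0 are undefined and skipped; if every
    level is undefined the neuron has no usable response and this raises.
    """
    df = neuron_trials
    df = df[
        (df["task"] == "active")
        & (df["outcome"] == "correct")
        & (df["signal_level"].isin(levels))
    ]
    if df.empty:
        raise ValueError("no correct active trials at the requested signal levels")
    neuron_id = str(df["neuron_id"].iloc[0])
    counts = counts_in_window(list(df["spike_times"]), window)
    cat = df["category"].to_numpy()
    lev = df["signal_level"].to_numpy()

    per_level: dict[int, float] = {}
    for s in levels:
        b = counts[(lev == s) & (cat == "body")]
        o = counts[(lev == s) & (cat == "nonbody")]
        if b.size == 0 or o.size == 0:
            continue
        mb, mo = float(np.mean(b)), float(np.mean(o))
        if mb + mo > 0:
            per_level[int(s)] = (mb - mo) / (mb + mo)
    mu_body = float(np.mean(counts[cat == "body"])) if np.any(cat == "body") else 0.0
    mu_object = float(np.mean(counts[cat == "nonbody"])) if np.any(cat == "nonbody") else 0.0
    if mode == "pooled":
        if mu_body + mu_object == 0:
            raise ValueError(f"neuron {neuron_id}: zero evoked response everywhere")
        si = (mu_body - mu_object) / (mu_body + mu_object)
    elif mode == "per_level":
        if not per_level:
            raise ValueError(f"neuron {neuron_id}: SI undefined at every signal level")
        si = float(np.mean(list(per_level.values())))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NeuronSelectivity(
        neuron_id=neuron_id,
        mu_body=mu_body,
        mu_object=mu_object,
        si=si,
        polarity="body" if si > 0 else "nonbody",
        band=_band_label(si),
        per_level=per_level,
    )


def compute_selectivity(
    df: pd.DataFrame,
    window: WindowLike = EVOKED_WINDOW,
    levels: tuple[int, ...] = SIGNAL_LEVELS,
    mode: str = "per_level",
) -> pd.DataFrame:
    """Per-neuron selectivity table (one row per neuron, indexed by id)."""
    rows = []
    for nid, g in df.groupby("neuron_id", sort=True):
        sel = selectivity_index(g, window=window, levels=levels, mode=mode)
        rows.append(
            {
                "neuron_id": sel.neuron_id,
                "mu_body": sel.mu_body,
                "mu_object": sel.mu_object,
                "si": sel.si,
                "polarity": sel.polarity,
                "band": sel.band,
                **{f"si_{s}": sel.per_level.get(s, np.nan) for s in levels},
            }
        )
    return pd.DataFrame(rows).set_index("neuron_id")


def select_neurons(
    selectivity: pd.DataFrame,
    rule: str,
    k: int | None = None,
    threshold: float | None = None,
    polarity: str | None = None,
    band: tuple[float, float] = NONSELECTIVE_BAND,
) -> list[str]:
    """Deterministic neuron subsets used by the population analyses.

    rules:
      - ``"polarity"``: body (SI > 0) or nonbody (SI < 0) neurons
      - ``"top_k"``: the ``k`` neurons with highest SI (within ``polarity``
        if given, by |SI| for nonbody); ties broken by neuron_id order
      - ``"threshold"``: SI strictly above ``threshold``
      - ``"nonselective"``: SI strictly inside ``band``
    """
    sel = selectivity.sort_index()
    si = sel["si"]
    if rule == "polarity":
        if polarity == "body":
            return list(si.index[si > 0])
        if polarity == "nonbody":
            return list(si.index[si < 0])
        raise ValueError("polarity rule needs polarity='body' or 'nonbody'")
    if rule == "top_k":
        if k is None:
            raise ValueError("top_k rule needs k")
        pool = si
        if polarity == "body":
            pool = si[si > 0]
        elif polarity == "nonbody":
            pool = si[si < 0].abs()
        if k > len(pool):
            raise ValueError(f"k={k} exceeds group size {len(pool)}")
        # stable mergesort keeps neuron_id order among ties
        order = pool.sort_values(ascending=False, kind="mergesort")
        return list(order.index[:k])
    if rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule needs threshold")
        return list(si.index[si > threshold])
    if rule == "nonselective":
        return list(si.index[(si > band[0]) & (si < band[1])])
    raise ValueError(f"unknown rule {rule!r}")


class MatchingError(RuntimeError):
    """A matching procedure hit its floor before reaching tolerance."""

    def __init__(self, message: str, achieved_gap: float):
        super().__init__(message)
        self.achieved_gap = achieved_gap


def match_mean_abs_si(
    group_a: pd.Series,
    group_b: pd.Series,
    tolerance: float = 0.005,
    floor: int = 10,
) -> tuple[list[str], list[str], list[tuple[str, str]]]:
    """Equalise mean |SI| of two neuron groups by trimming extremes.

    Iteratively removes the highest-|SI| neuron from whichever group has the
    larger mean |SI| until the means differ by less than ``tolerance``.
    Returns the surviving ids of both groups and the removal trace
    (group label, neuron id).  Raises :class:`MatchingError` if a group
    would shrink below ``floor`` first.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be nonempty")
    a = group_a.abs().sort_index()
    b = group_b.abs().sort_index()
    trace: list[tuple[str, str]] = []
    while True:
        gap = float(a.mean() - b.mean())
        if abs(gap) < tolerance:
            return list(a.index), list(b.index), trace
        donor, label = (a, "a") if gap > 0 else (b, "b")
        if len(donor) <= floor:
            raise MatchingError(
                f"group {label!r} reached floor size {floor} with |mean gap| "
                f"{abs(gap):.4f} >= tolerance {tolerance}",
                achieved_gap=abs(gap),
            )
        drop = donor.sort_values(kind="mergesort").index[-1]
        trace.append((label, str(drop)))
        if label == "a":
            a = a.drop(drop)
        else:
            b = b.drop(drop)


def rate_match(
    neuron_trials: pd.DataFrame,
    window: WindowLike = EVOKED_WINDOW,
    alpha: float = 0.05,
    min_stimuli: int = 20,
) -> tuple[list[str], list[float]]:
    """Equalise a neuron's active response magnitude to its passive one.

    Stimuli presented in both tasks are paired by ``stimulus_id``; while the
    two-sided signed-rank test on the per-stimulus (passive, active) mean
    evoked counts is significant (p <= alpha), the stimulus with the largest
    active response is removed (all its trials).  Returns the surviving
    stimulus ids and the p-value trace (one entry per test, so its length is
    number of removals + 1).
    """
    w = as_window(window)
    df = neuron_trials
    counts = counts_in_window(list(df["spike_times"]), w)
    tbl = pd.DataFrame(
        {
            "stimulus_id": df["stimulus_id"].to_numpy(),
            "task": df["task"].to_numpy(),
            "count": counts,
        }
    )
    means = tbl.groupby(["stimulus_id", "task"])["count"].mean().unstack("task")
    if "passive" not in means or "active" not in means:
        raise ValueError("rate matching needs trials from both tasks")
    means = means.dropna().sort_index()
    trace: list[float] = []
    while True:
        if len(means) < min_stimuli:
            raise MatchingError(
                f"fewer than {min_stimuli} stimuli remain before reaching p > {alpha}",
                achieved_gap=trace[-1] if trace else float("nan"),
            )
        p = paired_rank_test(means["passive"], means["active"])
        trace.append(p)
        if p > alpha:
            return list(means.index), trace
        drop = means["active"].sort_values(kind="mergesort").index[-1]
        means = means.drop(drop)


def split_by_preceding(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition trials by the category of the preceding stimulus.

    Block-initial trials (preceding "none") are excluded, so the group sizes
    sum to the number of trials minus the number of blocks.
    """
    return {
        "body": trials[trials["preceding_category"] == "body"],
        "nonbody": trials[trials["preceding_category"] == "nonbody"],
    }
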