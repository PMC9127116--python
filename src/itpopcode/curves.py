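"""Population-size analyses: neuron-adding curves and units-per-fraction.

A neuron-adding curve traces the categorization index as neurons are added
one at a time in a specified order (by selectivity index or by single-unit
CI), revealing how category information accumulates with population size.
From the curve, the number of units explaining a fraction f of the
"ultimate" CI (the all-units value) is the smallest k with
CI(k) >= f * CI(N), computed within each bootstrap repetition so the
normalization uses that repetition's own ultimate value, then averaged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CI_WINDOW, WindowLike
from .population import Condition, PopulationSampler
from .scatter import RIDGE_EPSILON, ci_of_matrix, ci_single_unit
from .stats import BootstrapResult, rng_stream, summarize_bootstrap

DIRECTIONS = ("increasing_si", "decreasing_si", "decreasing_unit_ci")


@dataclass
class AddingCurve:
    """CI as a function of population size along a fixed neuron order."""

    order: list[str]
    samples: np.ndarray  # (n_reps, n_neurons): CI of each prefix per rep
    results: list[BootstrapResult]  # one per prefix size k = 1..N
    direction: str

    @property
    def n_neurons(self) -> int:
        return len(self.order)

    def mean_curve(self) -> np.ndarray:
        return self.samples.mean(axis=0)


@dataclass
class UnitsForFraction:
    """Units needed to explain a fraction of the ultimate CI."""

    fraction: float
    n_units: float  # bootstrap mean of the smallest sufficient k
    sd: float
    samples: np.ndarray


def rank_neurons(
    df: pd.DataFrame,
    neurons: list[str],
    direction: str,
    condition: Condition | None = None,
    selectivity: pd.DataFrame | None = None,
    window: WindowLike = CI_WINDOW,
    seed: int = 0,
) -> list[str]:
    """Sort neurons for an adding curve; ties broken stably by neuron id."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if direction == "decreasing_unit_ci":
        if condition is None:
            raise ValueError("unit-CI ordering needs the condition")
        scores = pd.Series(
            {
                nid: ci_single_unit(
                    df[df["neuron_id"] == nid], condition, window=window,
                    n_reps=1, seed=seed,
                ).ci
                for nid in neurons
            }
        )
        ascending = False
    else:
        if selectivity is None:
            raise ValueError("SI ordering needs the selectivity table")
        scores = selectivity.loc[neurons, "si"]
        ascending = direction == "increasing_si"
    scores = scores.sort_index()  # stable tie-break by id
    return list(scores.sort_values(ascending=ascending, kind="mergesort").index)


def adding_curve(
    df: pd.DataFrame,
    condition: Condition,
    order: list[str],
    direction: str = "decreasing_unit_ci",
    window: WindowLike = CI_WINDOW,
    n_reps: int = 100,
    seed: int = 0,
    ridge: float = RIDGE_EPSILON,
) -> AddingCurve:
    """CI at every prefix size of an ordered neuron list, bootstrapped.

    Each repetition samples one pseudo-population over the full order and
    evaluates CI on the first k columns for k = 1..N, so all prefix sizes
    of a repetition share the same trials and the ridge (making curves
    comparable across dimensionality).
    """
    if len(order) < 2:
        raise ValueError("adding curve needs at least 2 neurons")
    sampler = PopulationSampler(
        df, condition, windows=[window], neurons=list(order)
    )
    # sampler sorts neurons by id internally; map columns back to the order
    col = [sampler.neuron_ids.index(nid) for nid in order]
    n = len(order)
    samples = np.empty((n_reps, n))
    for rep in range(n_reps):
        mat = sampler.sample(rng_stream(seed, rep))[0]
        counts = mat.counts[:, col]
        for k in range(1, n + 1):
            samples[rep, k - 1] = ci_of_matrix(
                counts[:, :k], mat.categories, ridge=ridge
            )
    results = [
        summarize_bootstrap(samples[:, k], alternative="greater") for k in range(n)
    ]
    return AddingCurve(
        order=list(order), samples=samples, results=results, direction=direction
    )


def units_for_fraction(
    curve: AddingCurve,
    fractions: tuple[float, ...] = (0.25, 0.50, 0.75, 0.95),
) -> list[UnitsForFraction]:
    """Smallest k with CI(k) >= f * CI(N), per repetition, summarized.

    The ultimate CI is each repetition's own all-units value; repetitions
    with a non-positive ultimate CI leave the estimator undefined.
    """
    ultimate = curve.samples[:, -1]
    if np.any(ultimate <= 0):
        raise ValueError(
            f"{int(np.sum(ultimate <= 0))} repetitions have non-positive "
            "ultimate CI; the fraction estimator is undefined"
        )
    out = []
    for f in sorted(fractions):
        if not 0 < f <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        reached = curve.samples >= (f * ultimate)[:, None]
        ks = np.argmax(reached, axis=1) + 1  # first prefix reaching the level
        out.append(
            UnitsForFraction(
                fraction=float(f),
                n_units=float(ks.mean()),
                sd=float(ks.std(ddof=1)) if len(ks) > 1 else 0.0,
                samples=ks.astype(float),
            )
        )
    return out
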