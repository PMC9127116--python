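"""Resampling utilities and the small statistical tests used throughout.

The bootstrap convention follows the pseudo-population procedure: a
statistic is recomputed over many seeded resamples, the spread of the
resamples is reported as the bootstrap SD ("SE" in figure captions), and
percentile p-values are obtained by counting exceedances.  The add-one
rule ``p = (count + 1) / (n + 1)`` keeps every p-value in
``[1/(n+1), 1]`` so that a sample can never be "impossibly" extreme
relative to its own finite null distribution.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps


def rng_stream(seed: int, *key: int) -> np.random.Generator:
    """Independent substream derived from a master seed and integer key.

    Keyed (counter-based) derivation makes bootstrap repetitions
    order-independent: repetition ``r`` draws from the same stream whether
    or not repetitions ``0..r-1`` were run.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(key)))


@dataclass
class BootstrapResult:
    """A statistic with its bootstrap distribution.

    ``sd`` is the standard deviation of ``samples`` (ddof=1); ``ci_low`` /
    ``ci_high`` are percentile bounds; ``p_value`` is the percentile
    (add-one) probability that the distribution does not exceed the null
    value in the claimed direction.
    """

    estimate: float
    samples: np.ndarray
    sd: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def n_reps(self) -> int:
        return len(self.samples)


def exceedance_p(
    null_samples: np.ndarray, observed: float, alternative: str = "greater"
) -> float:
    """Percentile p-value of ``observed`` against a null distribution.

    Counts the null samples at least as extreme as the observation (ties
    count as exceedances), add-one corrected.  ``alternative='greater'``
    asks how often the null meets or exceeds the observation;
    ``'two-sided'`` doubles the smaller tail, capped at 1.
    """
    s = np.asarray(null_samples, dtype=float)
    n = s.size
    if n == 0:
        raise ValueError("empty null distribution")
    hi = (np.sum(s >= observed) + 1) / (n + 1)
    lo = (np.sum(s <= observed) + 1) / (n + 1)
    if alternative == "greater":
        return float(hi)
    if alternative == "less":
        return float(lo)
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * min(hi, lo)))
    raise ValueError(f"unknown alternative {alternative!r}")


def summarize_bootstrap(
    samples: Sequence[float],
    estimate: float | None = None,
    null_value: float = 0.0,
    alternative: str = "greater",
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Package bootstrap samples into a :class:`BootstrapResult`.

    The p-value asks whether the bootstrap distribution exceeds
    ``null_value``: for ``alternative='greater'`` it is the (add-one)
    fraction of samples at or below the null value, i.e. the percentile of
    the null value inside the distribution.
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("no bootstrap samples")
    if estimate is None:
        estimate = float(np.mean(s))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(s, [alpha / 2, 1 - alpha / 2])
    n = s.size
    p_hi = (np.sum(s <= null_value) + 1) / (n + 1)
    p_lo = (np.sum(s >= null_value) + 1) / (n + 1)
    if alternative == "greater":
        p = p_hi
    elif alternative == "less":
        p = p_lo
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_hi, p_lo))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    sd = float(np.std(s, ddof=1)) if n > 1 else 0.0
    return BootstrapResult(
        estimate=float(estimate),
        samples=s,
        sd=sd,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
    )


class BootstrapError(RuntimeError):
    """A statistic failed on one of the bootstrap resamples."""


def bootstrap(
    statistic: Callable,
    data,
    n_reps: int = 1000,
    seed: int = 0,
    null_value: float = 0.0,
    alternative: str = "greater",
) -> BootstrapResult:
    """Nonparametric bootstrap of ``statistic`` over resamples of ``data``.

    ``data`` is indexable (ndarray, DataFrame rows via ``.iloc`` not
    supported here -- pass values); each repetition resamples its rows with
    replacement using an order-independent substream of ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    arr = np.asarray(data)
    n = arr.shape[0]
    samples = np.empty(n_reps, dtype=float)
    for rep in range(n_reps):
        rng = rng_stream(seed, rep)
        idx = rng.integers(0, n, size=n)
        try:
            samples[rep] = statistic(arr[idx])
        except Exception as exc:  # noqa: BLE001 - annotate with rep index
            raise BootstrapError(f"statistic failed on repetition {rep}: {exc}") from exc
    return summarize_bootstrap(
        samples,
        estimate=float(statistic(arr)),
        null_value=null_value,
        alternative=alternative,
    )


def paired_rank_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded (Wilcoxon's original treatment); if every
    difference is zero there is no detectable effect and p = 1.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if not np.any(d != 0):
        return 1.0
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
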