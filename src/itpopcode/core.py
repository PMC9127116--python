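"""Shared data model: trial records, analysis windows, spike counting.

The package analyses trial-wise single-unit spiking data recorded (or
simulated) around a brief visual stimulus.  Every trial carries the spike
times of one neuron relative to stimulus onset, in milliseconds, within
[-500, 600] ms, plus the task/stimulus/behaviour metadata the downstream
stages condition on.

All spike-count windows are half-open ``[start, end)`` in ms, so a tiling
partition of windows counts every spike exactly once.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TASKS = ("passive", "active")
CATEGORIES = ("body", "nonbody")
#: subcategory -> category; full-noise stimuli use the extra value "noise"
SUBCATEGORY_MAP = {
    "human": "body",
    "monkey": "body",
    "fourleg": "body",
    "airplane": "nonbody",
    "car": "nonbody",
    "chair": "nonbody",
}
NOISE_SUBCATEGORY = "noise"

#: absolute visual signal levels of the noisy stimuli (percent of pixels kept)
SIGNAL_LEVELS = (90, 70, 55, 40)
FULL_NOISE_LEVEL = 0

#: recorded span of spike times relative to stimulus onset, ms
RECORD_SPAN = (-500.0, 600.0)
#: evoked-response window used for the selectivity index, ms
EVOKED_WINDOW = (70.0, 420.0)
#: window used for the categorization index / decoder / choice probability, ms
CI_WINDOW = (150.0, 350.0)
#: baseline interval subtracted from sliding time courses, ms
TIMECOURSE_BASELINE = (-400.0, 0.0)
#: pre-stimulus window paired with CI_WINDOW for significance testing, ms
SIGNIFICANCE_BASELINE = (-200.0, 0.0)
#: strict band of selectivity-index values labelled non-selective
NONSELECTIVE_BAND = (-0.037, 0.037)


class ValidationError(ValueError):
    """A trial record violates one of the data-model invariants."""


@dataclass(frozen=True)
class AnalysisWindow:
    """A time window in ms relative to stimulus onset.

    ``width_ms``/``step_ms`` are only meaningful for a *span* that is to be
    tiled by :func:`sliding_windows`.
    """

    start_ms: float
    end_ms: float
    width_ms: float | None = None
    step_ms: float | None = None

    def __post_init__(self) -> None:
        if not self.end_ms > self.start_ms:
            raise ValueError(
                f"end_ms must exceed start_ms, got [{self.start_ms}, {self.end_ms})"
            )
        if self.step_ms is not None and self.step_ms <= 0:
            raise ValueError("step_ms must be positive")
        if self.width_ms is not None and self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    @property
    def center_ms(self) -> float:
        return 0.5 * (self.start_ms + self.end_ms)

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    def as_tuple(self) -> tuple[float, float]:
        return (self.start_ms, self.end_ms)


WindowLike = AnalysisWindow | tuple[float, float]


def as_window(window: WindowLike) -> AnalysisWindow:
    """Coerce a ``(start, end)`` pair into an :class:`AnalysisWindow`."""
    if isinstance(window, AnalysisWindow):
        return window
    start, end = window
    return AnalysisWindow(float(start), float(end))


@dataclass
class TrialRecord:
    """One stimulus presentation of one neuron.

    Spike times are ms relative to stimulus onset, strictly sorted, within
    :data:`RECORD_SPAN`.  Passive trials carry no outcome or choice; on
    active trials with signal > 0 the outcome is "correct" exactly when the
    choice matches the stimulus category, while full-noise (0% signal)
    trials are rewarded at random, so their outcome is unconstrained.
    """

    neuron_id: str
    session_id: str
    task: str
    stimulus_id: str
    category: str
    subcategory: str
    signal_level: int
    outcome: str
    choice: str
    preceding_category: str
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.validate()

    def validate(self) -> None:
        t = self.spike_times
        if t.size and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"trial {self.neuron_id}/{self.stimulus_id}: spike times not "
                "strictly sorted ascending"
            )
        if t.size and (t[0] < RECORD_SPAN[0] or t[-1] > RECORD_SPAN[1]):
            raise ValidationError(
                f"trial {self.neuron_id}/{self.stimulus_id}: spike times outside "
                f"recorded span {RECORD_SPAN}"
            )
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.subcategory == NOISE_SUBCATEGORY:
            if self.signal_level != FULL_NOISE_LEVEL:
                raise ValidationError(
                    "subcategory 'noise' is reserved for full-noise stimuli"
                )
        elif SUBCATEGORY_MAP.get(self.subcategory) != self.category:
            raise ValidationError(
                f"subcategory {self.subcategory!r} inconsistent with category "
                f"{self.category!r}"
            )
        if self.signal_level not in SIGNAL_LEVELS + (FULL_NOISE_LEVEL,):
            raise ValidationError(f"unknown signal level {self.signal_level!r}")
        if self.task == "passive":
            if self.outcome != "none" or self.choice != "none":
                raise ValidationError(
                    f"trial {self.neuron_id}/{self.stimulus_id}: passive trials "
                    "must have outcome=none and choice=none"
                )
        else:
            if self.choice not in CATEGORIES:
                raise ValidationError("active trials need a body/nonbody choice")
            if self.signal_level > 0:
                expected = "correct" if self.choice == self.category else "wrong"
                if self.outcome != expected:
                    raise ValidationError(
                        f"trial {self.neuron_id}/{self.stimulus_id}: outcome "
                        f"{self.outcome!r} inconsistent with choice/category"
                    )
            elif self.outcome not in ("correct", "wrong"):
                raise ValidationError("full-noise active trials carry a random outcome")
        if self.preceding_category not in CATEGORIES + ("none",):
            raise ValidationError(
                f"unknown preceding category {self.preceding_category!r}"
            )


def count_spikes(trial, window: WindowLike) -> int:
    """Number of spikes in the half-open window ``[start, end)``.

    ``trial`` may be a :class:`TrialRecord` or a sorted array of spike times.
    """
    w = as_window(window)
    if w.start_ms < RECORD_SPAN[0] or w.end_ms > RECORD_SPAN[1]:
        raise ValueError(f"window {w.as_tuple()} outside recorded span {RECORD_SPAN}")
    times = trial.spike_times if isinstance(trial, TrialRecord) else np.asarray(trial)
    lo = np.searchsorted(times, w.start_ms, side="left")
    hi = np.searchsorted(times, w.end_ms, side="left")
    return int(hi - lo)


def counts_in_window(spike_trains, window: WindowLike) -> np.ndarray:
    """Vectorised :func:`count_spikes` over a sequence of spike-time arrays."""
    w = as_window(window)
    if w.start_ms < RECORD_SPAN[0] or w.end_ms > RECORD_SPAN[1]:
        raise ValueError(f"window {w.as_tuple()} outside recorded span {RECORD_SPAN}")
    out = np.empty(len(spike_trains), dtype=np.int64)
    for i, t in enumerate(spike_trains):
        out[i] = np.searchsorted(t, w.end_ms) - np.searchsorted(t, w.start_ms)
    return out


def counts_at_edges(spike_trains, edges: np.ndarray) -> np.ndarray:
    """Spike counts of each train between consecutive ``edges`` pairs.

    ``edges`` has shape (n_windows, 2); the result has shape
    (n_trains, n_windows).  Used to evaluate many sliding windows at once.
    """
    edges = np.asarray(edges, dtype=float)
    flat = edges.reshape(-1)
    out = np.empty((len(spike_trains), edges.shape[0]), dtype=np.int64)
    for i, t in enumerate(spike_trains):
        pos = np.searchsorted(t, flat).reshape(edges.shape)
        out[i] = pos[:, 1] - pos[:, 0]
    return out


def sliding_windows(
    span: WindowLike, width_ms: float = 100.0, step_ms: float = 5.0
) -> list[AnalysisWindow]:
    """Tile ``span`` with half-open windows of ``width_ms`` every ``step_ms``.

    The number of windows is ``floor((span - width) / step) + 1``; each is
    tagged with its centre time for plotting at bin midpoints.
    """
    s = as_window(span)
    if s.width_ms is not None:
        width_ms = s.width_ms
    if s.step_ms is not None:
        step_ms = s.step_ms
    span_ms = s.end_ms - s.start_ms
    if span_ms < width_ms:
        raise ValueError(
            f"span of {span_ms} ms is shorter than the window width {width_ms} ms"
        )
    n = int(np.floor((span_ms - width_ms) / step_ms + 1e-9)) + 1
    return [
        AnalysisWindow(s.start_ms + k * step_ms, s.start_ms + k * step_ms + width_ms)
        for k in range(n)
    ]
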