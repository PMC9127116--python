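"""Trial-table I/O.

Datasets travel as tab-separated tables with one row per trial and a
``spike_times`` column holding semicolon-joined millisecond values --
diffable, language-neutral, and loadable into a DataFrame.  In memory the
package works on a pandas DataFrame whose ``spike_times`` column holds
sorted float arrays.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TrialRecord, ValidationError

COLUMNS = [
    "neuron_id",
    "session_id",
    "task",
    "stimulus_id",
    "category",
    "subcategory",
    "signal_level",
    "outcome",
    "choice",
    "preceding_category",
    "spike_times",
]


class TrialTableError(ValueError):
    """The trial table is malformed; the message lists offending rows."""


def _parse_spikes(cell: str) -> np.ndarray:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return np.empty(0)
    return np.array([float(v) for v in str(cell).split(";")], dtype=float)


def _format_spikes(times: np.ndarray) -> str:
    return ";".join(format(t, ".10g") for t in np.asarray(times, dtype=float))


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Validate a trial DataFrame row-by-row into :class:`TrialRecord` objects."""
    trials: list[TrialRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            trials.append(
                TrialRecord(
                    neuron_id=str(row.neuron_id),
                    session_id=str(row.session_id),
                    task=str(row.task),
                    stimulus_id=str(row.stimulus_id),
                    category=str(row.category),
                    subcategory=str(row.subcategory),
                    signal_level=int(row.signal_level),
                    outcome=str(row.outcome),
                    choice=str(row.choice),
                    preceding_category=str(row.preceding_category),
                    spike_times=np.asarray(row.spike_times, dtype=float),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise TrialTableError(
            f"{len(errors)} malformed rows:\n" + "\n".join(errors[:20])
        )
    return trials


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Stack trial records into the canonical DataFrame layout."""
    return pd.DataFrame(
        {
            "neuron_id": [t.neuron_id for t in trials],
            "session_id": [t.session_id for t in trials],
            "task": [t.task for t in trials],
            "stimulus_id": [t.stimulus_id for t in trials],
            "category": [t.category for t in trials],
            "subcategory": [t.subcategory for t in trials],
            "signal_level": [t.signal_level for t in trials],
            "outcome": [t.outcome for t in trials],
            "choice": [t.choice for t in trials],
            "preceding_category": [t.preceding_category for t in trials],
            "spike_times": [t.spike_times for t in trials],
        }
    )


def read_trial_frame(path) -> pd.DataFrame:
    """Read a TSV trial table into a DataFrame with parsed spike arrays."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing columns: {missing}")
    df["signal_level"] = df["signal_level"].astype(int)
    df["spike_times"] = [_parse_spikes(c) for c in df["spike_times"]]
    return df[COLUMNS]


def read_trials(path) -> list[TrialRecord]:
    """Read and validate a TSV trial table; malformed rows are reported by number."""
    return frame_to_trials(read_trial_frame(path))


def write_trials(trials, path) -> None:
    """Write trials (records or a DataFrame) as a TSV trial table."""
    if not isinstance(trials, pd.DataFrame):
        trials = trials_to_frame(trials)
    out = trials.copy()
    out["spike_times"] = [_format_spikes(t) for t in out["spike_times"]]
    out.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_jsonify))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
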