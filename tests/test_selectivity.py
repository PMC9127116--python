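"""Selectivity index, neuron grouping, and the matching controls."""
import numpy as np
import pandas as pd
import pytest

from itpopcode import (
    match_mean_abs_si,
    rate_match,
    select_neurons,
    selectivity_index,
    split_by_preceding,
)
from itpopcode.core import SIGNAL_LEVELS, TrialRecord
from itpopcode.io import trials_to_frame
from itpopcode.selectivity import MatchingError


def spikes_for(count):
    return np.linspace(100, 400, count) if count else np.empty(0)


def neuron_frame(body_counts, nonbody_counts, neuron_id="n0", task="active"):
    """Active-correct trials at every level with prescribed evoked counts."""
    trials = []
    for level in SIGNAL_LEVELS:
        for cat, sub, counts in (
            ("body", "human", body_counts),
            ("nonbody", "car", nonbody_counts),
        ):
            for i, c in enumerate(counts):
                trials.append(
                    TrialRecord(
                        neuron_id=neuron_id, session_id="s", task=task,
                        stimulus_id=f"{cat[0]}{i:03d}_s{level}", category=cat,
                        subcategory=sub, signal_level=level,
                        outcome="correct" if task == "active" else "none",
                        choice=cat if task == "active" else "none",
                        preceding_category="none", spike_times=spikes_for(c),
                    )
                )
    return trials_to_frame(trials)


class TestSelectivityIndex:
    def test_three_to_one_gives_half(self):
        sel = selectivity_index(neuron_frame([3, 3], [1, 1]))
        assert sel.si == pytest.approx(0.5)
        assert sel.polarity == "body"
        assert set(sel.per_level) == set(SIGNAL_LEVELS)

    def test_equal_means_give_zero(self):
        sel = selectivity_index(neuron_frame([2, 4], [4, 2]))
        assert sel.si == 0.0

    def test_band_boundaries_are_strict(self):
        # mu ratio chosen so SI = 0.02 (inside) and ~0.0385 (outside)
        inside = selectivity_index(neuron_frame([51], [49]))
        assert inside.si == pytest.approx(0.02)
        assert inside.band == "nonselective"
        outside = selectivity_index(neuron_frame([27], [25]))
        assert outside.si > 0.037
        assert outside.band == "selective"

    def test_antisymmetric_under_label_swap(self):
        df = neuron_frame([5, 3], [1, 2])
        si = selectivity_index(df).si
        swapped = df.copy()
        swapped["category"] = swapped["category"].map(
            {"body": "nonbody", "nonbody": "body"}
        )
        swapped["subcategory"] = swapped["subcategory"].map(
            {"human": "car", "car": "human"}
        )
        swapped["choice"] = swapped["category"]
        assert selectivity_index(swapped).si == pytest.approx(-si)

    def test_scale_invariance(self):
        a = selectivity_index(neuron_frame([6, 2], [2, 2])).si
        b = selectivity_index(neuron_frame([18, 6], [6, 6])).si
        assert a == pytest.approx(b)

    def test_no_usable_trials_rejected(self):
        df = neuron_frame([2], [1])
        with pytest.raises(ValueError, match="no correct active trials"):
            selectivity_index(df[df["task"] == "passive"])


class TestSelectNeurons:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame(
            {"si": [0.9, 0.5, 0.5, 0.1, -0.1, 0.0, 0.02]},
            index=[f"n{i}" for i in range(7)],
        )

    def test_polarity_filter(self, table):
        sub = pd.DataFrame({"si": [0.5, -0.1, 0.0]}, index=["a", "b", "c"])
        assert select_neurons(sub, "polarity", polarity="body") == ["a"]

    def test_top_k_stable_tie_break(self, table):
        assert select_neurons(table, "top_k", k=2) == ["n0", "n1"]
        # n1 and n2 tie at 0.5: the earlier id wins
        assert select_neurons(table, "top_k", k=3) == ["n0", "n1", "n2"]

    def test_top_k_too_large(self, table):
        with pytest.raises(ValueError, match="exceeds group size"):
            select_neurons(table, "top_k", k=99)

    def test_threshold_rule(self, table):
        assert select_neurons(table, "threshold", threshold=0.25) == ["n0", "n1", "n2"]

    def test_nonselective_band(self, table):
        assert select_neurons(table, "nonselective") == ["n5", "n6"]


class TestMatchMeanAbsSI:
    def test_already_equal_untouched(self):
        a = pd.Series([0.3, 0.1], index=["a1", "a2"])
        b = pd.Series([0.2, 0.2], index=["b1", "b2"])
        ids_a, ids_b, trace = match_mean_abs_si(a, b, floor=1)
        assert (ids_a, ids_b, trace) == (["a1", "a2"], ["b1", "b2"], [])

    def test_hand_trace(self):
        a = pd.Series([0.9, 0.1], index=["a1", "a2"])
        b = pd.Series([0.1], index=["b1"])
        ids_a, ids_b, trace = match_mean_abs_si(a, b, floor=1)
        assert ids_a == ["a2"]
        assert trace == [("a", "a1")]

    def test_random_inputs_converge_below_tolerance(self, rng):
        for _ in range(20):
            a = pd.Series(rng.uniform(0, 1, 30), index=[f"a{i}" for i in range(30)])
            b = pd.Series(-rng.uniform(0, 1, 25), index=[f"b{i}" for i in range(25)])
            ids_a, ids_b, _ = match_mean_abs_si(a, b, tolerance=0.01, floor=2)
            gap = abs(a[ids_a].abs().mean() - b[ids_b].abs().mean())
            assert gap < 0.01

    def test_floor_error_carries_gap(self):
        a = pd.Series([0.9, 0.8], index=["a1", "a2"])
        b = pd.Series([0.01], index=["b1"])
        with pytest.raises(MatchingError) as exc:
            match_mean_abs_si(a, b, tolerance=1e-6, floor=1)
        assert exc.value.achieved_gap > 0


def paired_task_frame(passive_counts, active_counts):
    """One neuron, same stimuli in both tasks, one trial per stimulus."""
    trials = []
    for task, counts in (("passive", passive_counts), ("active", active_counts)):
        for i, c in enumerate(counts):
            trials.append(
                TrialRecord(
                    neuron_id="n0", session_id="s", task=task,
                    stimulus_id=f"b{i:03d}_s90", category="body",
                    subcategory="human", signal_level=90,
                    outcome="none" if task == "passive" else "correct",
                    choice="none" if task == "passive" else "body",
                    preceding_category="none", spike_times=spikes_for(c),
                )
            )
    return trials_to_frame(trials)


class TestRateMatch:
    def test_identical_tasks_stop_immediately(self):
        counts = list(range(25))
        surviving, trace = rate_match(paired_task_frame(counts, counts))
        assert len(surviving) == 25
        assert trace == [1.0]

    def test_only_elevated_stimuli_removed(self):
        """Drops come exclusively from the inflated-response stimuli.

        With 12 elevated stimuli the signed-rank test stays significant
        while enough concordant pairs remain, so the procedure removes
        elevated stimuli one by one and stops once the survivors are too few
        to reach p <= 0.05 (a handful, exact count depending on the test's
        tie handling).
        """
        passive = [3] * 24 + [4] * 12
        active = [3] * 24 + [30] * 12
        surviving, trace = rate_match(
            paired_task_frame(passive, active), min_stimuli=10
        )
        elevated = {f"b{i:03d}_s90" for i in range(24, 36)}
        dropped = set(f"b{i:03d}_s90" for i in range(36)) - set(surviving)
        assert dropped <= elevated
        assert 5 <= len(dropped) <= 10
        assert len(trace) == len(dropped) + 1  # p recomputed after every removal
        assert trace[-1] > 0.05 and all(p <= 0.05 for p in trace[:-1])

    def test_floor_triggers_error(self):
        passive = [0] * 22
        active = [9] * 22
        with pytest.raises(MatchingError):
            rate_match(paired_task_frame(passive, active), min_stimuli=20)


class TestSplitByPreceding:
    def test_partition_excludes_block_starts(self, small_dataset):
        df, _ = small_dataset
        one = df[(df["neuron_id"] == "n000") & (df["task"] == "passive")]
        groups = split_by_preceding(one)
        n_blocks = (one["preceding_category"] == "none").sum()
        assert len(groups["body"]) + len(groups["nonbody"]) == len(one) - n_blocks
        assert n_blocks == len(one) // 90  # one block-start per 90-trial block

    def test_all_body_sequence_gives_empty_group(self):
        df = paired_task_frame([1, 2, 3], [1, 2, 3]).assign(
            preceding_category=["none", "body", "body"] * 2
        )
        groups = split_by_preceding(df)
        assert len(groups["nonbody"]) == 0
        assert len(groups["body"]) == 4
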