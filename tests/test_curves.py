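"""Neuron-adding curves and the units-per-fraction estimator."""
import numpy as np
import pandas as pd
import pytest

from itpopcode import (
    Condition,
    NeuronModel,
    TaskGain,
    adding_curve,
    ci_1d,
    rank_neurons,
    simulate_trial,
    units_for_fraction,
)
from itpopcode.core import CI_WINDOW, counts_in_window
from itpopcode.curves import AddingCurve
from itpopcode.io import trials_to_frame
from itpopcode.stats import rng_stream


def simulated_frame(tunings, n_per_cat=30, seed=5):
    """Passive trials for neurons with prescribed tuning strengths."""
    rng = rng_stream(seed, 0)
    trials = []
    for j, tuning in enumerate(tunings):
        neuron = NeuronModel(
            f"n{j:03d}", 10.0, 1, float(tuning), task_gain=TaskGain(0.0)
        )
        for cat in ("body", "nonbody"):
            for i in range(n_per_cat):
                trials.append(
                    simulate_trial(
                        neuron, "passive", cat, 90, rng,
                        stimulus_id=f"{cat[0]}{i:03d}_s90",
                        subcategory="human" if cat == "body" else "car",
                    )
                )
    return trials_to_frame(trials)


def synthetic_curve(samples, direction="decreasing_unit_ci"):
    from itpopcode.stats import summarize_bootstrap

    samples = np.asarray(samples, dtype=float)
    results = [
        summarize_bootstrap(samples[:, k]) for k in range(samples.shape[1])
    ]
    return AddingCurve(
        order=[f"n{k:03d}" for k in range(samples.shape[1])],
        samples=samples,
        results=results,
        direction=direction,
    )


class TestAddingCurve:
    def test_first_prefix_equals_single_unit_ci(self):
        """With every trial used, the k=1 point is the neuron's exact 1-D CI."""
        df = simulated_frame([6.0, 0.0], n_per_cat=25)
        curve = adding_curve(
            df, Condition("passive", 90), ["n000", "n001"], n_reps=3, seed=0,
            ridge=0.0,
        )
        sub = df[df["neuron_id"] == "n000"]
        counts = counts_in_window(list(sub["spike_times"]), CI_WINDOW).astype(float)
        expected = ci_1d(counts, sub["category"].to_numpy())
        np.testing.assert_allclose(curve.samples[:, 0], expected, rtol=1e-10)

    def test_noise_neurons_plateau(self):
        """Appending untuned neurons adds no category information."""
        df = simulated_frame([8.0, 8.0, 8.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        curve = adding_curve(
            df, Condition("passive", 90),
            [f"n{j:03d}" for j in range(8)], n_reps=30, seed=1,
        )
        mean = curve.mean_curve()
        assert mean[2] > 3 * mean[0] / 3  # information accumulates early
        # adding the five noise neurons changes CI much less than the core did
        assert (mean[7] - mean[2]) < 0.5 * (mean[2] - mean[0])

    def test_needs_two_neurons(self):
        df = simulated_frame([1.0])
        with pytest.raises(ValueError, match="at least 2"):
            adding_curve(df, Condition("passive", 90), ["n000"], n_reps=2)


class TestRankNeurons:
    def test_si_directions_and_stable_ties(self):
        sel = pd.DataFrame(
            {"si": [0.5, -0.2, 0.5, 0.0]}, index=["a", "b", "c", "d"]
        )
        up = rank_neurons(None, ["a", "b", "c", "d"], "increasing_si", selectivity=sel)
        assert up == ["b", "d", "a", "c"]
        down = rank_neurons(None, ["a", "b", "c", "d"], "decreasing_si", selectivity=sel)
        assert down == ["a", "c", "d", "b"]

    def test_unit_ci_ordering_puts_informative_first(self):
        df = simulated_frame([0.0, 9.0, 2.0])
        order = rank_neurons(
            df, ["n000", "n001", "n002"], "decreasing_unit_ci",
            condition=Condition("passive", 90),
        )
        assert order[0] == "n001"

    def test_unknown_direction(self):
        with pytest.raises(ValueError, match="direction"):
            rank_neurons(None, [], "sideways")


class TestUnitsForFraction:
    def test_linear_curve_closed_form(self):
        """A linear rise means f of the units explain f of the ultimate CI."""
        n = 40
        ramp = np.tile(np.arange(1, n + 1) / n, (5, 1))
        curve = synthetic_curve(ramp)
        for res in units_for_fraction(curve, (0.25, 0.5, 0.75, 0.95)):
            assert res.n_units == pytest.approx(np.ceil(res.fraction * n))
            assert res.sd == 0.0

    def test_concentrated_signal_found(self):
        """Five informative units out of twenty explain ~95% of the curve.

        Enough trials per category are used that the dimension-dependent
        small-sample inflation of CI stays small next to the signal carried
        by the tuned units.
        """
        df = simulated_frame([10.0] * 5 + [0.0] * 15, n_per_cat=250, seed=9)
        order = [f"n{j:03d}" for j in range(20)]  # informative first
        curve = adding_curve(
            df, Condition("passive", 90), order, n_reps=30, seed=2
        )
        res = {u.fraction: u.n_units for u in units_for_fraction(curve, (0.25, 0.95))}
        assert res[0.25] <= 3
        assert 3 <= res[0.95] <= 9

    def test_monotone_in_fraction(self, rng):
        samples = np.cumsum(rng.uniform(0, 1, size=(20, 15)), axis=1)
        curve = synthetic_curve(samples)
        res = units_for_fraction(curve, (0.25, 0.5, 0.75, 0.95))
        n_units = [u.n_units for u in res]
        assert np.all(np.diff(n_units) >= 0)
        per_rep = np.stack([u.samples for u in res])
        assert np.all(np.diff(per_rep, axis=0) >= 0)

    def test_nonpositive_ultimate_rejected(self):
        curve = synthetic_curve(np.array([[0.5, 0.0], [0.2, 0.4]]))
        with pytest.raises(ValueError, match="non-positive"):
            units_for_fraction(curve)
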