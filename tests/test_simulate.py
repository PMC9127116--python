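"""The synthetic generator: rate model, choice model, dataset structure."""
import numpy as np
import pandas as pd
import pytest

from itpopcode import (
    NeuronModel,
    PopulationModel,
    SimulationConfig,
    SIProfile,
    TaskGain,
    generate_dataset,
    psychometric,
    sample_population,
    simulate_choice,
    simulate_trial,
)
from itpopcode.core import EVOKED_WINDOW, NONSELECTIVE_BAND, count_spikes
from itpopcode.stats import rng_stream


def flat_neuron(baseline=10.0, tuning=4.0, preference=1, strength=0.0):
    return NeuronModel(
        neuron_id="n0",
        baseline_rate=baseline,
        preference=preference,
        tuning=tuning,
        task_gain=TaskGain(strength),
    )


class TestRateModel:
    def test_silent_neuron_never_spikes(self, rng):
        n = flat_neuron(baseline=0.0, tuning=0.0)
        for _ in range(20):
            t = simulate_trial(n, "passive", "body", 90, rng)
            assert t.spike_times.size == 0

    def test_baseline_count_matches_poisson_mean(self, rng):
        """10 sp/s over the 500-ms pre-stimulus span gives 5 expected spikes."""
        n = flat_neuron(baseline=10.0, tuning=0.0)
        counts = [
            count_spikes(simulate_trial(n, "passive", "body", 90, rng), (-500, 0))
            for _ in range(1000)
        ]
        assert np.mean(counts) == pytest.approx(5.0, rel=0.05)

    def test_evoked_difference_matches_rate_integral(self, rng):
        """Preferred minus null mean evoked counts = (s/100) * tuning * 0.35 s."""
        n = flat_neuron(baseline=8.0, tuning=6.0)
        s = 70
        pref, null = [], []
        for _ in range(1500):
            pref.append(
                count_spikes(simulate_trial(n, "passive", "body", s, rng), EVOKED_WINDOW)
            )
            null.append(
                count_spikes(
                    simulate_trial(n, "passive", "nonbody", s, rng), EVOKED_WINDOW
                )
            )
        expected = (s / 100) * 6.0 * 0.35
        assert np.mean(pref) - np.mean(null) == pytest.approx(expected, abs=0.12)

    def test_task_gain_boosts_active_evoked_rate(self):
        n = flat_neuron(strength=2.0)
        assert n.evoked_rate("active", "body", 40) > n.evoked_rate("passive", "body", 40)
        assert n.evoked_rate("active", "body", 40) == pytest.approx(
            10.0 + 0.4 * 4.0 * (1 + 2.0 * 0.6**1.5)
        )

    def test_gain_of_one_at_full_signal(self):
        assert TaskGain(2.2)(100) == 1.0
        assert TaskGain(0.0)(40) == 1.0

    def test_expected_si_monotone_in_tuning(self):
        sis = [flat_neuron(tuning=t).expected_si() for t in (0.0, 1.0, 3.0, 9.0)]
        assert sis[0] == 0.0
        assert np.all(np.diff(sis) > 0)


class TestPopulationSampling:
    def test_profile_realised_in_expectation(self):
        cfg = SimulationConfig(seed=3)
        pop = sample_population(cfg)
        exp = np.array([m.expected_si() for m in pop.neurons])
        prof = SIProfile()
        assert np.sum(exp > 0) == prof.n_body
        assert np.sum(exp < 0) == prof.n_nonbody
        lo, hi = NONSELECTIVE_BAND
        assert np.sum((exp > lo) & (exp < hi)) == prof.n_near_zero

    def test_all_zero_tuning_profile(self):
        cfg = SimulationConfig(n_neurons=10, seed=0)
        prof = SIProfile(n_body=5, n_nonbody=5, n_near_zero=10)
        pop = sample_population(cfg, prof)
        # every neuron sits inside the near-zero band by construction
        assert all(abs(m.expected_si()) < 0.037 for m in pop.neurons)

    def test_infeasible_profile_rejected(self):
        cfg = SimulationConfig(n_neurons=10, seed=0)
        with pytest.raises(ValueError, match="profile"):
            sample_population(cfg, SIProfile(n_body=9, n_nonbody=9, n_near_zero=0))

    def test_thresholds_balance_the_two_categories(self, default_dataset):
        """The per-level criterion keeps body/non-body accuracy within a few %."""
        df, _ = default_dataset
        act = df[(df["task"] == "active") & (df["signal_level"] == 40)]
        acc = (act["outcome"] == "correct").groupby(act["category"]).mean()
        assert abs(acc["body"] - acc["nonbody"]) < 0.05

    def test_empirical_si_recovers_expected(self, default_dataset, default_selectivity):
        """Estimated SI tracks the generator's expected SI (r > 0.9)."""
        _, manifest = default_dataset
        expected = pd.Series(
            {m["neuron_id"]: m["expected_si"] for m in manifest["neurons"]}
        ).loc[default_selectivity.index]
        r = np.corrcoef(expected, default_selectivity["si"])[0, 1]
        assert r > 0.9


class TestChoiceModel:
    @pytest.fixture()
    def tiny_population(self):
        neurons = [
            flat_neuron(),
            NeuronModel("n1", 10.0, -1, 4.0, task_gain=TaskGain(0.0)),
        ]
        return PopulationModel(
            neurons=neurons,
            readout_weights=np.array([1.0, -1.0]),
            decision_noise=0.0,
            lapse_rate=0.0,
        )

    def test_deterministic_readout(self, tiny_population):
        rng = rng_stream(0, 0)
        counts = tiny_population.baseline_counts() + np.array([3.0, 0.0])
        choice, outcome = simulate_choice(tiny_population, counts, "body", 90, rng)
        assert (choice, outcome) == ("body", "correct")
        counts = tiny_population.baseline_counts() + np.array([0.0, 3.0])
        choice, outcome = simulate_choice(tiny_population, counts, "body", 90, rng)
        assert (choice, outcome) == ("nonbody", "wrong")

    def test_infinite_noise_gives_chance(self, tiny_population):
        tiny_population.decision_noise = 1e9
        rng = rng_stream(1, 0)
        counts = tiny_population.baseline_counts() + np.array([50.0, 0.0])
        picks = [
            simulate_choice(tiny_population, counts, "body", 90, rng)[0]
            for _ in range(2000)
        ]
        assert np.mean(np.array(picks) == "body") == pytest.approx(0.5, abs=0.04)

    def test_full_noise_reward_is_a_coin(self, default_dataset):
        df, _ = default_dataset
        noise = df[(df["task"] == "active") & (df["signal_level"] == 0)]
        assert (noise["outcome"] == "correct").mean() == pytest.approx(0.5, abs=0.02)
        assert (noise["choice"] == "body").mean() == pytest.approx(0.5, abs=0.05)

    def test_count_vector_length_checked(self, tiny_population):
        with pytest.raises(ValueError, match="expected 2 counts"):
            simulate_choice(tiny_population, np.zeros(3), "body", 90, rng_stream(0, 0))


class TestGenerateDataset:
    def test_design_structure(self, default_dataset):
        """810 trials per task per neuron: 720 noisy + 90 full noise."""
        df, _ = default_dataset
        per = df.groupby(["neuron_id", "task"]).size()
        assert (per == 810).all()
        one = df[(df["neuron_id"] == "n000") & (df["task"] == "passive")]
        assert (one["signal_level"] == 0).sum() == 90
        by_level = one[one["signal_level"] > 0].groupby(
            ["signal_level", "category"]
        ).size()
        assert (by_level == 90).all()

    def test_preceding_category_follows_block_order(self, small_dataset):
        df, _ = small_dataset
        one = df[(df["neuron_id"] == "n001") & (df["task"] == "active")].reset_index()
        for block_start in range(0, len(one), 90):
            block = one.iloc[block_start : block_start + 90]
            assert block.iloc[0]["preceding_category"] == "none"
            np.testing.assert_array_equal(
                block["preceding_category"].to_numpy()[1:],
                block["category"].to_numpy()[:-1],
            )

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(
            n_neurons=4, n_stimuli_per_category=10, n_noise_stimuli=10, seed=21
        )
        df1, _ = generate_dataset(cfg)
        df2, _ = generate_dataset(cfg)
        assert df1.drop(columns="spike_times").equals(df2.drop(columns="spike_times"))
        for a, b in zip(df1["spike_times"], df2["spike_times"]):
            np.testing.assert_array_equal(a, b)

    def test_psychometric_shape(self, default_dataset):
        """Accuracy rises with signal and sits at chance for 0% signal."""
        df, _ = default_dataset
        psy = psychometric(df)
        assert list(psy.index) == [40, 55, 70, 90]
        assert np.all(np.diff(psy.to_numpy()) > 0)

    def test_passive_trials_carry_no_behaviour(self, small_dataset):
        df, _ = small_dataset
        passive = df[df["task"] == "passive"]
        assert (passive["outcome"] == "none").all()
        assert (passive["choice"] == "none").all()
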