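"""Hand-built fixture generators shared between test modules."""
import numpy as np

from itpopcode import NeuronModel, TaskGain, simulate_trial
from itpopcode.io import trials_to_frame
from itpopcode.stats import rng_stream


def informative_core_frame(n_informative=5, n_noise=15, n_per_cat=40, seed=8,
                           tuning=7.0):
    """Passive trials where only the first ``n_informative`` neurons are tuned."""
    rng = rng_stream(seed, 0)
    trials = []
    tunings = [tuning] * n_informative + [0.0] * n_noise
    for j, t in enumerate(tunings):
        neuron = NeuronModel(f"n{j:03d}", 10.0, 1, float(t), task_gain=TaskGain(0.0))
        for cat, sub in (("body", "human"), ("nonbody", "car")):
            for i in range(n_per_cat):
                trials.append(
                    simulate_trial(
                        neuron, "passive", cat, 90, rng,
                        stimulus_id=f"{cat[0]}{i:03d}_s90", subcategory=sub,
                    )
                )
    return trials_to_frame(trials)
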