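"""Generate a synthetic recording session set and inspect the behaviour.

Builds a scaled-down experiment (40 neurons, 60 stimuli per category at four
signal levels plus 60 full-noise stimuli, passive + active tasks), writes the
trial table and manifest, and prints the psychometric curve.  Accuracy should
fall toward the 50% chance level as the visual signal decreases, and reward
on 0%-signal trials is a fair coin by design.
"""
from pathlib import Path

from itpopcode import SimulationConfig, generate_dataset, psychometric, write_trials
from itpopcode.io import write_manifest

out = Path("scratch")
out.mkdir(exist_ok=True)

config = SimulationConfig(
    n_neurons=40, n_stimuli_per_category=60, n_noise_stimuli=60, seed=1
)
df, manifest = generate_dataset(config)
write_trials(df, out / "dataset.tsv")
write_manifest(manifest, out / "manifest.json")

print(f"{len(df)} trials ({config.n_neurons} neurons x 2 tasks x "
      f"{len(df) // (2 * config.n_neurons)} presentations)")
print("\nProportion correct by signal level (active task):")
for level, acc in psychometric(df).items():
    print(f"  {level:>3}% signal: {acc:.3f}")
noise = df[(df.task == "active") & (df.signal_level == 0)]
print(f"    0% signal: {(noise.outcome == 'correct').mean():.3f} (random reward)")
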