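"""How category information accumulates as neurons are added.

Neurons are ranked by single-unit CI and added one at a time to the
pseudo-population; the curve of CI vs population size shows how much of the
"ultimate" (all-units) information a few informative units carry.  The
units-per-fraction estimator reports the smallest population explaining
25/50/75/95% of the ultimate CI, per bootstrap repetition.
"""
from itpopcode import (
    Condition,
    SimulationConfig,
    adding_curve,
    compute_selectivity,
    generate_dataset,
    rank_neurons,
    select_neurons,
    units_for_fraction,
)

df, _ = generate_dataset(
    SimulationConfig(n_neurons=40, n_stimuli_per_category=60, n_noise_stimuli=60, seed=3)
)
sel = compute_selectivity(df)
group = select_neurons(sel, "top_k", k=16)
cond = Condition("passive", 90)

order = rank_neurons(df, group, "decreasing_unit_ci", condition=cond)
curve = adding_curve(df, cond, order, n_reps=60, seed=0)

mean = curve.mean_curve()
print("CI vs population size (most informative units first):")
for k in (1, 2, 4, 8, 16):
    print(f"  {k:>2} units: CI = {mean[k - 1]:.2f} +/- {curve.results[k - 1].sd:.2f}")

print("\nunits explaining a fraction of the ultimate CI:")
for res in units_for_fraction(curve):
    print(f"  {int(res.fraction * 100):>2}%: {res.n_units:.1f} +/- {res.sd:.1f} units")
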