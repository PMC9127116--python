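"""Synthetic spiking datasets with the structure the analyses assume.

The generator emulates a two-task experiment on body/non-body visual
categorization: each simulated neuron is presented 90 body and 90 non-body
stimuli at four signal levels (90/70/55/40% of pixels intact) plus 90
full-noise stimuli, once per task (passive fixation and active
categorization), in blocks of 90 trials.

Rate model (piecewise-constant, per trial)::

    baseline_rate                                   on [-500, 70) ms
    baseline + (s/100) * tuning * gain * matched    on [ 70, 420) ms
    baseline_rate                                   on [420, 600) ms

where ``matched`` is 1 when the stimulus category equals the neuron's
preference, ``s`` is the signal level, and ``gain`` is a multiplicative
task gain >= 1 applied to the tuning component in active trials only.  The
default gain grows as the signal level falls, emulating difficulty-dependent
response enhancement.

The task gain is gated by a per-trial latent attention state shared by the
whole population: with probability ``attention_reliability`` an active
trial is attended and the gain applies; on unattended trials stimulus
encoding is suppressed below the passive-viewing level (attention diverted
from the stimulus), ``unattended_gain`` times the tuning.  Choices on
active trials are produced mechanistically:
a linear readout of the whole population's evoked spike counts plus
Gaussian decision noise (whose level varies across recording sessions),
with a small lapse rate.  Because the readout sees the same noisy counts
the dataset records, wrong trials are the trials on which the population
response happened to be uninformative -- unattended, or unlucky in its
count noise -- so category information degrades in wrong trials by
selection, not by relabeling, and the same coupling gives individual
neurons above-chance choice probability on full-noise trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CATEGORIES,
    EVOKED_WINDOW,
    FULL_NOISE_LEVEL,
    NOISE_SUBCATEGORY,
    SIGNAL_LEVELS,
    TrialRecord,
)
from .io import trials_to_frame
from .stats import rng_stream

_EVOKED_S = (EVOKED_WINDOW[1] - EVOKED_WINDOW[0]) / 1000.0  # 0.35 s
_SEGMENTS = ((-500.0, 70.0), EVOKED_WINDOW, (420.0, 600.0))

# substream namespaces, so adding a stage never perturbs another stage's draws
_NS_POPULATION = 0
_NS_NEURON = 1
_NS_ORDER = 2
_NS_CHOICE = 3


@dataclass(frozen=True)
class TaskGain:
    """Multiplicative active-task gain on the tuning component.

    ``gain(s) = 1 + strength * (1 - s/100)**curvature``: unity at full
    signal, largest for the most ambiguous stimuli.  ``curvature > 1``
    concentrates the modulation on the hardest stimuli, the difficulty
    dependence the enhancement analyses probe.  ``strength = 0`` disables
    the task effect entirely (the no-task-effect null).
    """

    strength: float = 2.2
    curvature: float = 1.5

    def __call__(self, signal_level: float) -> float:
        g = 1.0 + self.strength * (1.0 - signal_level / 100.0) ** self.curvature
        if g < 1.0:
            raise ValueError("task gain must be >= 1 at every signal level")
        return g


@dataclass
class NeuronModel:
    """Rate parameters of one simulated neuron."""

    neuron_id: str
    baseline_rate: float  # spikes/s
    preference: int  # +1 body, -1 nonbody
    tuning: float  # spikes/s added for the preferred category at 100% signal
    task_gain: TaskGain = field(default_factory=TaskGain)
    dispersion: float = 1.0  # Fano-like factor of the segment counts
    #: attention-marginal active gain (set by sample_population); used for
    #: trial-averaged expectations, while task_gain is the attended-trial gain
    active_gain_fn: object | None = None

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.tuning < 0:
            raise ValueError("rates must be nonnegative")
        if self.preference not in (-1, 1):
            raise ValueError("preference must be +1 (body) or -1 (nonbody)")
        if self.dispersion < 1.0:
            raise ValueError("dispersion below 1 (sub-Poisson) is not modelled")

    @property
    def preferred_category(self) -> str:
        return "body" if self.preference > 0 else "nonbody"

    def evoked_rate(
        self, task: str, category: str, signal_level: float, marginal: bool = False
    ) -> float:
        """Firing rate on [70, 420) ms for one stimulus condition, spikes/s.

        Active-task rates default to the attended-trial gain; ``marginal``
        uses the attention-marginal gain instead when one is set.
        """
        if task == "active":
            if marginal and self.active_gain_fn is not None:
                gain = self.active_gain_fn(signal_level)
            else:
                gain = self.task_gain(signal_level)
        else:
            gain = 1.0
        matched = category == self.preferred_category
        return self.baseline_rate + (signal_level / 100.0) * self.tuning * gain * matched

    def expected_si(self, task: str = "active") -> float:
        """Expected (trial-averaged) selectivity index over the four levels.

        SI at one level is (mu_pref - mu_null) / (mu_pref + mu_null) with the
        sign of the preference; evoked means are rate * window duration, so
        the duration cancels.  Active-task expectations marginalize over the
        attention state.
        """
        vals = []
        for s in SIGNAL_LEVELS:
            mu_p = self.evoked_rate(task, self.preferred_category, s, marginal=True)
            mu_n = self.baseline_rate
            tot = mu_p + mu_n
            vals.append(0.0 if tot == 0 else (mu_p - mu_n) / tot)
        return self.preference * float(np.mean(vals))


@dataclass
class PopulationModel:
    """A set of neurons plus the linear readout that generates choices.

    ``thresholds`` maps each signal level to the evidence criterion that
    equalizes expected body/non-body accuracy (the midpoint of the two
    category-conditional evidence means); an unbalanced criterion would
    otherwise arise whenever the body and non-body readout pools differ in
    size.
    """

    neurons: list[NeuronModel]
    readout_weights: np.ndarray  # signed weight per neuron (body-positive)
    decision_noise: float  # SD of additive evidence noise
    lapse_rate: float  # probability of replacing the choice with a coin flip
    thresholds: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.readout_weights = np.asarray(self.readout_weights, dtype=float)
        if len(self.readout_weights) != len(self.neurons):
            raise ValueError("one readout weight per neuron required")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must be in [0, 1)")

    def threshold(self, signal_level: int) -> float:
        if not self.thresholds:
            return 0.0
        return self.thresholds.get(int(signal_level), 0.0)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def expected_evoked_counts(self, task: str, category: str, signal_level: float) -> np.ndarray:
        return np.array(
            [n.evoked_rate(task, category, signal_level) * _EVOKED_S for n in self.neurons]
        )

    def baseline_counts(self) -> np.ndarray:
        return np.array([n.baseline_rate * _EVOKED_S for n in self.neurons])


@dataclass(frozen=True)
class SIProfile:
    """Target composition of the population's selectivity distribution.

    Mirrors the empirical grouping: ``n_body``/``n_nonbody`` neurons with
    positive/negative expected SI, of which ``n_near_zero`` fall strictly
    inside the non-selective band.  Magnitudes outside the band are drawn as
    ``band_edge + |N(0, si_spread)|``.
    """

    n_body: int = 75
    n_nonbody: int = 48
    n_near_zero: int = 36
    band_edge: float = 0.037
    si_spread: float = 0.15

    def validate(self, n_neurons: int) -> None:
        if self.n_body + self.n_nonbody != n_neurons:
            raise ValueError(
                f"profile covers {self.n_body + self.n_nonbody} neurons, "
                f"config has {n_neurons}"
            )
        if self.n_near_zero > n_neurons:
            raise ValueError("more near-zero neurons than neurons")
        if min(self.n_body, self.n_nonbody, self.n_near_zero) < 0:
            raise ValueError("profile counts must be nonnegative")
        if self.band_edge <= 0 or self.si_spread <= 0:
            raise ValueError("band_edge and si_spread must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated experiment."""

    n_neurons: int = 123
    n_stimuli_per_category: int = 90
    signal_levels: tuple[int, ...] = SIGNAL_LEVELS
    include_full_noise: bool = True
    n_noise_stimuli: int = 90
    tasks: tuple[str, ...] = ("passive", "active")
    block_size: int = 90
    baseline_rate_mean: float = 10.0  # sp/s -> ~2 spikes per 200-ms window
    baseline_rate_shape: float = 4.0  # gamma shape of the across-neuron spread
    gain_strength: float = 2.2
    gain_curvature: float = 1.5
    readout_alignment: float = 0.45  # cosine between readout and tuning axis
    decision_noise: float = 0.5  # relative to unit neural evidence SD
    session_noise_jitter: float = 0.3  # lognormal sigma of per-session noise
    attention_reliability: float = 0.7  # mean P(trial attended) in the active task
    attention_session_sd: float = 0.18  # across-session SD of that probability
    unattended_gain: float = 0.3  # tuning multiplier on unattended active trials
    lapse_rate: float = 0.005
    dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_stimuli_per_category < 1:
            raise ValueError("counts must be positive")
        for s in self.signal_levels:
            if not 0 < s <= 100:
                raise ValueError("signal levels must lie in (0, 100]")
        if not 0.0 <= self.readout_alignment <= 1.0:
            raise ValueError("readout_alignment must be in [0, 1]")


def default_si_profile(config: SimulationConfig) -> SIProfile:
    """Scale the 75/48/36 composition to the configured population size."""
    n = config.n_neurons
    n_body = int(round(n * 75 / 123))
    n_near = int(round(n * 36 / 123))
    return SIProfile(n_body=n_body, n_nonbody=n - n_body, n_near_zero=min(n_near, n))


def _solve_tuning(
    targets: np.ndarray, baselines: np.ndarray, gain: TaskGain, levels
) -> np.ndarray:
    """Invert |expected SI| -> tuning (sp/s) by vectorised bisection.

    The mean over levels of ``q_s T / (2b + q_s T)`` with
    ``q_s = (s/100) * gain(s)`` is strictly increasing in T, from 0 toward 1.
    """
    targets = np.asarray(targets, dtype=float)
    if np.any(targets >= 1.0) or np.any(targets < 0):
        raise ValueError("target |SI| must lie in [0, 1)")
    q = np.array([(s / 100.0) * gain(s) for s in levels])

    def mean_si(T):
        return np.mean(q[:, None] * T[None, :] / (2 * baselines[None, :] + q[:, None] * T[None, :]), axis=0)

    lo = np.zeros_like(targets)
    hi = np.full_like(targets, 1.0)
    # expand hi until it brackets every target
    for _ in range(80):
        mask = mean_si(hi) < targets
        if not mask.any():
            break
        hi[mask] *= 2.0
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        too_low = mean_si(mid) < targets
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    out = 0.5 * (lo + hi)
    out[targets == 0] = 0.0
    return out


def sample_population(
    config: SimulationConfig, si_profile: SIProfile | None = None
) -> PopulationModel:
    """Draw neuron parameters whose expected SIs realise the profile.

    Baseline rates are gamma-distributed across neurons; target SI
    magnitudes are uniform inside the non-selective band for the near-zero
    group and shifted half-normal outside it; tuning strengths are solved
    from the targets given each neuron's baseline and the task gain.
    """
    profile = si_profile or default_si_profile(config)
    profile.validate(config.n_neurons)
    rng = rng_stream(config.seed, _NS_POPULATION)
    n = config.n_neurons
    gain = TaskGain(config.gain_strength, config.gain_curvature)

    # attention gates the gain on a random subset of trials, so the gain that
    # matters for trial-averaged active-task quantities is the mixture of the
    # attended gain and the unattended suppression
    def eff_gain(s: float) -> float:
        p = config.attention_reliability
        return p * gain(s) + (1.0 - p) * config.unattended_gain

    shape = config.baseline_rate_shape
    baselines = rng.gamma(shape, config.baseline_rate_mean / shape, size=n)
    baselines = np.maximum(baselines, 0.5)

    near = np.zeros(n, dtype=bool)
    near[rng.choice(n, size=profile.n_near_zero, replace=False)] = True
    mags = np.where(
        near,
        rng.uniform(0.0, profile.band_edge * 0.98, size=n),
        profile.band_edge + np.abs(rng.normal(0.0, profile.si_spread, size=n)),
    )
    mags = np.minimum(mags, 0.85)
    signs = np.concatenate(
        [np.ones(profile.n_body, dtype=int), -np.ones(profile.n_nonbody, dtype=int)]
    )
    rng.shuffle(signs)

    tunings = _solve_tuning(mags, baselines, eff_gain, config.signal_levels)
    neurons = [
        NeuronModel(
            neuron_id=f"n{j:03d}",
            baseline_rate=float(baselines[j]),
            preference=int(signs[j]),
            tuning=float(tunings[j]),
            task_gain=gain,
            dispersion=config.dispersion,
            active_gain_fn=eff_gain,
        )
        for j in range(n)
    ]

    # readout direction: partly aligned with the signed tuning axis, partly
    # random, then scaled so the neural contribution to the evidence has
    # roughly unit variance (Poisson count variance ~ mean at baseline)
    u_sig = signs * tunings
    nrm = np.linalg.norm(u_sig)
    u_sig = u_sig / nrm if nrm > 0 else np.zeros(n)
    u_rand = rng.normal(size=n)
    u_rand /= np.linalg.norm(u_rand)
    kappa = config.readout_alignment
    w = kappa * u_sig + np.sqrt(max(0.0, 1.0 - kappa**2)) * u_rand

    # balance the two readout pools so the category-conditional evidence
    # means are symmetric about zero in *every* attention/gain state (the
    # gain multiplies both pools alike).  The evidence bias is w . |T| and
    # the category separation is w . (signs*T); correcting along the part
    # of |T| orthogonal to signs*T zeroes the bias while leaving the
    # separation untouched, so the criterion is unbiased at threshold 0
    # with no loss of readout signal.
    t_abs = tunings.copy()
    sep_axis = u_sig  # unit vector along signs*tunings (or zero)
    c = t_abs - (t_abs @ sep_axis) * sep_axis
    denom = float(c @ t_abs)
    if denom > 1e-12:
        w = w - ((w @ t_abs) / denom) * c
    thresholds: dict[int, float] = {FULL_NOISE_LEVEL: 0.0}
    for s in config.signal_levels:
        thresholds[int(s)] = 0.0
    neural_var = float(np.sum(w**2 * baselines * _EVOKED_S))
    if neural_var > 0:
        w = w / np.sqrt(neural_var)
    return PopulationModel(
        neurons=neurons,
        readout_weights=w,
        decision_noise=config.decision_noise,
        lapse_rate=config.lapse_rate,
        thresholds=thresholds,
    )


def _segment_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Counts with mean ``means`` and variance ``dispersion * means``."""
    means = np.maximum(means, 0.0)
    if dispersion <= 1.0:
        return rng.poisson(means)
    shape = means / (dispersion - 1.0)
    lam = rng.gamma(np.maximum(shape, 1e-12), dispersion - 1.0)
    lam[means == 0] = 0.0
    return rng.poisson(lam)


def simulate_trial(
    neuron: NeuronModel,
    task: str,
    category: str,
    signal_level: int,
    rng: np.random.Generator,
    stimulus_id: str = "stim",
    **metadata,
) -> TrialRecord:
    """Draw one trial's spike train from the piecewise-constant rate model."""
    evoked = neuron.evoked_rate(task, category, signal_level)
    rates = (neuron.baseline_rate, evoked, neuron.baseline_rate)
    times = []
    for (lo, hi), rate in zip(_SEGMENTS, rates):
        m = rate * (hi - lo) / 1000.0
        k = int(_segment_counts(rng, np.array([m]), neuron.dispersion)[0])
        if k:
            times.append(rng.uniform(lo, hi, size=k))
    spikes = np.unique(np.concatenate(times)) if times else np.empty(0)
    # standalone use: active trials need a consistent behavioural record,
    # so default to a correct choice unless the caller provides one
    default_choice = "none" if task == "passive" else category
    default_outcome = "none" if task == "passive" else "correct"
    meta = dict(
        session_id=metadata.pop("session_id", "sim"),
        subcategory=metadata.pop(
            "subcategory",
            NOISE_SUBCATEGORY
            if signal_level == FULL_NOISE_LEVEL
            else ("human" if category == "body" else "car"),
        ),
        outcome=metadata.pop("outcome", default_outcome),
        choice=metadata.pop("choice", default_choice),
        preceding_category=metadata.pop("preceding_category", "none"),
    )
    return TrialRecord(
        neuron_id=neuron.neuron_id,
        task=task,
        stimulus_id=stimulus_id,
        category=category,
        signal_level=signal_level,
        spike_times=spikes,
        **meta,
    )


def simulate_choice(
    population: PopulationModel,
    trial_counts: np.ndarray,
    category: str,
    signal_level: int,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Readout one trial's evoked counts into a (choice, outcome) pair.

    Evidence is the weighted sum of baseline-centred evoked counts plus
    Gaussian noise; positive evidence means a "body" choice.  With
    probability ``lapse_rate`` the choice is replaced by a coin flip.  On
    full-noise trials the outcome is a fair coin (random reward).
    """
    counts = np.asarray(trial_counts, dtype=float)
    if counts.shape != (population.n_neurons,):
        raise ValueError(
            f"expected {population.n_neurons} counts, got shape {counts.shape}"
        )
    evidence = float(
        population.readout_weights @ (counts - population.baseline_counts())
    )
    evidence += rng.normal(0.0, population.decision_noise)
    choice = "body" if evidence > population.threshold(signal_level) else "nonbody"
    if rng.random() < population.lapse_rate:
        choice = "body" if rng.random() < 0.5 else "nonbody"
    if signal_level == FULL_NOISE_LEVEL:
        outcome = "correct" if rng.random() < 0.5 else "wrong"
    else:
        outcome = "correct" if choice == category else "wrong"
    return choice, outcome


def _stimulus_table(config: SimulationConfig) -> pd.DataFrame:
    """All distinct stimuli of the experiment (noisy instances + full noise)."""
    sub_body = ("human", "monkey", "fourleg")
    sub_nonbody = ("airplane", "car", "chair")
    rows = []
    per_sub = max(1, config.n_stimuli_per_category // 3)
    for level in config.signal_levels:
        for cat, subs, prefix in (
            ("body", sub_body, "b"),
            ("nonbody", sub_nonbody, "o"),
        ):
            for i in range(config.n_stimuli_per_category):
                rows.append(
                    {
                        "stimulus_id": f"{prefix}{i:03d}_s{level}",
                        "category": cat,
                        "subcategory": subs[min(i // per_sub, 2)],
                        "signal_level": level,
                    }
                )
    if config.include_full_noise:
        for i in range(config.n_noise_stimuli):
            rows.append(
                {
                    "stimulus_id": f"z{i:03d}_s0",
                    # nominal balanced labels; full-noise images carry no category
                    "category": CATEGORIES[i % 2],
                    "subcategory": NOISE_SUBCATEGORY,
                    "signal_level": FULL_NOISE_LEVEL,
                }
            )
    return pd.DataFrame(rows)


def _spike_trains(
    rng: np.random.Generator, seg_counts: np.ndarray
) -> list[np.ndarray]:
    """Uniform spike times per trial given (n_trials, 3) segment counts."""
    n_trials = seg_counts.shape[0]
    seg_times = []
    for s, (lo, hi) in enumerate(_SEGMENTS):
        total = int(seg_counts[:, s].sum())
        seg_times.append(np.split(rng.uniform(lo, hi, total), np.cumsum(seg_counts[:, s])[:-1]))
    return [
        np.unique(np.concatenate((seg_times[0][i], seg_times[1][i], seg_times[2][i])))
        for i in range(n_trials)
    ]


def generate_dataset(
    config: SimulationConfig,
    si_profile: SIProfile | None = None,
    population: PopulationModel | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the full experiment: a trial table plus a JSON-able manifest.

    Every stimulus is presented exactly once per task per neuron, in a
    per-neuron random order split into blocks; ``preceding_category`` holds
    the category of the previous stimulus within a block ("none" at block
    starts).  Deterministic given ``config.seed``.
    """
    if population is None:
        population = sample_population(config, si_profile)
    stim = _stimulus_table(config)
    n_stim = len(stim)
    weights = population.readout_weights
    baseline_counts = population.baseline_counts()
    all_tunings = np.array([m.tuning for m in population.neurons])
    all_baselines = np.array([m.baseline_rate for m in population.neurons])
    all_prefs = np.array([m.preference for m in population.neurons])
    gain = population.neurons[0].task_gain if population.neurons else TaskGain(0.0)

    frames = []
    for j, neuron in enumerate(population.neurons):
        rng_order = rng_stream(config.seed, _NS_ORDER, j)
        rng_spk = rng_stream(config.seed, _NS_NEURON, j)
        rng_cho = rng_stream(config.seed, _NS_CHOICE, j)
        # behavioural state varies across recording sessions: each session
        # gets its own decision-noise level (lognormal around the default)
        # and its own attentional engagement (beta around the mean), the
        # latter being the dominant source of across-session performance
        # differences
        session_noise = population.decision_noise * float(
            np.exp(config.session_noise_jitter * rng_cho.normal())
        )
        m, v = config.attention_reliability, config.attention_session_sd**2
        if v > 0:
            k = max(m * (1 - m) / v - 1.0, 0.5)
            session_attention = float(rng_cho.beta(m * k, (1 - m) * k))
        else:
            session_attention = m
        for task in config.tasks:
            order = rng_order.permutation(n_stim)
            s = stim.iloc[order].reset_index(drop=True)
            block_pos = np.arange(n_stim) % config.block_size
            preceding = np.roll(s["category"].to_numpy(), 1)
            preceding[block_pos == 0] = "none"

            levels = s["signal_level"].to_numpy(dtype=float)
            cats = s["category"].to_numpy()
            matched = (cats == neuron.preferred_category).astype(float)
            if task == "active":
                # one attention state per presentation, shared by the whole
                # population (it gates the gain of recorded and unrecorded
                # neurons alike); unattended trials have suppressed stimulus
                # encoding, below the passive-viewing level
                attended = rng_cho.random(n_stim) < session_attention
                g_att = np.array([gain(s) for s in levels])
                g = np.where(attended, g_att, config.unattended_gain)
            else:
                g = np.ones(n_stim)
            evoked = neuron.baseline_rate + (levels / 100.0) * neuron.tuning * g * matched

            seg_counts = np.empty((n_stim, 3), dtype=np.int64)
            for k, (lo, hi) in enumerate(_SEGMENTS):
                rate = evoked if k == 1 else np.full(n_stim, neuron.baseline_rate)
                seg_counts[:, k] = _segment_counts(
                    rng_spk, rate * (hi - lo) / 1000.0, neuron.dispersion
                )
            spikes = _spike_trains(rng_spk, seg_counts)

            if task == "active":
                # evoked counts of the rest of the population for each
                # presentation; the recorded neuron contributes its own count
                match_all = (cats[:, None] == np.where(all_prefs > 0, "body", "nonbody")[None, :])
                rates_all = all_baselines[None, :] + (
                    (levels / 100.0)[:, None] * all_tunings[None, :] * g[:, None] * match_all
                )
                counts_all = rng_cho.poisson(rates_all * _EVOKED_S).astype(float)
                counts_all[:, j] = seg_counts[:, 1]
                evidence = (counts_all - baseline_counts[None, :]) @ weights
                evidence += rng_cho.normal(0.0, session_noise, size=n_stim)
                crit = np.array([population.threshold(int(s)) for s in levels])
                choices = np.where(evidence > crit, "body", "nonbody")
                lapses = rng_cho.random(n_stim) < population.lapse_rate
                coin = rng_cho.random(n_stim) < 0.5
                choices = np.where(lapses, np.where(coin, "body", "nonbody"), choices)
                outcomes = np.where(choices == cats, "correct", "wrong")
                noise_mask = levels == FULL_NOISE_LEVEL
                noise_coin = rng_cho.random(n_stim) < 0.5
                outcomes = np.where(
                    noise_mask, np.where(noise_coin, "correct", "wrong"), outcomes
                )
            else:
                choices = np.full(n_stim, "none")
                outcomes = np.full(n_stim, "none")

            frames.append(
                pd.DataFrame(
                    {
                        "neuron_id": neuron.neuron_id,
                        "session_id": f"sess{j:03d}",
                        "task": task,
                        "stimulus_id": s["stimulus_id"],
                        "category": cats,
                        "subcategory": s["subcategory"],
                        "signal_level": s["signal_level"].astype(int),
                        "outcome": outcomes,
                        "choice": choices,
                        "preceding_category": preceding,
                        "spike_times": spikes,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "n_trials": int(len(df)),
        "neurons": [
            {
                "neuron_id": m.neuron_id,
                "baseline_rate": m.baseline_rate,
                "preference": m.preference,
                "tuning": m.tuning,
                "expected_si": m.expected_si(),
                "readout_weight": float(weights[j]),
            }
            for j, m in enumerate(population.neurons)
        ],
        "decision_noise": population.decision_noise,
        "lapse_rate": population.lapse_rate,
    }
    return df, manifest


def psychometric(df: pd.DataFrame) -> pd.Series:
    """Proportion correct by signal level in the active task (behaviour)."""
    act = df[(df["task"] == "active") & (df["signal_level"] > 0)]
    return (
        (act["outcome"] == "correct")
        .groupby(act["signal_level"])
        .mean()
        .sort_index()
    )


__all__ = [
    "TaskGain",
    "NeuronModel",
    "PopulationModel",
    "SIProfile",
    "SimulationConfig",
    "default_si_profile",
    "sample_population",
    "simulate_trial",
    "simulate_choice",
    "generate_dataset",
    "psychometric",
    "trials_to_frame",
]
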