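"""Choice probability (CP) of single neurons on full-noise trials.

Full-noise (0% signal) stimuli carry no category information, so any
association between a neuron's firing and the animal's body/non-body
choice is choice-related rather than stimulus-related.  CP is the area
under the empirical ROC curve separating the evoked spike-count
distributions of body-choice and non-body-choice trials -- equivalently
the Mann-Whitney U statistic divided by n1*n2 with ties counted 0.5 -- so
0.5 is chance and 1 a perfect association.  Significance uses a
permutation null (choice labels shuffled preserving class counts) with a
one-tailed criterion at the 90th percentile of the null by default.

Orientation: "body" scores the AUC toward the body-choice distribution;
"preference" flips it for nonbody-preferring neurons so that informative
neurons of either polarity score above 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import CI_WINDOW, FULL_NOISE_LEVEL, WindowLike, counts_in_window
from .population import Condition
from .scatter import ci_single_unit
from .selectivity import compute_selectivity
from .stats import exceedance_p, paired_rank_test, rng_stream


@dataclass
class ChoiceProbabilityResult:
    """CP of one neuron with its permutation null."""

    neuron_id: str
    cp: float
    null_samples: np.ndarray
    null_mean: float
    significant: bool
    p_value: float
    n_body_choice: int
    n_nonbody_choice: int
    orientation: str


def _auc_toward_body(responses: np.ndarray, is_body_choice: np.ndarray) -> float:
    """P(body-choice response > nonbody-choice response), ties counted 0.5."""
    n1 = int(is_body_choice.sum())
    n2 = int((~is_body_choice).sum())
    ranks = rankdata(responses)  # average ranks handle ties as 0.5
    u = float(ranks[is_body_choice].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def choice_probability(
    responses: np.ndarray,
    choices: np.ndarray,
    orientation: str = "body",
    preference: str | None = None,
    min_trials: int = 5,
) -> float:
    """ROC area separating responses by the animal's choice.

    ``orientation='body'`` scores toward the body-choice distribution;
    ``'nonbody'`` the complement; ``'preference'`` scores toward the
    neuron's preferred category (requires ``preference``).
    """
    responses = np.asarray(responses, dtype=float)
    choices = np.asarray(choices)
    is_body = choices == "body"
    n1, n2 = int(is_body.sum()), int((~is_body).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both choice classes must be nonempty")
    if min(n1, n2) < min_trials:
        raise ValueError(
            f"fewer than {min_trials} trials in a choice class ({n1} body, "
            f"{n2} nonbody)"
        )
    cp = _auc_toward_body(responses, is_body)
    if orientation == "body":
        return cp
    if orientation == "nonbody":
        return 1.0 - cp
    if orientation == "preference":
        if preference not in ("body", "nonbody"):
            raise ValueError("orientation='preference' needs preference=body|nonbody")
        return cp if preference == "body" else 1.0 - cp
    raise ValueError(f"unknown orientation {orientation!r}")


def permutation_null(
    responses: np.ndarray,
    choices: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    criterion: float = 0.90,
    orientation: str = "body",
    preference: str | None = None,
    min_trials: int = 5,
) -> ChoiceProbabilityResult:
    """CP with a choice-label permutation null and one-tailed significance.

    Labels are shuffled preserving the class counts; a neuron is flagged
    when its CP exceeds the ``criterion`` quantile of the null (one-tailed,
    high side, after orientation).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unusably coarse null")
    responses = np.asarray(responses, dtype=float)
    choices = np.asarray(choices)
    cp = choice_probability(
        responses, choices, orientation=orientation, preference=preference,
        min_trials=min_trials,
    )
    is_body = choices == "body"
    n = len(choices)
    n1 = int(is_body.sum())
    n2 = n - n1
    ranks = rankdata(responses)
    rng = rng_stream(seed, 0)
    # vectorised label shuffles: pick n1 random positions per permutation
    pick = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    null_u = ranks[pick].sum(axis=1) - n1 * (n1 + 1) / 2.0
    null_cp = null_u / (n1 * n2)
    flip = (orientation == "nonbody") or (
        orientation == "preference" and preference == "nonbody"
    )
    if flip:
        null_cp = 1.0 - null_cp
    threshold = float(np.quantile(null_cp, criterion))
    return ChoiceProbabilityResult(
        neuron_id="",
        cp=float(cp),
        null_samples=null_cp,
        null_mean=float(null_cp.mean()),
        significant=bool(cp > threshold),
        p_value=exceedance_p(null_cp, cp, alternative="greater"),
        n_body_choice=n1,
        n_nonbody_choice=n2,
        orientation=orientation,
    )


def cp_analysis(
    df: pd.DataFrame,
    window: WindowLike = CI_WINDOW,
    n_perm: int = 1000,
    seed: int = 0,
    criterion: float = 0.90,
    orientation: str = "preference",
    selectivity: pd.DataFrame | None = None,
    min_trials: int = 5,
) -> pd.DataFrame:
    """Per-neuron CP on full-noise active trials (one row per neuron).

    Neurons with too few trials in a choice class are skipped.  With the
    default "preference" orientation the selectivity table is computed from
    the dataset unless supplied.
    """
    if orientation == "preference" and selectivity is None:
        selectivity = compute_selectivity(df)
    noise = df[
        (df["task"] == "active") & (df["signal_level"] == FULL_NOISE_LEVEL)
    ]
    rows = []
    for k, (nid, g) in enumerate(noise.groupby("neuron_id", sort=True)):
        pref = (
            str(selectivity.loc[nid, "polarity"]) if selectivity is not None else None
        )
        responses = counts_in_window(list(g["spike_times"]), window)
        try:
            res = permutation_null(
                responses,
                g["choice"].to_numpy(),
                n_perm=n_perm,
                seed=seed + k,
                criterion=criterion,
                orientation=orientation,
                preference=pref,
                min_trials=min_trials,
            )
        except ValueError:
            continue
        rows.append(
            {
                "neuron_id": nid,
                "cp": res.cp,
                "null_mean": res.null_mean,
                "p_value": res.p_value,
                "significant": res.significant,
                "n_body_choice": res.n_body_choice,
                "n_nonbody_choice": res.n_nonbody_choice,
                "preference": pref,
            }
        )
    return pd.DataFrame(rows).set_index("neuron_id")


def ci_in_high_cp(
    df: pd.DataFrame,
    cp_table: pd.DataFrame,
    window: WindowLike = CI_WINDOW,
    n_reps: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Single-unit CI of high-CP neurons: correct active vs passive trials.

    Returns one row per flagged neuron (CI in each condition, pooled over
    noisy signal levels) and the two-sided signed-rank p-value of the
    paired correct-vs-passive comparison.
    """
    flagged = list(cp_table.index[cp_table["significant"]])
    if len(flagged) < 2:
        raise ValueError(
            f"need at least 2 significant-CP neurons, got {len(flagged)}"
        )
    rows = []
    for nid in flagged:
        g = df[df["neuron_id"] == nid]
        ci_p = ci_single_unit(
            g, Condition("passive"), window=window, n_reps=n_reps, seed=seed
        )
        ci_c = ci_single_unit(
            g,
            Condition("active", outcome="correct"),
            window=window,
            n_reps=n_reps,
            seed=seed,
        )
        rows.append(
            {"neuron_id": nid, "ci_passive": ci_p.ci, "ci_correct": ci_c.ci}
        )
    table = pd.DataFrame(rows).set_index("neuron_id")
    p = paired_rank_test(table["ci_correct"], table["ci_passive"])
    return table, p
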