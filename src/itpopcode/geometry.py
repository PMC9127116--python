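"""Low-dimensional visualization of category structure.

Per-stimulus mean responses (stimuli x neurons) are projected onto the two
principal components of the neural covariance; each category's spread in
the plane is summarized by a 2-standard-deviation ellipse (semi-axes
2*sqrt of the 2-D covariance eigenvalues).  Component signs are fixed
deterministically (largest-magnitude loading positive) so projections are
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CI_WINDOW, WindowLike, counts_in_window
from .population import Condition


@dataclass
class Ellipse:
    """2-SD ellipse of one category's projected points."""

    center: np.ndarray  # (2,)
    semi_axes: np.ndarray  # (2,), descending
    angle_rad: float  # orientation of the major axis

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether points fall inside (Mahalanobis distance <= 2)."""
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, s], [-s, c]])
        local = (np.atleast_2d(points) - self.center) @ rot.T
        with np.errstate(divide="ignore", invalid="ignore"):
            z = local / np.where(self.semi_axes > 0, self.semi_axes, np.inf)
        return (z**2).sum(axis=1) <= 1.0


@dataclass
class Projection2D:
    """Stimuli projected onto the first two principal components."""

    points: np.ndarray  # (n_stimuli, 2)
    categories: np.ndarray
    subcategories: np.ndarray | None
    components: np.ndarray  # (2, n_neurons)
    variance_explained: float
    ellipses: dict[str, Ellipse]


def ellipse_2sd(points: np.ndarray) -> Ellipse:
    """Center, 2*sqrt(eigenvalue) semi-axes, and orientation of 2-D points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected (n, 2) points")
    if pts.shape[0] < 3:
        raise ValueError("ellipse needs at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    return Ellipse(
        center=center,
        semi_axes=2.0 * np.sqrt(vals),
        angle_rad=float(np.arctan2(vecs[1, 0], vecs[0, 0])),
    )


def project(
    matrix: np.ndarray,
    categories: np.ndarray,
    subcategories: np.ndarray | None = None,
) -> Projection2D:
    """Project per-stimulus mean responses onto the top two components.

    The component axes are eigenvectors of the across-stimulus neural
    covariance; points are centred, so the projection is invariant to
    adding a constant vector to every stimulus.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need at least 3 stimuli and 2 neurons")
    centered = x - x.mean(axis=0)
    total_var = float(np.sum(centered**2))
    if total_var == 0:
        raise ValueError("zero-variance input")
    cov = centered.T @ centered / (x.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    comps = vecs[:, :2].T.copy()
    for k in range(2):  # deterministic sign: largest |loading| positive
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] *= -1.0
    points = centered @ comps.T
    categories = np.asarray(categories)
    ellipses = {
        str(cat): ellipse_2sd(points[categories == cat])
        for cat in pd.unique(categories)
        if np.sum(categories == cat) >= 3
    }
    return Projection2D(
        points=points,
        categories=categories,
        subcategories=None if subcategories is None else np.asarray(subcategories),
        components=comps,
        variance_explained=float(vals[:2].sum() / vals.sum()),
        ellipses=ellipses,
    )


def stimulus_means(
    df: pd.DataFrame,
    condition: Condition,
    window: WindowLike = CI_WINDOW,
    neurons: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-stimulus mean spike counts (stimuli x neurons) under a condition.

    Only stimuli observed for every requested neuron are kept, so the
    matrix has no missing entries.
    """
    sub = df[condition.mask(df)]
    if neurons is not None:
        sub = sub[sub["neuron_id"].isin(neurons)]
    if sub.empty:
        raise ValueError(f"no trials under condition ({condition.describe()})")
    counts = counts_in_window(list(sub["spike_times"]), window)
    tbl = pd.DataFrame(
        {
            "stimulus_id": sub["stimulus_id"].to_numpy(),
            "neuron_id": sub["neuron_id"].to_numpy(),
            "count": counts,
        }
    )
    wide = (
        tbl.groupby(["stimulus_id", "neuron_id"])["count"].mean().unstack("neuron_id")
    ).dropna()
    labels = (
        sub[["stimulus_id", "category", "subcategory", "signal_level"]]
        .drop_duplicates("stimulus_id")
        .set_index("stimulus_id")
        .loc[wide.index]
        .reset_index()
    )
    return wide.to_numpy(dtype=float), labels


def project_condition(
    df: pd.DataFrame,
    condition: Condition,
    window: WindowLike = CI_WINDOW,
    neurons: list[str] | None = None,
) -> Projection2D:
    """Stimulus-mean projection for one condition (fit per condition)."""
    matrix, labels = stimulus_means(df, condition, window=window, neurons=neurons)
    return project(
        matrix,
        labels["category"].to_numpy(),
        labels["subcategory"].to_numpy(),
    )
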