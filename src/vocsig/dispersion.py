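"""Within-group dispersion in discriminant signal space.

Calls are projected onto the fitted discriminant functions ("signal
space"); each call's dispersion is its Euclidean distance to its own
group's centroid (the mean coordinate of that group, recomputed from the
projected calls so the measure also works for held-out data).  Group
differences in dispersion are tested with a one-way ANOVA on the per-call
distances, reported with partial eta squared
(SS_between / (SS_between + SS_within)) and Tukey-HSD post-hoc pairwise
comparisons (Bonferroni-corrected t-tests available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .discriminant import DiscriminantModel, FeatureTable

__all__ = [
    "SignalSpace",
    "DispersionResult",
    "project_to_signal_space",
    "dispersion_distances",
    "dispersion_anova",
]


@dataclass
class SignalSpace:
    """Per-call coordinates in discriminant-function space."""

    coordinates: np.ndarray  # (n_calls, n_functions_used)
    group_labels: np.ndarray
    n_functions_used: int

    def validate(self) -> None:
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be 2-D (calls x functions)")
        if self.n_functions_used < 1:
            raise ValueError("need at least one discriminant function")
        if self.coordinates.shape[0] != self.group_labels.shape[0]:
            raise ValueError("one label per call required")


@dataclass
class DispersionResult:
    """Dispersion distances and the ANOVA comparing them between groups."""

    per_call_distance: np.ndarray
    group_labels: np.ndarray
    group_mean_distance: pd.Series
    anova_F: float
    df_between: int
    df_within: int
    p_value: float
    partial_eta_squared: float
    posthoc: pd.DataFrame  # columns: group_a, group_b, p_adjusted


def project_to_signal_space(
    model: DiscriminantModel,
    table: FeatureTable,
    n_functions: int | None = None,
) -> SignalSpace:
    """Map each call to its scores on the first ``n_functions`` functions.

    ``n_functions=None`` uses all retained functions; 2 gives the
    two-dimensional space conventionally plotted.
    """
    k = model.n_functions if n_functions is None else int(n_functions)
    if not (1 <= k <= model.n_functions):
        raise ValueError(
            f"n_functions must be in [1, {model.n_functions}], got {n_functions}"
        )
    X, y = table.matrices(model.selected_features)
    coords = model.transform(X, k)
    space = SignalSpace(coords, np.asarray(y), k)
    space.validate()
    return space


def dispersion_distances(space: SignalSpace) -> tuple[np.ndarray, pd.Series]:
    """Euclidean distance of every call to its own group centroid.

    Centroids are the mean coordinates of each group in the projected
    space.  Returns (per-call distances, per-group mean distance).
    """
    space.validate()
    labels = np.asarray(space.group_labels)
    uniq, idx = np.unique(labels, return_inverse=True)
    counts = np.bincount(idx)
    if np.any(counts < 2):
        bad = uniq[counts < 2].tolist()
        raise ValueError(f"singleton group(s) have undefined dispersion: {bad}")
    dists = np.empty(labels.size)
    for k, gname in enumerate(uniq):
        sel = idx == k
        centroid = space.coordinates[sel].mean(axis=0)
        dists[sel] = np.linalg.norm(space.coordinates[sel] - centroid, axis=1)
    means = pd.Series(
        [dists[idx == k].mean() for k in range(uniq.size)], index=uniq, name="mean_distance"
    )
    return dists, means


def dispersion_anova(
    distances: np.ndarray,
    group_labels: np.ndarray,
    posthoc: str = "tukey",
) -> DispersionResult:
    """One-way ANOVA on per-call centroid distances, with effect size.

    Reports F with (g-1, N-g) df, the p-value, partial eta squared
    SS_between/(SS_between+SS_within), and adjusted pairwise post-hoc
    p-values (``tukey`` or ``bonferroni``).
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(group_labels)
    uniq, idx = np.unique(labels, return_inverse=True)
    g = uniq.size
    N = distances.size
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(idx)
    if np.any(counts < 2):
        raise ValueError("every group needs >= 2 calls")

    grand = distances.mean()
    groups = [distances[idx == k] for k in range(g)]
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
    ss_within = sum(np.sum((x - x.mean()) ** 2) for x in groups)
    ss_total = ss_between + ss_within
    if ss_total <= 0:
        raise ValueError("zero total variance in distances; ANOVA undefined")
    df_b, df_w = g - 1, N - g
    if ss_within > 0:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    else:  # perfect separation of identical-within groups
        F, p = float("inf"), 0.0
    eta2 = float(ss_between / ss_total)

    pairs = list(combinations(range(g), 2))
    if posthoc == "tukey":
        if ss_within > 0:
            res = stats.tukey_hsd(*groups)
            rows = [
                {"group_a": uniq[a], "group_b": uniq[b], "p_adjusted": float(res.pvalue[a, b])}
                for a, b in pairs
            ]
        else:
            rows = [
                {
                    "group_a": uniq[a],
                    "group_b": uniq[b],
                    "p_adjusted": 0.0 if groups[a][0] != groups[b][0] else 1.0,
                }
                for a, b in pairs
            ]
    elif posthoc == "bonferroni":
        m = len(pairs)
        rows = []
        for a, b in pairs:
            t = stats.ttest_ind(groups[a], groups[b])
            rows.append(
                {
                    "group_a": uniq[a],
                    "group_b": uniq[b],
                    "p_adjusted": float(min(1.0, t.pvalue * m)),
                }
            )
    else:
        raise ValueError("posthoc must be 'tukey' or 'bonferroni'")

    means = pd.Series(
        [x.mean() for x in groups], index=uniq, name="mean_distance"
    )
    return DispersionResult(
        per_call_distance=distances,
        group_labels=labels,
        group_mean_distance=means,
        anova_F=float(F),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        partial_eta_squared=eta2,
        posthoc=pd.DataFrame(rows),
    )
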