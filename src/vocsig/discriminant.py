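"""Stepwise discriminant function analysis with leave-one-out cross-validation.

The engine behind the individual- and species-discrimination analyses:

1. multicollinearity screening (tolerance = 1 - R^2 of each feature
   regressed on the others);
2. classical Wilks'-lambda stepwise variable selection with F-to-enter /
   F-to-remove thresholds (defaults 3.84 / 2.71, the conventional ones);
3. a canonical discriminant solution — eigendecomposition of
   W^-1 B (within- vs between-group SSCP) — reporting eigenvalues,
   explained variation, Wilks' lambda and chi-squared per function, raw
   coefficients scaled to unit within-group score variance, and group
   centroids;
4. linear Gaussian classification with a shared pooled covariance and
   group priors (proportional to group sizes by default), cross-validated
   by leaving each call out in turn;
5. the chance level 100/g % and an exact one-sided binomial test of the
   classification success against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats

from .features import FEATURE_COLUMNS

__all__ = [
    "FeatureTable",
    "StepwiseCriteria",
    "DiscriminantModel",
    "ClassificationResult",
    "screen_multicollinearity",
    "stepwise_select",
    "fit_lda",
    "classify_loocv",
    "chance_level",
    "binomial_exceeds_chance",
    "explained_variation",
]


@dataclass
class FeatureTable:
    """A per-call feature table plus the grouping used for discrimination."""

    df: pd.DataFrame
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    group_field: str = "individual_id"

    def __post_init__(self) -> None:
        self.feature_columns = list(self.feature_columns)

    def validate(self) -> None:
        if self.group_field not in self.df.columns:
            raise ValueError(f"group field {self.group_field!r} not in table")
        missing = [c for c in self.feature_columns if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature columns missing from table: {missing}")
        X = self.df[self.feature_columns].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("feature table contains missing/non-finite values")
        counts = self.df[self.group_field].value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 groups")
        if counts.min() < 2:
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"every group needs >= 2 rows; too small: {small}")

    @property
    def groups(self) -> np.ndarray:
        return np.unique(self.df[self.group_field].to_numpy())

    def matrices(self, features: Sequence[str] | None = None):
        feats = list(features) if features is not None else self.feature_columns
        X = self.df[feats].to_numpy(dtype=float)
        y = self.df[self.group_field].to_numpy()
        return X, y


@dataclass(frozen=True)
class StepwiseCriteria:
    """Entry/removal thresholds for Wilks'-lambda stepwise selection."""

    f_to_enter: float = 3.84
    f_to_remove: float = 2.71
    tolerance_min: float = 0.001
    max_steps: int = 100

    def validate(self) -> None:
        if not (self.f_to_enter > self.f_to_remove > 0):
            raise ValueError("require f_to_enter > f_to_remove > 0")
        if not (0 < self.tolerance_min < 1):
            raise ValueError("tolerance_min must be in (0, 1)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class DiscriminantModel:
    """Fitted canonical discriminant space."""

    selected_features: list[str]
    eigenvalues: np.ndarray  # one per function, descending
    explained_variation: np.ndarray  # percent per function
    wilks_lambda: np.ndarray  # Lambda_k for functions k..r
    chi_squared: np.ndarray
    chi_squared_df: np.ndarray
    chi_squared_p: np.ndarray
    coefficients: np.ndarray  # (n_features, n_functions), unit within-variance
    grand_mean: np.ndarray
    group_labels: np.ndarray
    group_centroids: np.ndarray  # (n_groups, n_functions)
    priors: np.ndarray
    group_means: np.ndarray  # (n_groups, n_features) in feature space
    pooled_cov: np.ndarray  # (n_features, n_features)

    @property
    def n_functions(self) -> int:
        return int(self.eigenvalues.size)

    def transform(self, X: np.ndarray, n_functions: int | None = None) -> np.ndarray:
        """Discriminant scores of feature rows (first n_functions functions)."""
        k = self.n_functions if n_functions is None else int(n_functions)
        if not (1 <= k <= self.n_functions):
            raise ValueError(
                f"n_functions must be in [1, {self.n_functions}], got {k}"
            )
        return (np.asarray(X, dtype=float) - self.grand_mean) @ self.coefficients[:, :k]


@dataclass
class ClassificationResult:
    """Cross-validated classification summary."""

    group_labels: np.ndarray
    confusion: np.ndarray  # row percentages
    confusion_counts: np.ndarray
    per_group_n: np.ndarray
    overall_correct: float  # percent
    chance_level: float  # percent
    binomial_p: float
    n_total: int
    k_correct: int
    selected_features: list[str]

    def confusion_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.confusion, index=self.group_labels, columns=self.group_labels)
        df["n"] = self.per_group_n
        return df


# ------------------------------------------------------------- SSCP helpers

def _sscp(X: np.ndarray, y: np.ndarray):
    """Within- and total-group sums of squares and cross-products."""
    grand = X.mean(axis=0)
    Xc = X - grand
    total = Xc.T @ Xc
    within = np.zeros_like(total)
    for g in np.unique(y):
        Xg = X[y == g]
        d = Xg - Xg.mean(axis=0)
        within += d.T @ d
    return within, total


def _wilks(X: np.ndarray, y: np.ndarray) -> float:
    """Overall Wilks' lambda det(W)/det(T) for the given feature set."""
    if X.shape[1] == 0:
        return 1.0
    W, T = _sscp(X, y)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


# ------------------------------------------------------------- operations

def screen_multicollinearity(
    table: FeatureTable, tolerance_min: float = 0.001
) -> list[str]:
    """Drop features whose tolerance (1 - R^2 vs the other features) is tiny.

    Iteratively removes the feature with the smallest tolerance until all
    remaining features satisfy ``tolerance >= tolerance_min``; ties drop
    the later column, keeping the screen order-stable.
    """
    table.validate()
    feats = list(table.feature_columns)
    X = table.df[feats].to_numpy(dtype=float)

    def tolerances(cols: list[int]) -> np.ndarray:
        tol = np.empty(len(cols))
        for j, c in enumerate(cols):
            yv = X[:, c]
            others = [o for o in cols if o != c]
            sst = float(np.sum((yv - yv.mean()) ** 2))
            if sst == 0:
                tol[j] = 0.0
                continue
            A = np.column_stack([X[:, others], np.ones(len(yv))])
            resid = yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]
            tol[j] = max(0.0, float(np.sum(resid**2)) / sst)
        return tol

    cols = list(range(len(feats)))
    while len(cols) > 1:
        tol = tolerances(cols)
        worst = int(np.lexsort((-np.arange(len(cols)), tol))[0])
        if tol[worst] >= tolerance_min:
            break
        cols.pop(worst)
    if not cols or (len(cols) == 1 and np.std(X[:, cols[0]]) == 0):
        raise ValueError("multicollinearity screen dropped all features")
    return [feats[c] for c in cols]


def stepwise_select(
    table: FeatureTable, criteria: StepwiseCriteria = StepwiseCriteria()
) -> list[str]:
    """Wilks'-lambda stepwise feature selection.

    At each step the candidate minimizing the overall Wilks' lambda enters
    if its partial F-to-enter ``((N-g-p)/(g-1)) * (Lambda_p/Lambda_{p+1} - 1)``
    meets ``f_to_enter``; entered features whose F-to-remove falls below
    ``f_to_remove`` are then removed.  Terminates on no change or
    ``max_steps``.  May select nothing when no feature separates the
    groups at the entry threshold.
    """
    criteria.validate()
    retained = screen_multicollinearity(table, criteria.tolerance_min)
    X, y = table.matrices(retained)
    N = X.shape[0]
    g = len(np.unique(y))
    entered: list[int] = []
    removed_once: set[tuple[int, ...]] = set()

    def lam(cols: list[int]) -> float:
        return _wilks(X[:, cols], y)

    for _ in range(criteria.max_steps):
        changed = False
        p = len(entered)
        lam_p = lam(entered)
        # entry
        candidates = [c for c in range(len(retained)) if c not in entered]
        if candidates and N - g - p > 0:
            lams = np.array([lam(entered + [c]) for c in candidates])
            best = int(np.argmin(lams))
            lam_new = lams[best]
            if lam_new > 0:
                f_enter = ((N - g - p) / (g - 1)) * (lam_p / lam_new - 1.0)
            else:
                f_enter = np.inf
            if f_enter >= criteria.f_to_enter:
                key = tuple(sorted(entered + [candidates[best]]))
                if key not in removed_once:  # avoid enter/remove cycling
                    entered.append(candidates[best])
                    changed = True
        # removal
        p = len(entered)
        if p > 1:
            lam_p = lam(entered)
            worst_idx, worst_f = -1, np.inf
            for j, c in enumerate(entered):
                rest = [e for e in entered if e != c]
                lam_rest = lam(rest)
                if lam_p > 0:
                    f_rem = ((N - g - p + 1) / (g - 1)) * (lam_rest / lam_p - 1.0)
                else:
                    f_rem = np.inf
                if f_rem < worst_f:
                    worst_idx, worst_f = j, f_rem
            if worst_f < criteria.f_to_remove:
                removed_once.add(tuple(sorted(entered)))
                entered.pop(worst_idx)
                changed = True
        if not changed:
            break
    return [retained[c] for c in entered]


def explained_variation(eigenvalues: Sequence[float]) -> np.ndarray:
    """Percent of discriminating variance per function: 100 * l_i / sum(l)."""
    ev = np.asarray(eigenvalues, dtype=float)
    total = ev.sum()
    if total <= 0:
        return np.zeros_like(ev)
    return 100.0 * ev / total


def fit_lda(
    table: FeatureTable,
    features: Sequence[str] | None = None,
    priors: np.ndarray | str = "proportional",
) -> DiscriminantModel:
    """Canonical discriminant solution on the selected features.

    Solves the generalized eigenproblem ``B v = l W v`` (between vs within
    SSCP); coefficients are scaled so discriminant scores have unit pooled
    within-group variance.  Reports, per function k: the eigenvalue,
    explained variation 100*l_k/sum(l), residual Wilks'
    ``Lambda_k = prod_{i>=k} 1/(1+l_i)`` and the chi-squared
    approximation ``-(N - 1 - (p+g)/2) ln Lambda_k`` on
    ``(p-k+1)(g-k+1)`` df.
    """
    table.validate()
    feats = list(features) if features is not None else list(table.feature_columns)
    if not feats:
        raise ValueError("fit_lda needs at least one feature")
    X, y = table.matrices(feats)
    labels, y_idx = np.unique(y, return_inverse=True)
    N, p = X.shape
    g = labels.size
    counts = np.bincount(y_idx, minlength=g)
    if isinstance(priors, str):
        if priors == "proportional":
            pri = counts / N
        elif priors == "uniform":
            pri = np.full(g, 1.0 / g)
        else:
            raise ValueError("priors must be 'proportional', 'uniform', or an array")
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.size != g or not np.isclose(pri.sum(), 1.0):
            raise ValueError("priors must have one probability per group, summing to 1")

    W, T = _sscp(X, y)
    B = T - W
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise ValueError(
            f"singular within-group covariance on features {feats}: {exc}"
        ) from exc
    order = np.argsort(evals)[::-1]
    r = min(p, g - 1)
    evals = np.clip(evals[order][:r], 0.0, None)
    vecs = evecs[:, order][:, :r]
    # eigh normalizes v' W v = 1; rescale to unit pooled within-group
    # variance of the scores: v' (W/(N-g)) v = 1.
    vecs = vecs * np.sqrt(N - g)

    lam_k = np.array([np.prod(1.0 / (1.0 + evals[k:])) for k in range(r)])
    chi = -(N - 1 - (p + g) / 2.0) * np.log(np.clip(lam_k, 1e-300, None))
    dfs = np.array([(p - k) * (g - k - 1) for k in range(r)])
    chi_p = stats.chi2.sf(chi, np.maximum(dfs, 1))

    grand = X.mean(axis=0)
    gmeans = np.vstack([X[y_idx == i].mean(axis=0) for i in range(g)])
    centroids = (gmeans - grand) @ vecs
    pooled = W / (N - g)

    return DiscriminantModel(
        selected_features=feats,
        eigenvalues=evals,
        explained_variation=explained_variation(evals),
        wilks_lambda=lam_k,
        chi_squared=chi,
        chi_squared_df=dfs,
        chi_squared_p=chi_p,
        coefficients=vecs,
        grand_mean=grand,
        group_labels=labels,
        group_centroids=centroids,
        priors=pri,
        group_means=gmeans,
        pooled_cov=pooled,
    )


def _linear_scores(
    X: np.ndarray, means: np.ndarray, pooled: np.ndarray, priors: np.ndarray
) -> np.ndarray:
    """Linear discriminant scores x' S^-1 m_g - m_g' S^-1 m_g / 2 + ln pi_g."""
    solve = np.linalg.solve(pooled, means.T)  # (p, g)
    const = -0.5 * np.einsum("gp,pg->g", means, solve) + np.log(priors)
    return X @ solve + const


def _predict(
    X: np.ndarray, means: np.ndarray, pooled: np.ndarray, priors: np.ndarray
) -> np.ndarray:
    scores = _linear_scores(X, means, pooled, priors)
    # deterministic tie-break: larger prior, then group label order
    rank = np.lexsort((np.arange(priors.size), -priors))
    pos = np.empty_like(rank)
    pos[rank] = np.arange(priors.size)
    out = np.empty(scores.shape[0], dtype=int)
    for i, row in enumerate(scores):
        tied = np.flatnonzero(row == row.max())
        out[i] = tied[np.argmin(pos[tied])]
    return out


def classify_loocv(
    table: FeatureTable,
    criteria: StepwiseCriteria = StepwiseCriteria(),
    priors_mode: str = "proportional",
    nested_selection: bool = False,
    features: Sequence[str] | None = None,
) -> ClassificationResult:
    """Leave-one-out classification with stepwise-selected features.

    By default feature selection is performed once on the full data and
    held fixed while each call is left out and the group means and pooled
    covariance are refitted on the remaining N-1 calls (the conventional
    "leave-one-out classification" of discriminant-analysis software); a
    strict nested mode re-runs selection inside every fold.  If selection
    returns no features, calls are assigned by priors alone.
    """
    table.validate()
    X_all, y = table.matrices()
    labels, y_idx = np.unique(y, return_inverse=True)
    N = X_all.shape[0]
    g = labels.size
    counts = np.bincount(y_idx, minlength=g)
    if np.any(counts < 2):
        raise ValueError("every group needs >= 2 members for leave-one-out")

    if features is not None:
        selected_full = list(features)
    else:
        selected_full = stepwise_select(table, criteria)

    # priors follow the full-sample group sizes (or are uniform), matching
    # how unequal group sizes are adjusted for in the reported analyses
    if priors_mode == "proportional":
        pri = counts / N
    elif priors_mode == "uniform":
        pri = np.full(g, 1.0 / g)
    else:
        raise ValueError("priors_mode must be 'proportional' or 'uniform'")

    pred = np.empty(N, dtype=int)
    for i in range(N):
        mask = np.ones(N, dtype=bool)
        mask[i] = False
        yi = y_idx[mask]
        cnt = np.bincount(yi, minlength=g)
        if np.any(cnt < 2):
            raise ValueError(
                f"group {labels[np.argmin(cnt)]!r} has fewer than 2 members "
                "after holding one call out"
            )
        if nested_selection and features is None:
            sub = FeatureTable(
                table.df.iloc[mask].reset_index(drop=True),
                table.feature_columns,
                table.group_field,
            )
            sel = stepwise_select(sub, criteria)
        else:
            sel = selected_full
        if not sel:
            pred[i] = _predict(np.zeros((1, 1)), np.zeros((g, 1)), np.eye(1), pri)[0]
            continue
        cols = [table.feature_columns.index(s) for s in sel]
        Xf = X_all[:, cols]
        means = np.vstack([Xf[mask][yi == k].mean(axis=0) for k in range(g)])
        W = np.zeros((len(cols), len(cols)))
        for k in range(g):
            d = Xf[mask][yi == k] - means[k]
            W += d.T @ d
        pooled = W / (N - 1 - g)
        pred[i] = _predict(Xf[i : i + 1], means, pooled, pri)[0]

    conf_counts = np.zeros((g, g), dtype=int)
    np.add.at(conf_counts, (y_idx, pred), 1)
    with np.errstate(invalid="ignore"):
        conf_pct = 100.0 * conf_counts / counts[:, None]
    k_correct = int(np.trace(conf_counts))
    overall = 100.0 * k_correct / N
    chance = chance_level(g)
    p = binomial_exceeds_chance(k_correct, N, chance / 100.0)
    return ClassificationResult(
        group_labels=labels,
        confusion=conf_pct,
        confusion_counts=conf_counts,
        per_group_n=counts,
        overall_correct=overall,
        chance_level=chance,
        binomial_p=p,
        n_total=N,
        k_correct=k_correct,
        selected_features=selected_full,
    )


def chance_level(n_groups: int) -> float:
    """Expected success of random assignment, percent: 100 / n_groups."""
    if n_groups < 2:
        raise ValueError("chance level needs at least 2 groups")
    return 100.0 / n_groups


def binomial_exceeds_chance(k_correct: int, n_total: int, chance: float) -> float:
    """Exact one-sided binomial p-value P(X >= k | n, chance)."""
    if not (0 <= k_correct <= n_total) or n_total < 1:
        raise ValueError("require 0 <= k_correct <= n_total with n_total >= 1")
    if not (0.0 < chance < 1.0):
        raise ValueError("chance must be a probability in (0, 1)")
    return float(stats.binomtest(k_correct, n_total, chance, alternative="greater").pvalue)
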