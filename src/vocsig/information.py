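"""Beecher's information capacity of individual vocal signatures.

For each acoustic parameter the one-way ANOVA F statistic (individual
identity as the factor) measures how stereotyped the parameter is within
individuals relative to its spread between individuals.  Beecher's
stereotypy index converts each F into bits of identity information,

    H_s = log2 sqrt((F + n - 1) / n),

where ``n`` is the mean number of calls measured per individual.  Summing
the per-parameter contributions gives the total signature information
H_S of the call type, and 2**H_S is the number of individuals the call
type could in principle encode (e.g. 2**4.47 = 22.23 individuals).

Contributions are summed over the raw parameters without decorrelating
them first; an optional PCA-decorrelated variant (rotating the features to
principal components before computing F) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discriminant import FeatureTable

__all__ = [
    "StereotypyResult",
    "per_parameter_F",
    "stereotypy_index",
    "total_information",
    "capacity",
    "mean_calls_per_individual",
    "compute_stereotypy",
]


@dataclass
class StereotypyResult:
    """Per-parameter F statistics and information contributions."""

    per_parameter_F: dict[str, float]
    df_between: int
    df_within: int
    n_bar: float
    per_parameter_Hs: dict[str, float]
    total_Hs: float
    capacity: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": f,
                "F": self.per_parameter_F[f],
                "df_between": self.df_between,
                "df_within": self.df_within,
                "Hs_bits": self.per_parameter_Hs[f],
            }
            for f in self.per_parameter_F
        ]
        return pd.DataFrame(rows)


def per_parameter_F(table: FeatureTable) -> dict[str, float]:
    """One-way ANOVA F per feature with the group field as the factor.

    F = MS_between / MS_within with df_between = g-1, df_within = N-g.
    (With a single factor, type II sums of squares coincide with type I,
    so this is also the per-response F of a one-factor MANOVA.)
    """
    table.validate()
    X, y = table.matrices()
    labels, y_idx = np.unique(y, return_inverse=True)
    N, _ = X.shape
    g = labels.size
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for k in range(g):
        Xg = X[y_idx == k]
        m = Xg.mean(axis=0)
        ss_between += Xg.shape[0] * (m - grand) ** 2
        ss_within += np.sum((Xg - m) ** 2, axis=0)
    degenerate = ss_within <= 0
    if np.any(degenerate):
        bad = [table.feature_columns[i] for i in np.flatnonzero(degenerate)]
        raise ValueError(f"zero within-group variance for feature(s): {bad}")
    F = (ss_between / (g - 1)) / (ss_within / (N - g))
    return {f: float(v) for f, v in zip(table.feature_columns, F)}


def stereotypy_index(F: float, n_bar: float) -> float:
    """Bits of identity information in one parameter.

    ``log2 sqrt((F + n_bar - 1)/n_bar)``; F = 1 gives exactly 0 bits.
    Sub-null F (< 1) would give negative bits and is clipped to 0 —
    information content cannot be negative.
    """
    if n_bar < 1:
        raise ValueError("n_bar must be >= 1 (mean calls per individual)")
    if F < 0:
        raise ValueError("F must be >= 0")
    ratio = (F + n_bar - 1.0) / n_bar
    if ratio <= 1.0:
        return 0.0
    return float(np.log2(np.sqrt(ratio)))


def total_information(per_parameter_Hs: dict[str, float]) -> float:
    """Total signature information: sum of per-parameter contributions."""
    if not per_parameter_Hs:
        raise ValueError("no per-parameter contributions given")
    return float(sum(0.0 if v is None else v for v in per_parameter_Hs.values()))


def capacity(total_Hs: float) -> float:
    """Number of encodable individuals: 2**H_S."""
    if total_Hs < 0:
        raise ValueError("total_Hs must be >= 0")
    return float(2.0**total_Hs)


def mean_calls_per_individual(table: FeatureTable) -> float:
    """Pooled mean number of calls per individual: N_rows / N_groups."""
    if len(table.df) == 0:
        raise ValueError("empty table")
    groups = table.df[table.group_field].to_numpy()
    return len(table.df) / len(np.unique(groups))


def compute_stereotypy(
    table: FeatureTable,
    n_bar: float | None = None,
    decorrelate: bool = False,
) -> StereotypyResult:
    """Full stereotypy computation for one call type.

    ``n_bar`` defaults to the table's pooled mean calls per individual.
    With ``decorrelate=True`` features are rotated to principal components
    (of the pooled data) before the per-parameter F is computed — the
    variant that removes double-counting of correlated parameters; it is
    off by default, matching summation over the raw coefficients.
    """
    table.validate()
    if n_bar is None:
        n_bar = mean_calls_per_individual(table)
    work = table
    if decorrelate:
        X, _ = table.matrices()
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        pcs = Xc @ Vt.T
        cols = [f"pc{i + 1}" for i in range(pcs.shape[1])]
        df = table.df.copy()
        df[cols] = pcs
        work = FeatureTable(df, cols, table.group_field)
    Fs = per_parameter_F(work)
    g = len(np.unique(table.df[table.group_field].to_numpy()))
    N = len(table.df)
    hs = {f: stereotypy_index(v, n_bar) for f, v in Fs.items()}
    tot = total_information(hs)
    return StereotypyResult(
        per_parameter_F=Fs,
        df_between=g - 1,
        df_within=N - g,
        n_bar=float(n_bar),
        per_parameter_Hs=hs,
        total_Hs=tot,
        capacity=capacity(tot),
    )
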