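"""Agreement and inference statistics for the slice pipeline.

Bland-Altman limits of agreement validate the automated foci counter against
manual observers; a Pearson matrix summarises how morphology co-varies with
tissue depth; and a slice-clustered permutation test compares treatment
groups on per-nucleus readouts while respecting that nuclei are nested in
slices (slices, not nuclei, are the exchangeable units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AgreementResult",
    "CorrelationMatrix",
    "PermutationResult",
    "bland_altman",
    "pearson_matrix",
    "clustered_permutation_test",
]


@dataclass
class AgreementResult:
    """Bland-Altman agreement between two paired counters."""

    bias: float  # mean(a - b)
    sd_diff: float  # sample SD (n-1) of differences
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    n: int

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


def bland_altman(counts_a, counts_b) -> AgreementResult:
    """Bland-Altman statistics on paired counts.

    Differences d = a - b; bias = mean(d); sd_diff = sample SD with n-1
    denominator; 95% limits of agreement = bias -/+ 1.96 sd_diff.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts_a and counts_b must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n=int(a.size),
    )


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided t-test p-values."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    degenerate: list[str]  # zero-variance columns (R undefined for their pairs)


def pearson_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson R and p over numeric columns.

    Incomplete rows are dropped listwise; p-values come from the exact
    t-distribution with n-2 degrees of freedom.  Zero-variance columns are
    flagged and their pairwise entries left NaN.
    """
    if columns is None:
        columns = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    df = table[columns].dropna()
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    degenerate = [c for c in columns if df[c].std(ddof=0) == 0]
    if degenerate:
        warnings.warn(f"zero-variance columns, correlations undefined: {degenerate}")
    k = len(columns)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            if columns[i] in degenerate or columns[j] in degenerate:
                continue
            res = sps.pearsonr(df[columns[i]], df[columns[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(
        variables=list(columns),
        r=pd.DataFrame(r, index=columns, columns=columns),
        p=pd.DataFrame(p, index=columns, columns=columns),
        n=n,
        degenerate=degenerate,
    )


@dataclass
class PermutationResult:
    """Slice-clustered permutation test outcome."""

    observed: float  # difference of group means of slice means
    p_value: float
    n_perm: int
    groups: tuple[str, str]


def clustered_permutation_test(
    table: pd.DataFrame,
    value_col: str = "value",
    slice_col: str = "slice",
    group_col: str = "group",
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Two-group comparison of per-nucleus values nested in slices.

    The statistic is the difference of group means of slice means, so every
    slice contributes equally regardless of how many nuclei it holds.  Group
    labels are permuted across whole slices (respecting the group sizes),
    which preserves the within-slice correlation structure under the null.
    The two-sided p-value uses the add-one correction
    ``p = (1 + #{|T*| >= |T|}) / (n_perm + 1)`` so p is never zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    slice_means = table.groupby([group_col, slice_col], sort=True)[value_col].mean()
    sizes = slice_means.groupby(level=0).size()
    if (sizes < 2).any():
        raise ValueError(f"each group needs >= 2 slices, got {dict(sizes)}")
    g0 = slice_means.loc[groups[0]].to_numpy()
    g1 = slice_means.loc[groups[1]].to_numpy()
    values = np.concatenate([g0, g1])
    n0 = len(g0)
    observed = g0.mean() - g1.mean()

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        t = perm[:n0].mean() - perm[n0:].mean()
        if abs(t) >= abs(observed) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(
        observed=float(observed), p_value=float(p),
        n_perm=n_perm, groups=(str(groups[0]), str(groups[1])),
    )
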