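"""Differential expression across developmental ages.

The test is a one-way fixed-effects ANOVA with age as the factor, run on
log2(FPKM+1) values, followed by Benjamini-Hochberg adjustment over all genes
in the matrix.  A gene is called significant when it passes three gates:

1. mean FPKM over all samples  > ``mean_floor``   (abundance gate)
2. max/min age-mean fold change > ``fc``          (effect-size gate,
   computed with a pseudocount to tame zero means)
3. BH-adjusted ANOVA p          < ``alpha``       (statistical gate)
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

__all__ = [
    "log_fpkm",
    "anova_across_ages",
    "anova_table",
    "bh_adjust",
    "max_fold_change",
    "call_de",
]


def log_fpkm(values: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """The analysis transform: log2(FPKM + 1)."""
    return np.log2(values + 1.0)


def _age_column_groups(m: ExpressionMatrix) -> list[np.ndarray]:
    """Column index arrays grouping samples by age (ages ascending)."""
    cols = {s: i for i, s in enumerate(m.values.columns)}
    groups = []
    for age in m.ages:
        ids = m.samples.loc[m.samples["age_day"] == age, "sample_id"]
        groups.append(np.array([cols[s] for s in ids]))
    return groups


def _anova_matrix(x: np.ndarray, groups: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-way ANOVA of ``x`` (rows = genes) over column ``groups``.

    Degenerate rows with all values identical get (f=0, p=1) by convention.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 ages")
    n_total = sum(len(g) for g in groups)
    if n_total - len(groups) < 1:
        raise ValueError("ANOVA requires residual degrees of freedom >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input rows handled below
        f, p = scipy.stats.f_oneway(*(x[:, g] for g in groups), axis=1)
    f = np.atleast_1d(np.asarray(f, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    constant = np.ptp(x, axis=1) == 0
    f[constant] = 0.0
    p[constant] = 1.0
    # rows with zero within-group variance but between-group differences
    inf = np.isinf(f)
    p[inf] = 0.0
    bad = np.isnan(f) | np.isnan(p)
    f[bad] = 0.0
    p[bad] = 1.0
    return f, p


def anova_across_ages(m: ExpressionMatrix, gene_id: str) -> tuple[float, float]:
    """One-way ANOVA (age factor) for one gene on log2(FPKM+1) values.

    Returns (F statistic, upper-tail p) with (a-1, N-a) degrees of freedom.
    """
    x = log_fpkm(m.values.loc[[gene_id]].to_numpy(dtype=float))
    f, p = _anova_matrix(x, _age_column_groups(m))
    return float(f[0]), float(p[0])


def anova_table(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene ANOVA over ages; columns f_stat, p_raw, indexed by gene_id."""
    x = log_fpkm(m.values.to_numpy(dtype=float))
    f, p = _anova_matrix(x, _age_column_groups(m))
    return pd.DataFrame({"f_stat": f, "p_raw": p}, index=m.gene_ids)


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def max_fold_change(means: Sequence[float] | np.ndarray, pseudocount: float = 1.0) -> float:
    """(max age mean + pseudocount) / (min age mean + pseudocount); >= 1."""
    means = np.asarray(means, dtype=float)
    return float((means.max() + pseudocount) / (means.min() + pseudocount))


def call_de(
    m: ExpressionMatrix,
    alpha: float = 0.05,
    fc: float = 1.5,
    mean_floor: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full differential-expression table with the three-gate significance call.

    BH adjustment is applied over every gene in the matrix.  Returns a
    DataFrame indexed by gene_id with columns f_stat, p_raw, p_adj,
    mean_fpkm_overall, max_fold_change, significant.
    """
    tab = anova_table(m)
    tab["p_adj"] = bh_adjust(tab["p_raw"].to_numpy())
    tab["mean_fpkm_overall"] = m.values.mean(axis=1)
    prof = m.age_means()
    arr = prof.to_numpy(dtype=float)
    tab["max_fold_change"] = (arr.max(axis=1) + pseudocount) / (arr.min(axis=1) + pseudocount)
    tab["significant"] = (
        (tab["mean_fpkm_overall"] > mean_floor)
        & (tab["max_fold_change"] > fc)
        & (tab["p_adj"] < alpha)
    )
    return tab[["f_stat", "p_raw", "p_adj", "mean_fpkm_overall", "max_fold_change", "significant"]]
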