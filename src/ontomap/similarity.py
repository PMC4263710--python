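"""Inter-age similarity of expression profiles.

Pearson correlation between the age-mean expression vectors of two ages,
computed over a chosen gene subset on log2(FPKM+1) values (the log transform
keeps a handful of very abundant genes from dominating r).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .de import log_fpkm
from .expression import ExpressionMatrix

__all__ = ["age_similarity", "mean_offdiagonal"]


def age_similarity(
    m: ExpressionMatrix,
    subset: Optional[Sequence[str]] = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Ages x ages Pearson-r matrix over a gene subset.

    Symmetric with unit diagonal.  Raises on an age whose mean-expression
    vector has zero variance across the subset (correlation undefined).
    """
    prof = m.age_means()
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("gene subset must be non-empty")
        prof = prof.loc[subset]
    x = prof.to_numpy(dtype=float)
    if log_transform:
        x = log_fpkm(x)
    sd = x.std(axis=0)
    for age, s in zip(prof.columns, sd):
        if s == 0:
            raise ValueError(f"age {age}: zero-variance expression vector, correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=prof.columns, columns=prof.columns)


def mean_offdiagonal(sim: pd.DataFrame) -> float:
    """Mean of the off-diagonal entries of a similarity matrix."""
    a = sim.to_numpy(dtype=float)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two ages")
    return float((a.sum() - np.trace(a)) / (n * (n - 1)))
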