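"""FPKM expression matrices with age/replicate structure.

The canonical container is a pandas DataFrame (genes x samples) plus a sample
sheet (sample_id, age_day, replicate).  Ages are integer postnatal days and
may be negative (prenatal).  All downstream per-age quantities are arithmetic
means of FPKM over the replicates at that age.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleInfo",
    "ExpressionMatrix",
    "age_means",
    "expressed_genes",
    "expressed_per_age",
    "read_expression",
    "read_samples",
]


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    age_day: int
    replicate: int


class ExpressionMatrix:
    """Genes x samples FPKM values with ordered sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene_id with one column per sample_id, in the
        same order as the sample sheet.  Values must be finite and >= 0.
    samples
        DataFrame with columns ``sample_id``, ``age_day``, ``replicate``.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        samples = samples.reset_index(drop=True)
        required = {"sample_id", "age_day", "replicate"}
        if not required.issubset(samples.columns):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        if samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        key = samples[["age_day", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("(age_day, replicate) must be unique across samples")
        if list(values.columns) != list(samples["sample_id"]):
            raise ValueError("expression columns must match sample sheet sample_ids in order")
        if values.index.duplicated().any():
            raise ValueError("duplicate gene_id in expression matrix")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite (missing values unsupported)")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = values.astype(float)
        self.samples = samples.copy()
        self.samples["age_day"] = self.samples["age_day"].astype(int)
        self.samples["replicate"] = self.samples["replicate"].astype(int)

    # -- basic structure ----------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def ages(self) -> list[int]:
        return sorted(self.samples["age_day"].unique())

    @property
    def sample_infos(self) -> list[SampleInfo]:
        return [
            SampleInfo(r.sample_id, int(r.age_day), int(r.replicate))
            for r in self.samples.itertuples()
        ]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples)

    # -- derived quantities -------------------------------------------------

    def age_means(self) -> pd.DataFrame:
        """Per-gene arithmetic mean FPKM over replicates within each age.

        Columns are the distinct ages sorted ascending.
        """
        groups = self.samples.groupby("age_day")["sample_id"]
        out = {age: self.values[list(ids)].mean(axis=1) for age, ids in groups}
        return pd.DataFrame(out).reindex(columns=self.ages)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, expr_path: str | Path, samples_path: str | Path,
               float_format: str = "%.6g") -> None:
        self.values.rename_axis("gene_id").to_csv(
            expr_path, sep="\t", float_format=float_format
        )
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expr_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        values = read_expression(expr_path)
        samples = read_samples(samples_path)
        return cls(values, samples)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "gene_id"
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def age_means(m: ExpressionMatrix) -> pd.DataFrame:
    """Functional alias for :meth:`ExpressionMatrix.age_means`."""
    return m.age_means()


def expressed_genes(profiles: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Genes whose replicate-averaged FPKM exceeds ``threshold`` at any age.

    The comparison is strict (> threshold), so a gene peaking exactly at the
    threshold is not expressed.
    """
    return profiles.index[profiles.max(axis=1) > threshold]


def expressed_per_age(
    profiles: pd.DataFrame,
    klass: Mapping[str, str],
    threshold: float = 1.0,
    classes: Optional[Sequence[str]] = ("coding", "lncRNA"),
) -> pd.DataFrame:
    """Per-age expressed-gene counts, split by gene class.

    Parameters
    ----------
    profiles
        Age-mean FPKM (genes x ages), as from :func:`age_means`.
    klass
        gene_id -> class label lookup; genes absent from it are dropped.
    classes
        Which classes to report (columns of the result); None = all seen.

    Returns a DataFrame indexed by age with one count column per class.
    """
    kl = pd.Series({g: klass[g] for g in profiles.index if g in klass})
    if classes is None:
        classes = sorted(kl.unique())
    sub = profiles.loc[kl.index]
    counts = {}
    for c in classes:
        genes_c = kl.index[kl == c]
        counts[c] = (sub.loc[genes_c] > threshold).sum(axis=0)
    out = pd.DataFrame(counts)
    out.index.name = "age_day"
    return out
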