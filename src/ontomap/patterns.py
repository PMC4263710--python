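"""Ontogenic expression-pattern clustering.

Differentially expressed genes are represented by per-age z-scores of
log2(mean FPKM + 1), hierarchically clustered with Pearson-correlation
distance and average linkage, and each major cluster is labeled by the
developmental stage in which its centroid profile peaks (neonatal,
adolescent, or adult; a perinatal peak maps to the neonatal label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .annotation import GeneSet
from .de import log_fpkm

__all__ = [
    "StageWindows",
    "zscore_profiles",
    "cluster_patterns",
    "chromosome_density",
    "plot_chromosome_density",
]

MAJOR_LABELS = ("neonatal", "adolescent", "adult")


@dataclass(frozen=True)
class StageWindows:
    """Age-day groupings used to name clusters by their peak stage.

    Day 30 is grouped with adolescence by default (configurable: correlation
    structure places it with young adulthood in some analyses).
    """

    windows: Mapping[str, frozenset[int]] = field(
        default_factory=lambda: {
            "perinatal": frozenset({-2, 0}),
            "neonatal": frozenset({1, 3, 5, 10}),
            "adolescent": frozenset({15, 20, 25, 30}),
            "adult": frozenset({45, 60}),
        }
    )

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for days in self.windows.values():
            if seen & set(days):
                raise ValueError("stage windows must be disjoint")
            seen |= set(days)

    def label_for_age(self, day: int) -> str:
        for stage, days in self.windows.items():
            if day in days:
                # perinatal peaks are grouped with the neonatal pattern
                return "neonatal" if stage == "perinatal" else stage
        raise KeyError(f"age day {day} not covered by any stage window")


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores of log2(mean FPKM + 1) across ages.

    Population SD; rows constant across ages map to all-zero vectors.
    """
    x = log_fpkm(profiles.to_numpy(dtype=float))
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population SD
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def cluster_patterns(
    z: pd.DataFrame,
    k: int = 3,
    windows: Optional[StageWindows] = None,
    return_linkage: bool = False,
):
    """Average-linkage hierarchical clustering of z-profiles, cut into ``k`` clusters.

    Distance is 1 - Pearson r between profiles.  Genes whose z-profile has
    zero variance (constant raw profile) are excluded from the tree and
    labeled ``other`` with cluster index 0.  When ``k`` > 3, only the three
    largest clusters receive stage labels; the rest are ``other``.

    Gene order is canonicalized (sorted by gene_id) before clustering, so
    assignments do not depend on input order.

    Returns a DataFrame indexed by gene_id with columns ``cluster``,
    ``label``, ``peak_age`` (NaN for unclustered genes); with
    ``return_linkage=True`` also the linkage matrix and the clustered ids.
    """
    if windows is None:
        windows = StageWindows()
    z = z.sort_index()
    ages = [int(c) for c in z.columns]
    variable = z.index[z.std(axis=1) > 0]
    degenerate = z.index.difference(variable)
    if len(variable) < k:
        raise ValueError(f"need at least k={k} genes with non-constant profiles")

    zv = z.loc[variable].to_numpy(dtype=float)
    dist = pdist(zv, metric="correlation")
    linkage = sch.linkage(dist, method="average")
    cluster_ids = sch.fcluster(linkage, t=k, criterion="maxclust")

    sizes = pd.Series(cluster_ids).value_counts()
    majors = sorted(sizes.index, key=lambda c: (-sizes[c], c))[:3]

    labels = {}
    peak_ages = {}
    for c in sizes.index:
        centroid = zv[cluster_ids == c].mean(axis=0)
        peak = ages[int(np.argmax(centroid))]
        peak_ages[c] = peak
        labels[c] = windows.label_for_age(peak) if c in majors else "other"

    out = pd.DataFrame(index=z.index, columns=["cluster", "label", "peak_age"])
    out.loc[variable, "cluster"] = cluster_ids
    out.loc[variable, "label"] = [labels[c] for c in cluster_ids]
    out.loc[variable, "peak_age"] = [peak_ages[c] for c in cluster_ids]
    out.loc[degenerate, "cluster"] = 0
    out.loc[degenerate, "label"] = "other"
    out["cluster"] = out["cluster"].astype(int)
    if return_linkage:
        return out, linkage, list(variable)
    return out


def chromosome_density(assignments: pd.DataFrame, gs: GeneSet) -> pd.DataFrame:
    """Counts of labeled genes per (chromosome, strand, label).

    ``assignments`` must have a ``label`` column indexed by gene_id; every
    gene must exist in ``gs`` (missing ids raise KeyError listing them).
    """
    missing = [g for g in assignments.index if g not in gs]
    if missing:
        raise KeyError(f"gene ids absent from annotation: {missing}")
    rows = [
        {"chrom": gs[g].chrom, "strand": gs[g].strand, "label": assignments.loc[g, "label"]}
        for g in assignments.index
    ]
    if not rows:
        return pd.DataFrame(columns=["chrom", "strand", "label", "count"])
    df = pd.DataFrame(rows)
    out = (
        df.value_counts(["chrom", "strand", "label"])
        .rename("count")
        .reset_index()
        .sort_values(["chrom", "strand", "label"])
        .reset_index(drop=True)
    )
    return out


def plot_chromosome_density(density: pd.DataFrame, path: str) -> None:
    """Plain per-chromosome bar plot of pattern-labeled gene counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = density.pivot_table(
        index="chrom", columns="label", values="count", aggfunc="sum", fill_value=0
    )
    ax = pivot.plot.bar(figsize=(max(6, 0.5 * len(pivot)), 4))
    ax.set_ylabel("genes")
    ax.set_xlabel("chromosome")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)
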