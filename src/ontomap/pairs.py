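"""Neighbor gene-pair correlation analysis.

Each anchor gene (coding for PC-PC, lncRNA for PC-NC) is paired with its
nearest protein-coding neighbor on the same chromosome.  Two stringency
tiers are used: ``all`` (every anchor with a neighbor) and ``hi``
(pairs within a maximum gap where the lncRNA — or for PC-PC at least one
gene — is expressed).  Pair correlation r is the Pearson correlation of the
two genes' log2(mean FPKM + 1) profiles across the ordered ages; a random
sample of coding-gene pairs provides the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneSet, NeighborPair, nearest_coding_neighbor

__all__ = [
    "NeighborPair",
    "build_pairs",
    "filter_hi",
    "pair_correlations",
    "random_pair_null",
    "RHistogram",
    "r_distribution",
    "concordant_pairs",
    "pairs_to_frame",
]

_ANCHOR_CLASS = {"coding": "PC-PC", "lncRNA": "PC-NC"}


def build_pairs(gs: GeneSet, klass_anchor: str) -> list[NeighborPair]:
    """One tier-``all`` pair per anchor gene of the given class.

    Anchors on chromosomes with no (other) coding gene are dropped.
    """
    if klass_anchor not in _ANCHOR_CLASS:
        raise ValueError(f"klass_anchor must be 'coding' or 'lncRNA', got {klass_anchor!r}")
    pairs = []
    for g in gs.sorted_by_position():
        if g.klass != klass_anchor:
            continue
        p = nearest_coding_neighbor(g, gs)
        if p is not None:
            pairs.append(p)
    return pairs


def filter_hi(
    pairs: Iterable[NeighborPair],
    expressed: set[str] | frozenset[str],
    max_gap: int = 10_000,
) -> list[NeighborPair]:
    """High-stringency tier: gap < ``max_gap`` and the expression rule.

    PC-NC pairs require the lncRNA (anchor) to be expressed; PC-PC pairs
    require at least one of the two genes.
    """
    out = []
    for p in pairs:
        if p.gap_bp is None or p.gap_bp >= max_gap:
            continue
        if p.pair_class == "PC-NC":
            ok = p.id_a in expressed
        else:
            ok = p.id_a in expressed or p.id_b in expressed
        if ok:
            out.append(replace(p, tier="hi"))
    return out


def _normalized_rows(log_profiles: pd.DataFrame) -> tuple[np.ndarray, dict[str, int], np.ndarray]:
    """Rows centered and scaled to unit norm; zero-norm (constant) rows flagged."""
    x = log_profiles.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(x, axis=1)
    ok = norm > 0
    x[ok] = x[ok] / norm[ok, None]
    index = {g: i for i, g in enumerate(log_profiles.index)}
    return x, index, ok


def pair_correlations(
    pairs: Sequence[NeighborPair], log_profiles: pd.DataFrame
) -> list[NeighborPair]:
    """Attach Pearson r over the ordered ages to each pair.

    ``log_profiles`` is the genes x ages matrix of log2(mean FPKM + 1).
    Pairs where either profile is constant get r = None (correlation
    undefined); callers exclude them from distributions and report the count.
    """
    x, index, ok = _normalized_rows(log_profiles)
    out = []
    for p in pairs:
        ia, ib = index[p.id_a], index[p.id_b]
        if ok[ia] and ok[ib]:
            r = float(np.clip(np.dot(x[ia], x[ib]), -1.0, 1.0))
        else:
            r = None
        out.append(replace(p, r=r))
    return out


def random_pair_null(
    gs: GeneSet,
    log_profiles: pd.DataFrame,
    n_pairs: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[NeighborPair]:
    """Random unordered coding-gene pairs with correlations (the null).

    Pairs are drawn uniformly among all annotated coding genes present in
    ``log_profiles``; the two members of a pair are distinct, but the same
    pair may recur across draws.  A seeded RNG makes the draw reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    coding = sorted(
        g.gene_id for g in gs.of_class("coding") if g.gene_id in log_profiles.index
    )
    if len(coding) < 2:
        raise ValueError("need at least 2 coding genes for the random null")
    if n_pairs == 0:
        return []
    idx = rng.integers(0, len(coding), size=(n_pairs, 2))
    clash = idx[:, 0] == idx[:, 1]
    while clash.any():
        idx[clash, 1] = rng.integers(0, len(coding), size=int(clash.sum()))
        clash = idx[:, 0] == idx[:, 1]
    pairs = [
        NeighborPair(
            id_a=coding[a], id_b=coding[b], pair_class="random-PC",
            gap_bp=None, tier="all",
        )
        for a, b in idx
    ]
    return pair_correlations(pairs, log_profiles)


@dataclass(frozen=True)
class RHistogram:
    """Binned correlation distribution over [-1, 1] with its modal-bin peak."""

    counts: np.ndarray
    edges: np.ndarray
    peak: float
    n_defined: int
    n_undefined: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.edges[:-1],
                "bin_hi": self.edges[1:],
                "count": self.counts,
            }
        )


def r_distribution(
    pairs: Sequence[NeighborPair], bin_width: float = 0.1
) -> RHistogram:
    """Histogram of pair correlations over [-1, 1] and the modal-bin midpoint.

    Ties between modal bins resolve toward the bin whose midpoint is closer
    to 0.  Undefined-r pairs are excluded and counted.
    """
    rs = [p.r for p in pairs if p.r is not None]
    n_undef = len(pairs) - len(rs)
    if not rs:
        raise ValueError("no defined correlations to bin")
    n_bins = int(round(2.0 / bin_width))
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(rs, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2.0
    best = max(range(n_bins), key=lambda i: (counts[i], -abs(mids[i]), -mids[i]))
    return RHistogram(
        counts=counts, edges=edges, peak=float(mids[best]),
        n_defined=len(rs), n_undefined=n_undef,
    )


def concordant_pairs(
    pairs: Sequence[NeighborPair],
    de: pd.DataFrame,
    assignments: pd.DataFrame,
    alpha: float = 0.05,
    max_gap: int = 10_000,
) -> list[NeighborPair]:
    """Concordant cis-candidate PC-NC pairs.

    Keeps pairs where the lncRNA anchor changes significantly during
    development (BH-adjusted ANOVA p < ``alpha``), the genomic gap is below
    ``max_gap``, and both genes carry the same major ontogenic pattern label
    (neonatal/adolescent/adult).  Pairs whose partner has no pattern
    assignment (e.g. not differentially expressed) are dropped.
    """
    major = {"neonatal", "adolescent", "adult"}
    out = []
    for p in pairs:
        if p.gap_bp is None or p.gap_bp >= max_gap:
            continue
        if p.id_a not in de.index or de.loc[p.id_a, "p_adj"] >= alpha:
            continue
        if p.id_a not in assignments.index or p.id_b not in assignments.index:
            continue
        la = assignments.loc[p.id_a, "label"]
        lb = assignments.loc[p.id_b, "label"]
        if la in major and la == lb:
            out.append(p)
    return out


def pairs_to_frame(pairs: Sequence[NeighborPair]) -> pd.DataFrame:
    """Tabular view of a pair collection."""
    return pd.DataFrame(
        {
            "id_a": [p.id_a for p in pairs],
            "id_b": [p.id_b for p in pairs],
            "pair_class": [p.pair_class for p in pairs],
            "gap_bp": [p.gap_bp for p in pairs],
            "tier": [p.tier for p in pairs],
            "r": [p.r for p in pairs],
        }
    )
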