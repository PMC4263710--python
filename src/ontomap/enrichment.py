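"""Gene-set over-representation analysis.

A flat gene -> term map (no ontology DAG, no term propagation) is tested with
the one-sided hypergeometric test, and FDR is controlled by Benjamini-Hochberg
over the tested terms.  Terms with zero hits in the query set are not tested
by default (this changes the BH family size; configurable).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust

__all__ = ["read_term_map", "enrich"]


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (gene_id, term_id) TSV into a gene -> terms map."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene_id", "term_id"])
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term_id"]):
        out.setdefault(str(g), set()).add(str(t))
    return out


def enrich(
    gene_set: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Sequence[str] | set[str]],
    include_zero_hit_terms: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` terms vs ``universe``.

    For each term with annotation in the universe: k = hits in the set,
    n = set size, K = hits in the universe, N = universe size, and
    p_raw = P(X >= k) for X ~ Hypergeom(N, K, n).  Results are sorted by
    (fdr, term_id).

    Raises ValueError when the gene set is not contained in the universe.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    stray = sorted(gene_set - universe)
    if stray:
        raise ValueError(f"gene_set members absent from universe: {stray}")

    term_universe: dict[str, set[str]] = {}
    for g in universe:
        for t in term_map.get(g, ()):
            term_universe.setdefault(t, set()).add(g)

    N, n = len(universe), len(gene_set)
    rows = []
    for term in sorted(term_universe):
        hits = term_universe[term]
        k = len(hits & gene_set)
        if k == 0 and not include_zero_hit_terms:
            continue
        K = len(hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "n": n, "K": K, "N": N, "p_raw": p})
    if not rows:
        return pd.DataFrame(columns=["term_id", "k", "n", "K", "N", "p_raw", "fdr"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_raw"].to_numpy())
    return out.sort_values(["fdr", "term_id"]).reset_index(drop=True)
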