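"""Neighbor-pair construction, stringency filtering, correlations, the null."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_gene, random_geneset
from ontomap.annotation import GeneSet, NeighborPair, gene_gap
from ontomap.pairs import (
    build_pairs,
    concordant_pairs,
    filter_hi,
    pair_correlations,
    r_distribution,
    random_pair_null,
)


def _profiles(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T


class TestBuildPairs:
    def test_every_coding_anchor_paired(self):
        gs = GeneSet([
            make_gene("c1", start=0, end=100, klass="coding"),
            make_gene("c2", start=500, end=600, klass="coding"),
            make_gene("c3", start=2000, end=2100, klass="coding"),
        ])
        pairs = build_pairs(gs, "coding")
        assert len(pairs) == 3
        assert all(p.pair_class == "PC-PC" for p in pairs)

    def test_lonely_lncrna_dropped(self):
        gs = GeneSet([
            make_gene("n1", chrom="chrX", klass="lncRNA", biotype="lincRNA"),
            make_gene("c1", chrom="chr1", klass="coding"),
        ])
        assert build_pairs(gs, "lncRNA") == []

    def test_matches_brute_force(self, rng):
        gs = random_geneset(rng, 100)
        pairs = build_pairs(gs, "lncRNA")
        by_anchor = {p.id_a: p for p in pairs}
        for g in gs:
            if g.klass != "lncRNA":
                continue
            best = None
            for cand in gs:
                if cand.klass != "coding":
                    continue
                gap = gene_gap(g, cand)
                if gap is None:
                    continue
                key = (gap, cand.start, cand.gene_id)
                if best is None or key < best:
                    best = key
            if best is None:
                assert g.gene_id not in by_anchor
            else:
                p = by_anchor[g.gene_id]
                assert (p.gap_bp, p.id_b) == (best[0], best[2])


class TestFilterHi:
    def _pair(self, cls, gap, a="nc1", b="pc1"):
        return NeighborPair(id_a=a, id_b=b, pair_class=cls, gap_bp=gap)

    def test_pcnc_requires_expressed_lncrna(self):
        p = self._pair("PC-NC", 5000)
        assert filter_hi([p], expressed={"pc1"}) == []
        kept = filter_hi([p], expressed={"nc1"})
        assert len(kept) == 1 and kept[0].tier == "hi"

    def test_pcpc_requires_either_expressed(self):
        p = self._pair("PC-PC", 5000, a="pc0")
        assert len(filter_hi([p], expressed={"pc1"})) == 1
        assert len(filter_hi([p], expressed={"pc0"})) == 1
        assert filter_hi([p], expressed=set()) == []

    def test_distance_rule_strict(self):
        near = self._pair("PC-NC", 9999)
        at = self._pair("PC-NC", 10_000)
        far = self._pair("PC-NC", 12_000)
        kept = filter_hi([near, at, far], expressed={"nc1"})
        assert [p.gap_bp for p in kept] == [9999]

    def test_subset_of_all_tier(self, rng):
        gs = random_geneset(rng, 60)
        all_tier = build_pairs(gs, "lncRNA")
        expressed = {g.gene_id for g in gs if rng.random() < 0.5}
        hi = filter_hi(all_tier, expressed)
        all_keys = {(p.id_a, p.id_b) for p in all_tier}
        assert {(p.id_a, p.id_b) for p in hi} <= all_keys


class TestPairCorrelations:
    def test_identical_and_mirrored_profiles(self):
        prof = _profiles({
            "a": [1, 2, 3, 4], "b": [2, 4, 6, 8], "c": [4, 3, 2, 1],
        })
        pairs = [
            NeighborPair("a", "b", "PC-NC", 100),
            NeighborPair("a", "c", "PC-NC", 100),
        ]
        out = pair_correlations(pairs, prof)
        assert out[0].r == pytest.approx(1.0)
        assert out[1].r == pytest.approx(-1.0)

    def test_constant_profile_undefined(self):
        prof = _profiles({"a": [1, 2, 3], "b": [5, 5, 5]})
        out = pair_correlations([NeighborPair("a", "b", "PC-NC", 0)], prof)
        assert out[0].r is None

    def test_matches_direct_formula(self, rng):
        names = [f"g{i}" for i in range(20)]
        prof = pd.DataFrame(rng.random((20, 12)), index=names)
        pairs = [
            NeighborPair(names[i], names[i + 1], "PC-PC", 0)
            for i in range(0, 18, 2)
        ]
        out = pair_correlations(pairs, prof)
        for p in out:
            u = prof.loc[p.id_a].to_numpy()
            v = prof.loc[p.id_b].to_numpy()
            r = np.corrcoef(u, v)[0, 1]
            assert p.r == pytest.approx(r, abs=1e-12)


class TestRandomPairNull:
    def _setup(self, rng, n=50):
        gs = random_geneset(rng, n, coding_fraction=1.0)
        prof = pd.DataFrame(rng.random((n, 12)), index=[g.gene_id for g in gs])
        return gs, prof

    def test_zero_pairs(self, rng):
        gs, prof = self._setup(rng)
        assert random_pair_null(gs, prof, n_pairs=0, seed=1) == []

    def test_deterministic_under_seed(self, rng):
        gs, prof = self._setup(rng)
        a = random_pair_null(gs, prof, n_pairs=200, seed=42)
        b = random_pair_null(gs, prof, n_pairs=200, seed=42)
        assert a == b

    def test_members_distinct(self, rng):
        gs, prof = self._setup(rng, n=5)
        pairs = random_pair_null(gs, prof, n_pairs=500, seed=3)
        assert all(p.id_a != p.id_b for p in pairs)

    def test_independent_profiles_mean_near_zero(self, rng):
        gs, prof = self._setup(rng, n=300)
        pairs = random_pair_null(gs, prof, n_pairs=10_000, seed=9)
        rs = [p.r for p in pairs if p.r is not None]
        assert abs(np.mean(rs)) < 0.03


class TestRDistribution:
    def _pairs(self, rs):
        return [NeighborPair(f"a{i}", f"b{i}", "PC-PC", 0, r=r)
                for i, r in enumerate(rs)]

    def test_all_ones_peak(self):
        hist = r_distribution(self._pairs([1.0] * 10))
        assert hist.peak == pytest.approx(0.95)

    def test_tie_resolved_toward_zero(self):
        hist = r_distribution(self._pairs([0.55, 0.55, -0.45, -0.45]))
        assert hist.peak == pytest.approx(-0.45)

    def test_undefined_counted(self):
        hist = r_distribution(self._pairs([0.5, None, None]))
        assert hist.n_defined == 1 and hist.n_undefined == 2
        assert hist.counts.sum() == 1


class TestConcordantPairs:
    def _fixtures(self):
        de = pd.DataFrame({"p_adj": [0.01, 0.5]}, index=["nc1", "nc2"])
        assign = pd.DataFrame(
            {"label": ["neonatal", "neonatal", "adult", "neonatal"]},
            index=["nc1", "pc1", "pc2", "nc2"],
        )
        return de, assign

    def test_kept_when_all_criteria_met(self):
        de, assign = self._fixtures()
        p = NeighborPair("nc1", "pc1", "PC-NC", 3000, tier="hi")
        assert concordant_pairs([p], de, assign) == [p]

    def test_discordant_labels_dropped(self):
        de, assign = self._fixtures()
        p = NeighborPair("nc1", "pc2", "PC-NC", 3000, tier="hi")
        assert concordant_pairs([p], de, assign) == []

    def test_non_significant_lncrna_dropped(self):
        de, assign = self._fixtures()
        p = NeighborPair("nc2", "pc1", "PC-NC", 3000, tier="hi")
        assert concordant_pairs([p], de, assign) == []

    def test_distant_pair_dropped(self):
        de, assign = self._fixtures()
        p = NeighborPair("nc1", "pc1", "PC-NC", 15_000, tier="hi")
        assert concordant_pairs([p], de, assign) == []
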