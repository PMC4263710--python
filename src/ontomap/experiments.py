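"""Canned synthetic-study experiments with summary metrics.

Three experiment designs exercise the pipeline end to end:

* :func:`null_calibration` — a pure-null study (every gene non-changing) to
  measure the ANOVA type-I error rate and the random-pair null correlation.
* :func:`null_pair_comparison` — a denser pure-null genome where uncoupled
  hi-tier PC-NC pairs are compared against the random null (they should be
  statistically indistinguishable).
* :func:`planted_recovery` — the planted-structure study with three
  ontogenic classes, cis-coupled PC-NC pairs (coupling 0.8) and discordant
  decoys; measures DE sensitivity/specificity, pattern-label accuracy,
  concordant-pair recovery, and the neighbor-pair correlation separation.

Problem sizes are desk-scale (a few thousand genes per study); every study
condition is stated in the config builders below.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import ks_2samp

from . import de, expression, pairs, patterns
from .simulate import SimConfig, simulate

__all__ = [
    "null_calibration_config",
    "null_pair_config",
    "recovery_config",
    "null_calibration",
    "null_pair_comparison",
    "planted_recovery",
]


def null_calibration_config(seed: int) -> SimConfig:
    """2,000 non-changing genes (half coding, half lncRNA), CV 0.2."""
    return SimConfig(
        seed=seed, n_coding=1_000, n_lncrna=1_000, n_small_rna=0,
        pattern_fractions={"flat": 1.0}, n_cis_pairs=0, n_decoy_pairs=0,
        within_age_cv=0.2,
    )


def null_pair_config(seed: int) -> SimConfig:
    """Dense pure-null genome so >=1,000 uncoupled hi-tier PC-NC pairs exist."""
    return SimConfig(
        seed=seed, n_coding=3_500, n_lncrna=3_500, n_small_rna=0,
        pattern_fractions={"flat": 1.0}, n_cis_pairs=0, n_decoy_pairs=0,
        within_age_cv=0.2, spacing_range=(1_000, 15_000),
        chrom_length=60_000_000,
    )


def recovery_config(seed: int) -> SimConfig:
    """Planted-structure study: 3 pattern classes (60/15/25 of changing genes),
    fold change 4, within-age CV 0.1, 100 cis pairs (rho 0.8) and 50 decoys.

    Uncoupled lncRNAs are kept >10 kb from coding genes so the hi-tier PC-NC
    set is exactly the planted pairs (cis coupling restricted to hi tier).
    """
    return SimConfig(seed=seed, within_age_cv=0.1, lncrna_clearance=10_000)


def null_calibration(seed: int, alpha: float = 0.05, n_random: int = 10_000) -> dict:
    """Type-I error of the ANOVA and mean r of the random-pair null."""
    sim = simulate(null_calibration_config(seed))
    tab = de.anova_table(sim.matrix)
    frac = float((tab["p_raw"] < alpha).mean())
    log_prof = de.log_fpkm(sim.matrix.age_means())
    null = pairs.random_pair_null(sim.genes, log_prof, n_pairs=n_random, seed=seed + 1)
    rs = [p.r for p in null if p.r is not None]
    return {
        "n_genes": len(tab),
        "frac_p_below_alpha": frac,
        "null_mean_r": float(np.mean(rs)),
        "n_null_pairs": len(rs),
    }


def _hi_pcnc_rs(sim, max_gap: int = 10_000) -> list[float]:
    prof = sim.matrix.age_means()
    log_prof = de.log_fpkm(prof)
    expressed = set(expression.expressed_genes(prof))
    hi = pairs.pair_correlations(
        pairs.filter_hi(pairs.build_pairs(sim.genes, "lncRNA"), expressed, max_gap),
        log_prof,
    )
    return [p.r for p in hi if p.r is not None]


def null_pair_comparison(seed: int, n_seeds: int = 20, n_null: int = 1_000) -> dict:
    """KS comparison of uncoupled hi-tier PC-NC pairs against the random null.

    Runs ``n_seeds`` independent pure-null studies; reports the median KS p.
    """
    pvals, n_hi = [], []
    for s in range(n_seeds):
        sim = simulate(null_pair_config(seed + s))
        r_hi = _hi_pcnc_rs(sim)
        log_prof = de.log_fpkm(sim.matrix.age_means())
        null = pairs.random_pair_null(
            sim.genes, log_prof, n_pairs=n_null, seed=seed + 10_000 + s
        )
        r_null = [p.r for p in null if p.r is not None]
        pvals.append(float(ks_2samp(r_hi, r_null).pvalue))
        n_hi.append(len(r_hi))
    return {
        "ks_pvalues": pvals,
        "median_ks_p": float(np.median(pvals)),
        "median_n_hi_pairs": int(np.median(n_hi)),
    }


def planted_recovery(seed: int, alpha: float = 0.05, fc: float = 1.5,
                     mean_floor: float = 1.0, n_random: int = 10_000) -> dict:
    """Full-pipeline recovery metrics on the planted-structure study.

    DE sensitivity is measured among planted changing genes whose true
    (noise-free) curves satisfy the abundance and fold-change gates — the
    mean-FPKM floor removes low-abundance lncRNAs by design, which is an
    intended filter, not a power failure.  Pattern accuracy is measured on
    DE-called planted changing genes.
    """
    sim = simulate(recovery_config(seed))
    truth = sim.gene_truth
    m = sim.matrix
    prof = m.age_means()
    log_prof = de.log_fpkm(prof)
    expressed = set(expression.expressed_genes(prof))

    klass = truth["klass"]
    expressed_by_class = {
        c: int(sum(1 for g in expressed if klass.get(g) == c))
        for c in ("coding", "lncRNA")
    }

    # --- differential expression ---
    det = de.call_de(m, alpha=alpha, fc=fc, mean_floor=mean_floor)
    tm = truth[[c for c in truth.columns if c.startswith("true_mean_")]]
    changing = truth.index[truth["pattern"] != "flat"]
    eligible = changing[
        (tm.loc[changing].mean(axis=1) > mean_floor)
        & ((tm.loc[changing].max(axis=1) + 1) / (tm.loc[changing].min(axis=1) + 1) > fc)
    ]
    flat = truth.index[truth["pattern"] == "flat"]
    de_sensitivity = float(det.loc[eligible, "significant"].mean())
    flat_false_rate = float(det.loc[flat, "significant"].mean())

    # --- pattern clustering ---
    de_genes = det.index[det["significant"]]
    assign = patterns.cluster_patterns(patterns.zscore_profiles(prof.loc[de_genes]))
    planted_de = [g for g in de_genes if truth.loc[g, "pattern"] != "flat"]
    pattern_accuracy = float(
        np.mean([assign.loc[g, "label"] == truth.loc[g, "pattern"] for g in planted_de])
    )

    # --- neighbor pairs ---
    pair_sets = {}
    for anchor, cls in (("coding", "PC-PC"), ("lncRNA", "PC-NC")):
        all_tier = pairs.pair_correlations(pairs.build_pairs(sim.genes, anchor), log_prof)
        hi_tier = pairs.pair_correlations(
            pairs.filter_hi(all_tier, expressed), log_prof
        )
        pair_sets[(cls, "all")] = all_tier
        pair_sets[(cls, "hi")] = hi_tier
    null = pairs.random_pair_null(sim.genes, log_prof, n_pairs=n_random, seed=seed + 1)

    def _rs(ps):
        return np.array([p.r for p in ps if p.r is not None])

    medians = {k: float(np.median(_rs(v))) for k, v in pair_sets.items()}
    mean_all_pcnc = float(np.mean(_rs(pair_sets[("PC-NC", "all")])))
    mean_null = float(np.mean(_rs(null)))
    mean_hi_pcnc = float(np.mean(_rs(pair_sets[("PC-NC", "hi")])))

    cis = {(r.nc_id, r.pc_id) for r in sim.pair_truth.itertuples() if r.kind == "cis"}
    decoys = {(r.nc_id, r.pc_id) for r in sim.pair_truth.itertuples() if r.kind == "decoy"}
    planted_pairs = [p for p in pair_sets[("PC-NC", "hi")] if (p.id_a, p.id_b) in cis]
    planted_peak = pairs.r_distribution(planted_pairs).peak if planted_pairs else float("nan")

    conc = pairs.concordant_pairs(pair_sets[("PC-NC", "hi")], det, assign, alpha=alpha)
    conc_ids = {(p.id_a, p.id_b) for p in conc}
    cis_sensitivity = float(np.mean([c in conc_ids for c in sorted(cis)]))
    decoy_rejection = float(np.mean([d not in conc_ids for d in sorted(decoys)]))

    de_frac_of_expressed = {
        c: float(
            np.mean([bool(det.loc[g, "significant"]) for g in expressed if klass.get(g) == c])
        )
        for c in ("coding", "lncRNA")
    }

    return {
        "n_genes": len(truth),
        "expressed_by_class": expressed_by_class,
        "de_frac_of_expressed": de_frac_of_expressed,
        "de_sensitivity": de_sensitivity,
        "n_de_eligible": len(eligible),
        "flat_false_call_rate": flat_false_rate,
        "pattern_accuracy": pattern_accuracy,
        "n_patterned_de": len(planted_de),
        "median_r": medians,
        "mean_r_pcnc_all": mean_all_pcnc,
        "mean_r_pcnc_hi": mean_hi_pcnc,
        "mean_r_null": mean_null,
        "median_null_r": float(np.median(_rs(null))),
        "planted_pair_mean_r": float(np.mean(_rs(planted_pairs))),
        "planted_pair_peak": float(planted_peak),
        "n_planted_found": len(planted_pairs),
        "cis_sensitivity": cis_sensitivity,
        "decoy_rejection": decoy_rejection,
        "n_concordant": len(conc),
        "label_counts": assign["label"].value_counts().to_dict(),
    }
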