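"""End-to-end pipeline orchestration.

``run_all`` executes annotation merging, expression filtering, differential
expression, pattern clustering, inter-age similarity, neighbor-pair analysis
and (optionally) enrichment from a single configuration, writing every stage
table as a self-describing TSV (comment header lines carry the parameters and
seed) plus a summary report.  The pipeline is a pure function of
(inputs, configuration, seed): reruns produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotation, de, enrichment, expression, pairs, patterns, similarity
from .simulate import SimConfig, simulate, write_outputs

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Inputs and thresholds for a full pipeline run.

    Either ``simulate`` is set (synthetic study) or ``primary_gtf`` [+
    ``secondary_gtf``], ``expr`` and ``samples`` name input files.  Threshold
    defaults are the analysis standards: expressed at FPKM > 1, DE at fold
    change > 1.5 and BH-adjusted p < 0.05, three pattern clusters, 10 kb
    neighbor window, 10,000 random null pairs.
    """

    outdir: str = "ontomap_out"
    simulate: Optional[SimConfig] = None
    primary_gtf: Optional[str] = None
    secondary_gtf: Optional[str] = None
    expr: Optional[str] = None
    samples: Optional[str] = None
    term_map: Optional[str] = None
    expressed_threshold: float = 1.0
    alpha: float = 0.05
    fc: float = 1.5
    mean_floor: float = 1.0
    k: int = 3
    max_gap: int = 10_000
    n_random: int = 10_000
    seed: int = 0
    drop_small_rna: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("simulate"), dict):
            d["simulate"] = SimConfig(**d["simulate"])
        return cls(**d)


def _write_tsv(df: pd.DataFrame, path: Path, params: dict, index: bool = True) -> None:
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
    df.to_csv(path, sep="\t", mode="a", index=index, float_format="%.6g")


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns the summary report as a nested dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {
        "seed": config.seed, "expressed_threshold": config.expressed_threshold,
        "alpha": config.alpha, "fc": config.fc, "mean_floor": config.mean_floor,
        "k": config.k, "max_gap": config.max_gap, "n_random": config.n_random,
    }

    # ---- inputs ----------------------------------------------------------
    if config.simulate is not None:
        sim = simulate(config.simulate)
        write_outputs(sim, outdir / "sim")
        gs = sim.genes
        matrix = sim.matrix
    else:
        for name in ("primary_gtf", "expr", "samples"):
            p = getattr(config, name)
            if p is None:
                raise ValueError(f"run_all requires {name} (or a simulate config)")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if config.secondary_gtf and not Path(config.secondary_gtf).exists():
            raise FileNotFoundError(f"secondary_gtf: {config.secondary_gtf}")
        if config.term_map and not Path(config.term_map).exists():
            raise FileNotFoundError(f"term_map: {config.term_map}")
        gs = annotation.read_gtf(config.primary_gtf)
        if config.secondary_gtf:
            gs = annotation.merge_nonoverlapping(gs, annotation.read_gtf(config.secondary_gtf))
        matrix = expression.ExpressionMatrix.from_tsv(config.expr, config.samples)

    gs = annotation.classify_genes(gs)
    annotation.write_gtf(gs, outdir / "merged.gtf")
    klass = {g.gene_id: g.klass for g in gs}

    analysis_ids = [
        g for g in matrix.gene_ids
        if not (config.drop_small_rna and klass.get(g) == "small_rna")
    ]
    matrix = matrix.subset_genes(analysis_ids)

    # ---- expression filter -----------------------------------------------
    profiles = matrix.age_means()
    expressed = expression.expressed_genes(profiles, config.expressed_threshold)
    per_age = expression.expressed_per_age(profiles, klass, config.expressed_threshold)
    _write_tsv(per_age, outdir / "expressed_per_age.tsv", params)
    expressed_by_class = {
        c: sum(1 for g in expressed if klass.get(g) == c) for c in ("coding", "lncRNA")
    }

    # ---- differential expression -----------------------------------------
    de_tab = de.call_de(matrix, alpha=config.alpha, fc=config.fc, mean_floor=config.mean_floor)
    _write_tsv(de_tab, outdir / "de.tsv", params)
    de_genes = de_tab.index[de_tab["significant"]]
    de_by_class = {c: sum(1 for g in de_genes if klass.get(g) == c) for c in ("coding", "lncRNA")}

    # ---- pattern clustering ----------------------------------------------
    z = patterns.zscore_profiles(profiles.loc[de_genes])
    assignments = patterns.cluster_patterns(z, k=config.k)
    _write_tsv(assignments, outdir / "patterns.tsv", params)
    density = patterns.chromosome_density(assignments, gs)
    _write_tsv(density, outdir / "chromosome_density.tsv", params, index=False)
    label_counts = assignments["label"].value_counts().to_dict()

    # ---- inter-age similarity --------------------------------------------
    sim_report = {}
    for name, sub in (
        ("all", list(expressed)),
        ("coding", [g for g in expressed if klass.get(g) == "coding"]),
        ("lncrna", [g for g in expressed if klass.get(g) == "lncRNA"]),
    ):
        if len(sub) >= 2:
            s = similarity.age_similarity(matrix, sub)
            _write_tsv(s, outdir / f"similarity_{name}.tsv", params)
            sim_report[name] = round(similarity.mean_offdiagonal(s), 4)

    # ---- neighbor pairs ---------------------------------------------------
    log_prof = de.log_fpkm(profiles)
    expressed_set = set(expressed)
    pair_sets: dict[tuple[str, str], list] = {}
    for anchor in ("coding", "lncRNA"):
        all_tier = pairs.pair_correlations(pairs.build_pairs(gs, anchor), log_prof)
        hi_tier = pairs.pair_correlations(
            pairs.filter_hi(all_tier, expressed_set, config.max_gap), log_prof
        )
        cls = "PC-PC" if anchor == "coding" else "PC-NC"
        pair_sets[(cls, "all")] = all_tier
        pair_sets[(cls, "hi")] = hi_tier
    null = pairs.random_pair_null(gs, log_prof, n_pairs=config.n_random, seed=config.seed)
    pair_sets[("random-PC", "all")] = null

    all_pairs = [p for ps in pair_sets.values() for p in ps]
    _write_tsv(pairs.pairs_to_frame(all_pairs), outdir / "pairs.tsv", params, index=False)
    pair_report = {}
    for (cls, tier), ps in pair_sets.items():
        if ps and any(p.r is not None for p in ps):
            hist = pairs.r_distribution(ps)
            _write_tsv(
                hist.to_frame(), outdir / f"hist_{cls.replace('-', '_')}_{tier}.tsv",
                params, index=False,
            )
            pair_report[f"{cls} {tier}"] = {"n": len(ps), "peak": hist.peak}
        else:
            pair_report[f"{cls} {tier}"] = {"n": len(ps), "peak": None}

    concordant = pairs.concordant_pairs(
        pair_sets[("PC-NC", "hi")], de_tab, assignments,
        alpha=config.alpha, max_gap=config.max_gap,
    )
    _write_tsv(pairs.pairs_to_frame(concordant), outdir / "concordant.tsv", params, index=False)

    # ---- enrichment --------------------------------------------------------
    enrich_n = None
    if config.term_map:
        term_map = enrichment.read_term_map(config.term_map)
        universe = [g for g in expressed if klass.get(g) == "coding"]
        partners = sorted({p.id_b for p in concordant} & set(universe))
        res = enrichment.enrich(partners, universe, term_map)
        _write_tsv(res, outdir / "enrichment.tsv", params, index=False)
        enrich_n = int((res["fdr"] < 0.05).sum()) if len(res) else 0

    # ---- report ------------------------------------------------------------
    report = {
        "params": params,
        "n_genes_annotated": len(gs),
        "n_genes_analyzed": len(matrix.gene_ids),
        "expressed": expressed_by_class,
        "differentially_expressed": de_by_class,
        "cluster_labels": label_counts,
        "pairs": pair_report,
        "n_concordant_pairs": len(concordant),
    }
    if enrich_n is not None:
        report["n_enriched_terms_fdr05"] = enrich_n
    _write_report(report, outdir / "report.txt")
    return report


def _write_report(report: dict, path: Path) -> None:
    lines = ["# ontomap pipeline report"]
    for k, v in report["params"].items():
        lines.append(f"# {k}={v}")
    lines.append("")
    lines.append(f"genes annotated\t{report['n_genes_annotated']}")
    lines.append(f"genes analyzed\t{report['n_genes_analyzed']}")
    for c, n in report["expressed"].items():
        lines.append(f"expressed {c}\t{n}")
    for c, n in report["differentially_expressed"].items():
        lines.append(f"differentially expressed {c}\t{n}")
    total_labeled = sum(report["cluster_labels"].values()) or 1
    for label, n in sorted(report["cluster_labels"].items()):
        lines.append(f"cluster {label}\t{n}\t{n / total_labeled:.3f}")
    for key, info in report["pairs"].items():
        lines.append(f"pairs {key}\t{info['n']}\tpeak={info['peak']}")
    lines.append(f"concordant PC-NC pairs\t{report['n_concordant_pairs']}")
    if "n_enriched_terms_fdr05" in report:
        lines.append(f"enriched terms (FDR<0.05)\t{report['n_enriched_terms_fdr05']}")
    Path(path).write_text("\n".join(lines) + "\n")
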