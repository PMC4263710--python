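"""Synthetic developmental-transcriptome generator with ground truth.

Emulates a 12-age (postnatal day -2 through 60), 3-replicate liver-style
bulk RNA-seq study: a synthetic genome annotation with protein-coding genes,
lncRNAs (~10-fold lower abundance on average) and a few small RNAs; planted
ontogenic pattern classes (neonatal-, adolescent-, adult-enriched, plus
non-changing genes); and planted cis-coupled coding/lncRNA neighbor pairs
within 10 kb (a mixture of intergenic and antisense-overlap placements),
alongside discordant decoy pairs for specificity checks.

Model
-----
Each gene's per-age mean curve is built on the log2(FPKM+1) scale:

    log2(mean_a + 1) = log2(B + 1) + A_c * s(a)

where B is a lognormal baseline, s is a standardized shape vector and A_c an
amplitude chosen so the curve's max/min FPKM ratio equals the configured fold
change.  Shapes are a class archetype (Gaussian bump over age rank peaking
inside the class's stage window) plus per-gene jitter; cis-coupled partners
mix the anchor's shape at weight rho with independent jitter, so the
expected profile correlation of a planted pair is rho.  Replicate values are
the age mean times lognormal noise with a configured coefficient of
variation.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneSet, write_gtf
from .expression import ExpressionMatrix

__all__ = ["SimConfig", "SimResult", "archetype", "simulate", "write_outputs"]

DEFAULT_AGES = (-2, 0, 1, 3, 5, 10, 15, 20, 25, 30, 45, 60)

#: archetype peak day per pattern class (inside the matching stage window)
_PEAK_DAY = {"neonatal": 3, "adolescent": 20, "adult": 60}

_LNC_BIOTYPES = ("lincRNA", "antisense", "processed_transcript")
_SMALL_BIOTYPES = ("tRNA", "rRNA", "snRNA", "snoRNA", "miRNA", "miscRNA")


@dataclass
class SimConfig:
    """Study-design and noise parameters for :func:`simulate`.

    Defaults mirror the emulated study: 12 ages x 3 replicates, lncRNAs ~10x
    less abundant than coding genes, three planted pattern classes plus
    non-changing genes, fold change 4 between peak and trough ages, and 100
    cis-coupled pairs (coupling 0.8) within 10 kb.
    """

    seed: int = 0
    # genome
    n_chrom: int = 5
    chrom_length: int = 40_000_000
    gene_length_range: tuple[int, int] = (1_000, 20_000)
    spacing_range: tuple[int, int] = (2_000, 40_000)
    # roster
    n_coding: int = 2_000
    n_lncrna: int = 1_000
    n_small_rna: int = 50
    # design
    ages: tuple[int, ...] = DEFAULT_AGES
    replicates: int = 3
    pattern_fractions: dict = field(
        default_factory=lambda: {
            "neonatal": 0.45, "adolescent": 0.1125, "adult": 0.1875, "flat": 0.25,
        }
    )
    # expression model
    fold_change: float = 4.0
    within_age_cv: float = 0.2
    lncrna_abundance_ratio: float = 0.1
    lncrna_cv_scale: float = 1.0
    coding_baseline_median: float = 20.0
    baseline_sigma: float = 1.0
    shape_jitter: float = 0.3
    # planted pairs
    n_cis_pairs: int = 100
    cis_max_gap: int = 10_000
    cis_rho: float = 0.8
    n_decoy_pairs: int = 50
    antisense_fraction: float = 0.3
    cis_min_baseline: float = 5.0
    # extra clearance (bp) around uncoupled lncRNAs; >= cis_max_gap confines
    # hi-tier PC-NC pairs to the planted ones
    lncrna_clearance: int = 0

    def __post_init__(self) -> None:
        total = sum(self.pattern_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"pattern_fractions must sum to 1, got {total}")
        if not -1.0 <= self.cis_rho <= 1.0:
            raise ValueError("cis_rho must lie in [-1, 1]")
        for name in ("n_coding", "n_lncrna", "n_small_rna", "n_cis_pairs", "n_decoy_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cis_pairs + self.n_decoy_pairs > min(self.n_coding, self.n_lncrna):
            raise ValueError("more planted pairs than coding or lncRNA genes")
        if len(self.ages) < 2:
            raise ValueError("need at least 2 ages")


@dataclass
class SimResult:
    """Generator output: annotation, expression, and ground-truth tables."""

    config: SimConfig
    genes: GeneSet
    matrix: ExpressionMatrix
    gene_truth: pd.DataFrame  # per-gene class/pattern/baseline/pair bookkeeping + true means
    pair_truth: pd.DataFrame  # planted cis and decoy pairs


def archetype(pattern: str, ages: Sequence[int] = DEFAULT_AGES) -> np.ndarray:
    """Unit-scale ontogenic curve for a pattern class (max 1, positive).

    A Gaussian bump over the age rank centered at the class's peak day
    (neonatal: day 3, adolescent: day 20, adult: day 60); ``flat`` is the
    constant 1 curve.
    """
    ages = list(ages)
    if pattern == "flat":
        return np.ones(len(ages))
    if pattern not in _PEAK_DAY:
        raise ValueError(f"unknown pattern class {pattern!r}")
    peak_day = _PEAK_DAY[pattern]
    center = min(range(len(ages)), key=lambda i: abs(ages[i] - peak_day))
    ranks = np.arange(len(ages), dtype=float)
    width = 1.5
    curve = np.exp(-0.5 * ((ranks - center) / width) ** 2)
    return curve / curve.max()


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _jittered_shape(e: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Class archetype plus per-gene jitter, unit-variance by construction."""
    xi = _zscore(rng.standard_normal(len(e)))
    return (e + tau * xi) / math.sqrt(1.0 + tau * tau)


def _split_exons(start: int, end: int, rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """1-3 exons spanning exactly [start, end)."""
    n_ex = int(rng.integers(1, 4))
    length = end - start
    if n_ex == 1 or length < 6 * n_ex:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * (n_ex - 1), replace=False))
    bounds = [start] + [start + int(c) for c in cuts] + [end]
    return tuple((bounds[2 * i], bounds[2 * i + 1]) for i in range(n_ex))


def simulate(config: SimConfig) -> SimResult:
    """Generate the synthetic annotation, expression matrix, and ground truth."""
    rng = np.random.default_rng(config.seed)
    ages = list(config.ages)
    n_ages = len(ages)

    # class archetypes (z-scored) and amplitudes realizing the fold change
    classes = [c for c in config.pattern_fractions if c != "flat"]
    arch_z = {c: _zscore(archetype(c, ages)) for c in classes}
    amp = {
        c: math.log2(config.fold_change) / (arch_z[c].max() - arch_z[c].min())
        for c in classes
    }

    frac = config.pattern_fractions
    class_names = list(frac)
    class_p = np.array([frac[c] for c in class_names])
    nonflat = [c for c in class_names if c != "flat"]
    nonflat_p = np.array([frac[c] for c in nonflat])
    nonflat_p = nonflat_p / nonflat_p.sum()

    tau = config.shape_jitter
    sigma = math.sqrt(math.log(1.0 + config.within_age_cv**2))

    n_pairs = config.n_cis_pairs + config.n_decoy_pairs
    n_reg_coding = config.n_coding - n_pairs
    n_reg_lnc = config.n_lncrna - n_pairs

    records: list[dict] = []  # per-gene bookkeeping, filled before placement
    pair_records: list[dict] = []

    def _baseline(scale: float, floor: float = 0.0) -> float:
        b = scale * math.exp(config.baseline_sigma * rng.standard_normal())
        return max(b, floor)

    def _shape_for(pattern: str) -> np.ndarray:
        if pattern == "flat":
            return np.zeros(n_ages)
        return _jittered_shape(arch_z[pattern], tau, rng)

    def _add_gene(gid, klass, biotype, pattern, shape, baseline,
                  pair_id="", pair_role="", rho=np.nan, cv_scale=1.0):
        a = amp[pattern] if pattern != "flat" else 0.0
        logm = math.log2(baseline + 1.0) + a * shape
        mean = np.maximum(np.exp2(logm) - 1.0, 0.0)
        records.append(
            dict(gene_id=gid, klass=klass, biotype=biotype, pattern=pattern,
                 baseline=baseline, pair_id=pair_id, pair_role=pair_role,
                 rho=rho, cv_scale=cv_scale, shape=shape, true_means=mean)
        )

    # --- regular genes -----------------------------------------------------
    for i in range(n_reg_coding):
        pat = rng.choice(class_names, p=class_p)
        _add_gene(f"PC{i:05d}", "coding", "protein_coding", pat,
                  _shape_for(pat), _baseline(config.coding_baseline_median))
    lnc_scale = config.coding_baseline_median * config.lncrna_abundance_ratio
    for i in range(n_reg_lnc):
        pat = rng.choice(class_names, p=class_p)
        bt = str(rng.choice(["lincRNA", "processed_transcript"]))
        _add_gene(f"NC{i:05d}", "lncRNA", bt, pat, _shape_for(pat),
                  _baseline(lnc_scale), cv_scale=config.lncrna_cv_scale)
    for i in range(config.n_small_rna):
        bt = str(rng.choice(_SMALL_BIOTYPES))
        _add_gene(f"SR{i:03d}", "small_rna", bt, "flat",
                  np.zeros(n_ages), _baseline(lnc_scale))

    # --- planted pairs -----------------------------------------------------
    for j in range(config.n_cis_pairs):
        pat = str(rng.choice(nonflat, p=nonflat_p))
        s_anchor = _shape_for(pat)
        xi = _zscore(rng.standard_normal(n_ages))
        s_partner = config.cis_rho * s_anchor + math.sqrt(1.0 - config.cis_rho**2) * xi
        anti = bool(rng.random() < config.antisense_fraction)
        nc_id, pc_id = f"NCX{j:04d}", f"PCX{j:04d}"
        bt = "antisense" if anti else "lincRNA"
        _add_gene(nc_id, "lncRNA", bt, pat, s_anchor,
                  _baseline(lnc_scale, floor=config.cis_min_baseline),
                  pair_id=f"cis{j:04d}", pair_role="anchor", rho=config.cis_rho,
                  cv_scale=config.lncrna_cv_scale)
        _add_gene(pc_id, "coding", "protein_coding", pat, s_partner,
                  _baseline(config.coding_baseline_median),
                  pair_id=f"cis{j:04d}", pair_role="partner", rho=config.cis_rho)
        pair_records.append(
            dict(pair_id=f"cis{j:04d}", nc_id=nc_id, pc_id=pc_id, kind="cis",
                 rho=config.cis_rho, antisense=anti, pattern_nc=pat, pattern_pc=pat)
        )
    for j in range(config.n_decoy_pairs):
        pat_nc = str(rng.choice(nonflat, p=nonflat_p))
        others = [c for c in nonflat if c != pat_nc]
        pat_pc = str(rng.choice(others)) if others else pat_nc
        anti = bool(rng.random() < config.antisense_fraction)
        nc_id, pc_id = f"NCD{j:04d}", f"PCD{j:04d}"
        _add_gene(nc_id, "lncRNA", "antisense" if anti else "lincRNA", pat_nc,
                  _shape_for(pat_nc),
                  _baseline(lnc_scale, floor=config.cis_min_baseline),
                  pair_id=f"dec{j:04d}", pair_role="anchor", rho=0.0,
                  cv_scale=config.lncrna_cv_scale)
        _add_gene(pc_id, "coding", "protein_coding", pat_pc, _shape_for(pat_pc),
                  _baseline(config.coding_baseline_median),
                  pair_id=f"dec{j:04d}", pair_role="partner", rho=0.0)
        pair_records.append(
            dict(pair_id=f"dec{j:04d}", nc_id=nc_id, pc_id=pc_id, kind="decoy",
                 rho=0.0, antisense=anti, pattern_nc=pat_nc, pattern_pc=pat_pc)
        )

    by_id = {r["gene_id"]: r for r in records}

    # --- genome placement --------------------------------------------------
    # units: singleton genes or planted (partner, anchor) pairs; shuffled and
    # distributed round-robin over chromosomes, then laid out left to right.
    singles = [r["gene_id"] for r in records if not r["pair_id"]]
    pair_units = [(p["pair_id"], p["pc_id"], p["nc_id"], p["antisense"]) for p in pair_records]
    units: list[tuple] = [("single", g) for g in singles] + [("pair", *u) for u in pair_units]
    order = rng.permutation(len(units))
    chrom_of = [f"chr{(i % config.n_chrom) + 1}" for i in range(len(units))]
    cursors = {f"chr{c + 1}": 0 for c in range(config.n_chrom)}
    last_clearance = {ch: 0 for ch in cursors}
    placements: dict[str, tuple[str, int, int, str]] = {}
    lo_len, hi_len = config.gene_length_range
    lo_sp, hi_sp = config.spacing_range

    def _clearance_of(unit) -> int:
        if unit[0] == "single":
            if by_id[unit[1]]["klass"] == "lncRNA":
                return config.lncrna_clearance
            return 0
        # planted pairs are kept clear of flanking genes so the partner is
        # genuinely the anchor's nearest coding neighbor
        return config.cis_max_gap + 1

    for k, ui in enumerate(order):
        unit = units[ui]
        chrom = chrom_of[k]
        spacing = int(rng.integers(lo_sp, hi_sp))
        spacing = max(spacing, last_clearance[chrom], _clearance_of(unit))
        if unit[0] == "single":
            gid = unit[1]
            length = int(rng.integers(lo_len, hi_len))
            start = cursors[chrom] + spacing
            strand = "+" if rng.random() < 0.5 else "-"
            placements[gid] = (chrom, start, start + length, strand)
            cursors[chrom] = start + length
        else:
            _, _pid, pc_id, nc_id, anti = unit
            pc_len = int(rng.integers(lo_len, hi_len))
            nc_len = int(rng.integers(lo_len, hi_len))
            pc_start = cursors[chrom] + spacing
            pc_strand = "+" if rng.random() < 0.5 else "-"
            placements[pc_id] = (chrom, pc_start, pc_start + pc_len, pc_strand)
            if anti:
                # overlapping, opposite strand (gap 0)
                nc_start = pc_start + int(rng.integers(0, max(pc_len // 2, 1)))
                nc_strand = "+" if pc_strand == "-" else "-"
            else:
                gap = int(rng.integers(0, config.cis_max_gap))
                nc_start = pc_start + pc_len + gap
                nc_strand = "+" if rng.random() < 0.5 else "-"
            placements[nc_id] = (chrom, nc_start, nc_start + nc_len, nc_strand)
            cursors[chrom] = max(pc_start + pc_len, nc_start + nc_len)
        last_clearance[chrom] = _clearance_of(unit)
        if cursors[chrom] > config.chrom_length:
            raise ValueError(
                f"infeasible placement: {chrom} exceeds chrom_length="
                f"{config.chrom_length}; increase it or reduce gene counts"
            )

    gene_models = []
    for r in records:
        chrom, start, end, strand = placements[r["gene_id"]]
        gene_models.append(
            GeneModel(
                gene_id=r["gene_id"], chrom=chrom, strand=strand,
                start=start, end=end, exons=_split_exons(start, end, rng),
                biotype=r["biotype"], klass=r["klass"], source="sim",
            )
        )
    genes = GeneSet(gene_models)

    # --- expression values -------------------------------------------------
    sample_rows = [
        {"sample_id": f"d{a}_r{rep}", "age_day": a, "replicate": rep}
        for a in ages
        for rep in range(1, config.replicates + 1)
    ]
    samples = pd.DataFrame(sample_rows)
    mean_mat = np.vstack([r["true_means"] for r in records])  # genes x ages
    rep_means = np.repeat(mean_mat, config.replicates, axis=1)  # genes x samples
    cv_scales = np.array([r["cv_scale"] for r in records])[:, None]
    sig = np.sqrt(np.log1p((config.within_age_cv * cv_scales) ** 2))
    noise = np.exp(rng.standard_normal(rep_means.shape) * sig - sig**2 / 2.0)
    values = pd.DataFrame(
        rep_means * noise,
        index=[r["gene_id"] for r in records],
        columns=[s["sample_id"] for s in sample_rows],
    )
    values.index.name = "gene_id"
    matrix = ExpressionMatrix(values, samples)

    # --- truth tables ------------------------------------------------------
    gt_rows = []
    for r in records:
        chrom, start, end, strand = placements[r["gene_id"]]
        row = dict(
            gene_id=r["gene_id"], klass=r["klass"], biotype=r["biotype"],
            pattern=r["pattern"], baseline=r["baseline"], chrom=chrom,
            start=start, end=end, strand=strand, pair_id=r["pair_id"],
            pair_role=r["pair_role"], rho=r["rho"],
        )
        for a, mval in zip(ages, r["true_means"]):
            row[f"true_mean_{a}"] = mval
        gt_rows.append(row)
    gene_truth = pd.DataFrame(gt_rows).set_index("gene_id")

    pt_rows = []
    for p in pair_records:
        pc = placements[p["pc_id"]]
        nc = placements[p["nc_id"]]
        gap = max(pc[1] - nc[2], nc[1] - pc[2], 0)
        pt_rows.append({**p, "gap_bp": gap})
    pair_truth = pd.DataFrame(
        pt_rows,
        columns=["pair_id", "nc_id", "pc_id", "kind", "rho", "antisense",
                 "pattern_nc", "pattern_pc", "gap_bp"],
    )

    return SimResult(config=config, genes=genes, matrix=matrix,
                     gene_truth=gene_truth, pair_truth=pair_truth)


def write_outputs(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write annotation, expression, sample sheet, and truth tables to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": outdir / "merged.gtf",
        "expr": outdir / "expr.tsv",
        "samples": outdir / "samples.tsv",
        "gene_truth": outdir / "truth_genes.tsv",
        "pair_truth": outdir / "truth_pairs.tsv",
    }
    write_gtf(sim.genes, paths["gtf"])
    sim.matrix.to_tsv(paths["expr"], paths["samples"])
    sim.gene_truth.to_csv(paths["gene_truth"], sep="\t", float_format="%.6g")
    sim.pair_truth.to_csv(paths["pair_truth"], sep="\t", index=False, float_format="%.6g")
    return paths
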