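# ontomap

Ontogenic expression profiling of protein-coding genes and long non-coding
RNAs (lncRNAs) across a developmental time course, with a focus on *cis*
candidate regulation: lncRNAs whose expression trajectory tracks that of a
genomically neighboring coding gene.

The package is written for transcriptomics analysts working with replicated
multi-age bulk expression studies (e.g. postnatal organ maturation series
sampled at days −2 through 60, n = 3 per age). It takes a gene annotation
(GTF, optionally merged from a primary biotyped source and a secondary
noncoding model set), a genes × samples FPKM table with a sample sheet, and
optionally a flat gene → term map, and produces expressed-gene filters,
differential-expression calls, ontogenic pattern clusters, inter-age
similarity matrices, neighbor-pair correlation distributions with a
random-pair null, concordant cis-candidate pairs, and term enrichment.

## The analysis

* **Expressed genes** — a gene is expressed if its replicate-averaged FPKM
  exceeds 1 at any age (strict `>`); per-age counts are reported separately
  for coding genes and lncRNAs.
* **Differential expression** — one-way fixed-effects ANOVA on
  log₂(FPKM+1) with age as the factor, F ~ F(a−1, N−a). A gene is called
  significant when mean FPKM > 1 over all samples, the max/min age-mean fold
  change (pseudocount 1) exceeds 1.5, and the Benjamini–Hochberg adjusted
  p-value is below 0.05.
* **Ontogenic patterns** — per-age z-scores of log₂(mean FPKM+1) are
  hierarchically clustered (Pearson-correlation distance, average linkage)
  and cut into k = 3 clusters; each cluster is labeled by the developmental
  stage (neonatal / adolescent / adult) in which its centroid peaks.
* **Neighbor pairs** — every anchor gene (coding for PC-PC, lncRNA for
  PC-NC) is paired with its nearest coding neighbor by span gap
  (strand-agnostic; overlapping genes have gap 0). The high-stringency tier
  keeps pairs within 10 kb where the lncRNA (PC-NC) or at least one gene
  (PC-PC) is expressed. Pair correlation r is the Pearson correlation of
  the two log₂(mean FPKM+1) age profiles; 10,000 random coding pairs give
  the null distribution.
* **Concordant cis candidates** — PC-NC hi-tier pairs where the lncRNA is
  differentially expressed (adjusted p < 0.05), the gap is under 10 kb, and
  both genes carry the same pattern label.
* **Enrichment** — one-sided hypergeometric over-representation of a gene
  set against a flat term map, BH-FDR controlled.

A fully ground-truthed synthetic-data generator (`ontomap.simulate`) emulates
the study design — 12 ages × 3 replicates, lncRNAs ~10-fold less abundant,
three planted pattern classes plus non-changing genes, and planted
cis-coupled neighbor pairs (coupling ρ = 0.8) within 10 kb — so every stage
of the pipeline can be validated against planted structure.

## Worked example

```python
from ontomap.simulate import SimConfig, simulate
from ontomap import de, expression, patterns, pairs

cfg = SimConfig(seed=42, n_coding=400, n_lncrna=200, n_small_rna=10,
                n_cis_pairs=20, n_decoy_pairs=10, within_age_cv=0.1)
sim = simulate(cfg)
prof = sim.matrix.age_means()
expressed = expression.expressed_genes(prof)
print(f"expressed genes: {len(expressed)} / {len(prof)}")

det = de.call_de(sim.matrix, alpha=0.05, fc=1.5, mean_floor=1.0)
print(f"differentially expressed: {int(det.significant.sum())}")

z = patterns.zscore_profiles(prof.loc[det.index[det.significant]])
assign = patterns.cluster_patterns(z, k=3)
print("cluster sizes:", assign.label.value_counts().to_dict())

log_prof = de.log_fpkm(prof)
pcnc = pairs.pair_correlations(pairs.build_pairs(sim.genes, "lncRNA"), log_prof)
hi = pairs.pair_correlations(pairs.filter_hi(pcnc, set(expressed)), log_prof)
conc = pairs.concordant_pairs(hi, det, assign)
print(f"PC-NC pairs: {len(pcnc)} all, {len(hi)} hi; concordant: {len(conc)}")
```

prints

```
expressed genes: 604 / 610
differentially expressed: 449
cluster sizes: {'neonatal': 257, 'adult': 103, 'adolescent': 89}
PC-NC pairs: 200 all, 73 hi; concordant: 28
```

604 of 610 genes pass the FPKM > 1 filter; 449 change significantly across
the ages and fall into the three ontogenic clusters, the neonatal class
largest (the planted 60/15/25 split). 73 of the 200 lncRNA-anchored pairs
survive the 10 kb + expression filter, and 28 are concordant cis candidates
(the 20 planted coupled pairs plus incidental same-label neighbors; the
median pair r of the hi tier is +0.15 against −0.08 for the random null,
and the 20 planted pairs average r ≈ 0.79, matching the planted ρ = 0.8).

The same pipeline is available from the shell:

```bash
ontomap simulate --seed 42 --outdir sim/
ontomap de --expr sim/expr.tsv --samples sim/samples.tsv --out de.tsv
ontomap cluster --de de.tsv --expr sim/expr.tsv --samples sim/samples.tsv --out patterns.tsv
ontomap pairs --annot sim/merged.gtf --expr sim/expr.tsv --samples sim/samples.tsv \
              --de de.tsv --patterns patterns.tsv --seed 42 --out pairs.tsv
ontomap run-all --config run.yaml   # the whole pipeline from one YAML config
```

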