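# Methods

## Scope and data model

The pipeline starts from a gene-level annotation and a genes × samples FPKM
matrix; read alignment and FPKM estimation are upstream concerns and out of
scope. Coordinates are 0-based half-open internally; GTF I/O converts to and
from the format's 1-based inclusive convention. A gene's span is the min/max
over its exons, and the gap between two genes is the number of bases strictly
between their spans — overlapping or abutting genes have gap 0, so antisense
partners (overlapping, opposite strands) count as distance-0 neighbors. All
overlap and distance logic is deliberately strand-agnostic: antisense
lncRNA/mRNA pairs are first-class objects in this analysis, and a
per-strand overlap rule would silently discard them. When a secondary
noncoding model set is merged into a primary annotation, a secondary gene is
kept only if its span overlaps no primary gene span by ≥ 1 bp (half-open:
abutment is not overlap). Biotype classification maps `protein_coding` to
the coding class, the small structural RNA biotypes
(t/r/sn/sno/mi/misc-RNA) to a small-RNA class excluded from lncRNA analyses,
and everything else — including secondary models that carry no biotype — to
the lncRNA class.

## Statistical procedures

**Expressed-gene filter.** A gene is expressed if its replicate-averaged
FPKM exceeds the threshold (default 1) at any age. The average is taken
first because every other per-age quantity in the pipeline is a replicate
mean; the comparison is strict (`>`), matching the threshold's definition.

**Differential expression.** One-way fixed-effects ANOVA with age as the
factor, computed on log₂(FPKM+1). The log transform stabilizes the strongly
multiplicative FPKM noise; the pseudocount keeps zeros finite and damps
low-abundance noise. Degenerate genes whose values are all identical get
F = 0, p = 1 by convention rather than NaN. BH adjustment is applied over
all genes in the input matrix (not only expressed genes); the significance
call additionally requires overall mean FPKM > 1 and a max/min age-mean
fold change > 1.5 computed with pseudocount 1, so zero-mean ages cannot
produce infinite fold changes. The omnibus ANOVA p (not per-age-pair
t-tests) feeds the BH step; with two groups the F statistic reduces to the
squared pooled t statistic, which the tests exploit as an oracle.

**Pattern clustering.** Differentially expressed genes are represented by
per-age z-scores of log₂(mean FPKM+1) (population SD; constant profiles map
to zero vectors and are excluded from the tree, reported as `other`).
Agglomerative clustering uses Pearson-correlation distance (1 − r) with
average linkage, cut by cluster count (k = 3 by default) rather than
height. Genes are canonically sorted by id before linkage so assignments do
not depend on input order. Each of the three largest clusters is labeled by
the stage window containing its centroid's peak age: perinatal {−2, 0}
(mapped to the neonatal label), neonatal {1, 3, 5, 10}, adolescent
{15, 20, 25, 30}, adult {45, 60}. Day 30 sits on a boundary between
adolescence and young adulthood in correlation structure; it defaults to
adolescent and the windows are configurable. With k > 3, clusters beyond
the three largest are labeled `other`.

**Inter-age similarity.** Pearson r between the age-mean vectors of two
ages over a gene subset, on log₂(FPKM+1); the log keeps a handful of very
abundant genes from dominating the correlation. A zero-variance age vector
is an error naming the age.

**Neighbor pairs.** Each anchor (every coding gene for PC-PC, every
annotated lncRNA for PC-NC — not only expressed ones) is paired with the
same-chromosome coding gene minimizing the span gap; ties break by smaller
start then gene id, and anchors on chromosomes without another coding gene
are dropped. The hi tier keeps pairs with gap < 10 kb where the lncRNA
(PC-NC) or at least one member (PC-PC) is expressed. Pair correlation is
the Pearson r of the two genes' log₂(mean FPKM+1) profiles across the
ordered ages; pairs with a constant profile get undefined r and are counted
rather than imputed. The null is 10,000 uniform random unordered pairs of
annotated coding genes from a seeded RNG (members of a pair distinct; pairs
may recur across draws). Correlation histograms use 0.1-wide bins on
[−1, 1]; the reported peak is the modal bin's midpoint, with ties resolved
toward 0.

**Concordant cis candidates.** PC-NC hi-tier pairs whose lncRNA passes the
adjusted-p < 0.05 gate, whose gap is < 10 kb, and whose two genes share the
same major pattern label. "Same developmental pattern" is operationalized
as identical cluster label; a partner without a label (not differentially
expressed) cannot be concordant.

**Enrichment.** One-sided hypergeometric upper-tail p for each term with at
least one hit in the query set, BH over the tested terms. The term map is a
flat two-column table; ontology structure and term propagation are out of
scope, which keeps the test exact and lets synthetic vocabularies drive the
tests.

## The synthetic-data generator

`ontomap.simulate` emulates a postnatal-maturation study design: 12 ages (days −2,
0, 1, 3, 5, 10, 15, 20, 25, 30, 45, 60) × 3 replicates, coding genes and
lncRNAs with a ~10-fold abundance gap (lognormal baselines, lncRNA scale
0.1× the coding median of 20 FPKM), three planted ontogenic classes plus
non-changing genes (default 45/11.25/18.75/25% — a 60/15/25 split of the
changing genes), and planted cis-coupled PC-NC pairs within 10 kb (default
100 pairs, coupling ρ = 0.8, ~30% placed as overlapping antisense, the rest
intergenic with gap ~ U(0, 10 kb)), plus discordant decoy pairs (same
placement, uncoupled, different pattern classes).

Mean curves are built on the log₂(FPKM+1) scale as baseline plus amplitude ×
standardized shape, the amplitude chosen per class so the max/min FPKM
ratio equals the configured fold change (default 4). Shapes are a Gaussian
bump over age rank peaking at day 3 (neonatal), 20 (adolescent) or 60
(adult), z-scored, plus per-gene jitter (τ = 0.3, giving within-class
profile correlations around 0.9). A cis partner's shape mixes the anchor's
shape at weight ρ with independent jitter at weight √(1−ρ²), so the
expected profile correlation of a planted pair is ρ; at ρ = 1 with zero
noise the pair correlation is exactly 1. Replicate values are the age mean
times lognormal noise with unit mean and configured CV (default 0.2).
Planted-pair units are placed with flanking clearance greater than the cis
gap window so the partner really is the anchor's nearest coding neighbor.
Ground truth (per-gene class, pattern, baseline, true per-age means; per-pair
coupling and gap) is always emitted, and outputs are byte-identical under a
fixed seed.

Two generator switches support specific study designs: `lncrna_cv_scale`
inflates lncRNA replicate noise (used to demonstrate the weaker inter-age
similarity of lncRNAs), and `lncrna_clearance` keeps uncoupled lncRNAs at
least a given distance from coding genes (used in the planted-recovery
study so that the hi-tier PC-NC set is exactly the planted pairs, i.e. cis
coupling is restricted to the hi tier). Both default to neutral values.

What the generator does **not** emulate: a continuum of trajectory shapes
(real data has one; the generator draws from three archetypes plus jitter,
so random same-class pairs correlate near 0.9 and the null's modal bin can
reflect class co-membership — medians are the robust cross-class summary),
count-level sampling noise, library-size effects, isoforms, and any
chromosome-level clustering of classes. Passing tests therefore demonstrate
the pipeline's correctness and calibration under a known generative model,
not biological conclusions about real tissues.

## Canned experiments and problem sizes

`ontomap.experiments` defines the three validation studies the acceptance
script and tests share, at desk scale:

* **Null calibration** — 2,000 non-changing genes (1,000 coding + 1,000
  lncRNA), CV 0.2: fraction of raw ANOVA p < 0.05 (should be 0.05 within
  3 binomial SE) and the mean r of 10,000 random coding pairs (should be 0
  within ±0.03).
* **Null pair comparison** — 20 independent denser pure-null genomes
  (3,500 + 3,500 genes, spacing U(1, 15) kb so that ≥ 1,000 uncoupled
  hi-tier PC-NC pairs exist): two-sample KS test of hi-tier PC-NC r against
  1,000 random pairs; the median KS p across seeds should be well above
  0.01 since the two distributions are identical by construction.
* **Planted recovery** — the default study (2,000 coding + 1,000 lncRNA +
  50 small RNAs, CV 0.1, fold change 4, 100 cis pairs at ρ = 0.8, 50
  decoys, uncoupled lncRNAs isolated > 10 kb from coding genes): DE
  sensitivity and flat-gene false-call rate, pattern-label accuracy,
  concordant-pair sensitivity and decoy rejection, and the separation of
  median hi-tier PC-NC vs PC-PC correlation.

DE sensitivity is measured among planted changing genes whose true
(noise-free) curves pass the abundance and fold-change gates: the mean-FPKM
floor excludes low-abundance lncRNAs *by design*, and conditioning on the
gates separates the test's statistical power from that intended filter.
Pattern accuracy is measured on DE-called planted changing genes, since
only called genes are clustered.

## Numerical choices and edge cases

* Population SD in z-scores; constant rows → zero vectors, not NaN.
* ANOVA degenerate rows (all values identical) → (F, p) = (0, 1); zero
  within-group variance with real between-group differences → p = 0.
* Fold-change pseudocount 1 (configurable) tames zero age means.
* Histogram peak ties resolve toward the bin midpoint closest to 0
  (then the negative one), making the peak deterministic.
* Nearest-neighbor ties break by (gap, start, gene id).
* Undefined correlations (constant profiles) are excluded and counted.
* All RNG use goes through seeded `numpy` generators; the pipeline, the
  generator, and the acceptance script are deterministic given their seeds.

## Known limitations

* The ANOVA assumes homoscedastic within-age noise on the log scale; the
  generator satisfies this, real data only approximately.
* The concordance rule requires identical cluster labels, so it inherits
  any instability of the k = 3 cut; label-free alternatives (e.g. direct
  profile-correlation thresholds) are not implemented.
* Enrichment ignores term dependency structure (no ontology DAG).
* Pair analysis considers only the nearest coding neighbor; second-nearest
  or bidirectional-promoter geometries are not modeled.
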