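# Methods

`rumennet` implements an integrative co-association analysis for cattle
feed-efficiency studies: liver gene expression, rumen microbial taxa, rumen
volatile fatty acid (VFA) concentrations and three production phenotypes —
dry matter intake (DMI, kg DM/day), residual feed intake (RFI, kg DM/day) and
average daily gain (ADG, kg/day) — are assembled into one node set, edges are
inferred with the PCIT partial-correlation filter, and the phenotype
neighbourhoods are interrogated with stepwise regression, correlation tables
and hierarchical clustering. A synthetic-cohort generator with planted ground
truth makes every stage testable without animal data.

## The synthetic cohort

The generator emulates a two-breed (Charolais-like and Holstein-Friesian-like
starting weights of 485 and 401 kg), two-diet (high concentrate and zero-grazed
grass), High/Low-RFI factorial with `n_per_group` replicates per cell. The
observation unit is animal x diet phase; repeated measures on an animal are
treated as independent observations, matching how the downstream network pools
phases into a single correlation structure.

**Phenotypes.** Intake follows the residual-intake generating model

    DMI = b0 + b1*ADG + b2*MW + s*g + e,

with MW the mid-test metabolic weight (live weight^0.75, kg^0.75), g = +1 for
High-RFI and -1 for Low-RFI animals, and e Gaussian. Defaults: b0 = 0.5,
b1 = 1.2 kg DM per kg gain, b2 = 0.08 kg DM per kg^0.75, s = 0.8 kg DM/day and
noise SD 0.5 kg DM/day — producing daily intakes around 10 kg DM and a
High-minus-Low intake gap of ~1.6 kg DM/day, the magnitude a divergent-RFI
selection produces in growing steers. RFI itself is then *derived*, not drawn:
it is the within-breed least-squares residual of DMI on ADG and MW. By
construction it sums to zero and is exactly orthogonal to both regressors
inside each breed; the group shift survives into the residual because group is
not a regressor, so High-RFI animals have positive RFI.

**Gene counts.** Negative-binomial (gamma-Poisson) counts with log-normal
gene-wise baseline proportions, a shared dispersion (default 0.1, a typical
bulk RNA-seq value), and library sizes uniform on [1e6, 3e6]. A planted
differentially expressed gene multiplies its mean by 2^(lfc/2 * code) under
the +-1 contrast coding, so the realised between-group fold change is 2^lfc.
Defaults plant 30 genes per contrast at |log2FC| = 2 in disjoint index blocks.
Dispersion below 1e-12 degenerates to pure Poisson, which the tests use to
check the mean-variance limit.

**Microbiome.** Leaf taxa get log-normal abundances (log-scale noise SD 0.6);
a taxon linked to a phenotype adds effect x z(phenotype) to its log abundance
(default |effect| = 0.8 SD — a strong, recoverable association). Leaves are
closed to the unit simplex per sample; internal taxonomy rows (genus up to
phylum, pairwise-nested) are exact sums of their leaf descendants. This single
mechanism yields the clade co-clustering seen in real multi-rank taxon panels:
parent and child rows are mechanically correlated. Defaults use 30 leaves +
30 internal rows = 60 taxa rows.

**VFAs.** The 13 variables are the six component acids (acetic, propionic,
isobutyric, butyric, isovaleric, valeric), total short-chain fatty acids, the
acetic:propionic ratio, D-, L-, DL- and g-lactic acid, and ammonia. Each
measured variable is baseline x (0.5 + 5 x sum of its producer-taxon
abundances) plus Gaussian noise proportional to baseline, truncated at zero;
baselines are rumen-typical concentrations (acetic 60, propionic 22 mmol/L,
...). The three derived variables are computed last, so total SCFA = sum of
the six acids, ratio = acetic/propionic and DL = D + L hold exactly whatever
the noise did. A zero propionic draw (ratio undefined) is redrawn by default
or raised as an error by configuration.

**What the generator does not emulate:** sequencing reads or amplicon error,
count zero-inflation beyond what the NB gives, phylogenetically structured
effect sharing beyond the clade sums, diet- or breed-specific microbiome
shifts, and within-animal correlation across diet phases. Passing recovery
tests therefore show the pipeline recovers planted linear-association signal
at realistic noise — not that it would survive every pathology of real 16S
data.

## Expression preparation

Counts are normalised to counts per million (CPM); a gene is "expressed" if it
has >= 1 CPM in at least ceil(n/2) samples. Differential expression for the
three contrasts is one OLS per gene on log2(CPM + 0.5) with RFI group, breed
and diet as additive +-1-coded factors, so each contrast is tested adjusted
for the other two. The 0.5 pseudocount keeps zeros finite and is standard for
log-scale expression. We deliberately use a Gaussian working model rather than
a count GLM: at the package's acceptance surface what matters is the ranking
of genes and the exact selection arithmetic, and the OLS t-statistics deliver
both with far less machinery. Raw p-values come from the t distribution with
n - 4 df; Benjamini-Hochberg adjustment is applied within contrast
(statsmodels). A gene constant across samples gets statistic 0 and p = 1.

The per-contrast network gene list is the top 5% of expressed genes by
adjusted p, with size floor(0.05 x n) — floor is the only rule consistent
with selecting 608 of 12,161, 605 of 12,114 and 629 of 12,581. Ties break by
adjusted p, then raw p, then gene id, making the cut a total order.

## Microbiome preparation

Taxa are closed to relative abundance per sample and transformed with
log10(x + 1e-6) by default; the 1e-6 pseudocount maps a true zero to -6,
below any observable abundance. A centred log-ratio (CLR) transform is
available by configuration for compositionality-aware runs; CLR input that is
not on the simplex is closed first (with a warning). VFA concentrations enter
the network untransformed — they are continuous, roughly symmetric
concentrations at this scale. Prevalence filtering is off by default and
available as a knob. All tables are then aligned to their shared sample ids
in sorted order; alignment is idempotent and column-order invariant and
reports what each table dropped.

## Network inference (PCIT)

Node profiles are: log2(CPM + 0.5) for the selected genes, transformed
abundances for all taxa rows, raw VFA concentrations, and the DMI/RFI/ADG
vectors. Pearson correlations over the aligned samples (n >= 4 required) form
the input matrix; constant profiles are dropped with a warning before
filtering rather than propagating undefined correlations.

For every trio (x, y, z) the three first-order partial correlations are

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))   (cyclic),

and the trio tolerance is eps = mean of the ratios partial/direct. Ratios
whose direct correlation magnitude falls below delta = 1e-8 are excluded from
the average (the ratio is numerically meaningless there); if all three are
excluded eps = 1, which keeps the elimination test conservative in the
degenerate all-zero trio. The edge (x, y) is eliminated if for at least one z

    |r_xy| <= |eps * r_xz|  and  |r_xy| <= |eps * r_yz|.

A partial-correlation denominator of zero (|r| = 1 among the conditioning
pair) sets that partial to 0 rather than dividing. Two implementations are
shipped: a plain triple loop over trios (the reference) and a vectorised pass
over conditioning nodes; the suite asserts edge-set equality between them on
random instances up to 40 nodes.

A useful closed form for intuition: on an exact chain r_xy = r_yz = r,
r_xz = r^2 (the conditional-independence signature), the mediated x-z edge is
eliminated iff r <= 1/sqrt(3) ~ 0.577. Strong chains keep all three edges —
the tolerance, averaged over a ratio that is exactly zero for the mediated
edge, cannot reach the level needed to dominate a correlation as large as
r^2. This is a property of the rule itself, not of either implementation.

Surviving edges carry their correlation and sign; the final network keeps
those whose correlation t-test (t = r * sqrt(n-2)/sqrt(1-r^2), two-sided,
n - 2 df) has p < alpha (default 0.05). |r| = 1 edges get p = 0 and a
`saturated` flag; alpha = 1 retains every survivor.

## Neighbourhood analyses

A phenotype's first neighbours are the nodes sharing a surviving significant
edge with it. Summaries report per-type counts, percentages (half-up rounding
at 1 decimal by default, 2 by option — computation is always full precision,
only formatting varies), the share of connected network nodes, and the share
of surviving edges. "Direct connections" are defined as the incident edges of
the phenotype node, which in a simple graph equals the neighbour count. The
three-way neighbourhood comparison enumerates all seven disjoint Venn
regions. Networks export as SIF (`a <sign> b`), GraphML with node-type,
provenance, rank/lineage and edge-weight attributes, or a plain edge TSV that
round-trips losslessly.

## Stepwise regression, correlation table, clustering

Stepwise variance attribution is greedy forward selection on R^2: candidates
are the microbes connected to any phenotype; at each step the candidate
maximising the cumulative OLS R^2 (with intercept) enters, until the target
(default 0.90) is reached, no candidate improves R^2 by more than 1e-6, or
adding one more predictor would exhaust the residual degrees of freedom. Ties
break by candidate label, so the path is invariant to candidate order. On
orthogonal predictors this reproduces the exact greedy order of individual
variance shares.

The correlation table reports Pearson r and the same two-sided t-test per
(phenotype, taxon) pair, flagged at alpha; its decisions coincide with the
edge significance filter at equal r, n and alpha, which the suite checks
cross-module. Constant taxa yield flagged-undefined cells.

Clustering is agglomerative (scipy) on the 1 - r distance with average
linkage by default (complete available). The leaf order is canonicalised —
at every merge the smaller subtree comes first, ties broken by the smallest
contained label — so results are reproducible and invariant to input row
order up to dendrogram reflection. Constant rows are dropped with a warning.

## Problem sizes and determinism

The default study conditions are 80 observations (10 per breed x diet x RFI
group cell), 2,000 genes and 60 taxa rows; at these sizes the full pipeline
runs in a few seconds and the planted DE genes and phenotype-linked taxa are
recovered essentially completely (the test suite requires >= 80% planted-DE
recall per contrast and >= 50% planted-taxon neighbourhood recall). All
randomness flows from a single integer seed through named child streams, so
every simulate_* output and the end-to-end JSON run report are bit-identical
across runs with the same configuration.

## Known limitations

- The DE model is a Gaussian working model on log CPM; exact count-GLM
  shrinkage behaviour (e.g. for very low counts) is out of scope.
- PCIT keeps strongly mediated edges (see the closed form above); it is a
  heuristic edge filter, not a consistent structure-learning estimator.
- Correlation-based edges pool breeds, diets and RFI groups; group-level
  mean shifts can induce edges that are between-group rather than
  within-group associations, exactly as in real pooled-network studies.
- The stepwise path is greedy; it neither guarantees the best subset of its
  size nor provides valid post-selection inference on the entered taxa.
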