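# Methods

## The analysis model

The package tests whether cases carry more qualifying variants (QVs) than
controls, gene by gene and over gene sets, while controlling for genetic
ancestry by exact stratification rather than covariate adjustment.

A QV model is a pair of filters: a consequence-class set and frequency
bounds. Frequency comparisons use strict `<` ("less than 0.1%"), and
"absent from external references" means exactly `external_present =
False`, regardless of how a zero frequency was rounded. The built-in
models are ultrarare LOF (absent externally), flex LOF (external MAF
< 0.1%), and their synonymous counterparts (the negative control). The
flex model also bounds the internal MAF at 0.1%, computed over the
combined case+control cohort before collapsing — standard collapsing
practice where the internal filter is otherwise unspecified. Internal
allele frequency is carrier count / (2 × analyzed samples), i.e. at most
one qualifying allele per individual per gene is assumed; the binary
collapsed indicator is insensitive to this convention.

Collapsing assigns individual *i* the indicator 1 for gene *g* when *i*
carries ≥ 1 QV in *g*. All downstream statistics consume only these
indicators.

### Stratified tests

Per stratum (ancestry cluster) *k*, the 2×2 table is (aₖ = case carriers,
bₖ, cₖ, dₖ). Estimation and testing are deliberately separated:

* **Effect size**: Mantel–Haenszel pooled OR with a Wald interval on the
  log scale using the Robins–Breslow–Greenland variance. A zero MH
  denominator yields an infinite OR with undefined CI, flagged rather
  than patched.
* **Significance**: the exact conditional CMH test. Under the common-OR=1
  null, each stratum's aₖ is central hypergeometric given its margins, so
  S = Σ aₖ has the convolution law, computed by dynamic-programming
  convolution of the per-stratum pmfs. This is exact at any stratum count
  and fast at cohort scale (support sizes are bounded by carrier counts).
  The two-sided p is the doubled smaller tail, capped at 1 — the common
  "exact two-sided CMH" convention; the point-probability alternative for
  the single-table Fisher test is used where a pooled-table Fisher test
  is requested (scipy's convention). No continuity corrections anywhere;
  strata with a zero margin are dropped from both estimation and testing
  because they carry no information about the odds ratio.
* The asymptotic CMH chi-square (1 df, no continuity correction) backs
  the vectorised paths (per-gene diagnostics, permutation loops); it is
  cross-checked against statsmodels and against the exact test in the
  suite.

The Fisher CI is the conditional exact (Cornfield) interval, while the
reported point estimate is the sample OR ad/bc — the estimate users of
forest-plot style reports expect.

### The intolerance scan

Thresholds are the unique LOEUF values among QV-harbouring genes; the set
at *t* is every such gene with LOEUF ≤ *t*. Because sets are nested, an
individual's carrier state along the scan flips 0→1 exactly once — at the
first threshold whose added genes it carries — so per-threshold carrier
counts are cumulative histograms of per-individual flip indices. One
permutation therefore costs O(individuals + thresholds), not
O(individuals × thresholds).

Permutations shuffle case/control labels **within** clusters, preserving
every cluster's margins and hence the stratification; one shuffle yields
the whole p-vector, preserving the scan's dependence structure across
thresholds. The empirical p at *t* is (1 + #{p_perm ≤ p_obs}) / (n_perm +
1) (the add-one estimator; r/n available as `estimator="plugin"`).
Because within-cluster shuffling fixes the margins, the per-threshold
expectation and variance of the CMH statistic are permutation-invariant,
and ranking permuted p-values is identical to ranking the chi-square
statistics — the permutation loop therefore uses the asymptotic statistic
by default and never evaluates a tail probability inside the loop;
`statistic="exact"` switches both the observed and permuted values to the
exact test for small problems. Nominal and empirical p-values always come
from the same statistic.

**Optimum and significance.** The optimum is the threshold attaining the
minimum empirical p. A strong signal pins the empirical p at its floor
1/(n_perm+1) across a long run of thresholds, so ties are broken by the
nominal p (the quantity the permutations rank) and only then by the
smallest threshold; with a pure smallest-threshold rule the reported
optimum would systematically be the left edge of the floor plateau rather
than anything near the true boundary. Bonferroni correction uses the
number of unique thresholds. When the permutation count makes the
Bonferroni bar unattainable from the empirical p (floor > α/m — e.g.
1000 permutations against ~10³ thresholds), significance falls back to
the nominal CMH p with a warning; at very large permutation counts the
two coincide in practice.

### Gene-set batteries and candidates

Intolerant genes (LOEUF ≤ 0.680 by default — the scan optimum reported
for the motivating cohort) are partitioned by the disease-association
flag; variants by ultrarare vs rare-but-present status (disjoint, with
union the all-rare model). The default battery crosses the two gene
partitions with the three variant partitions under one test kind (exact
CMH, or pooled-table Fisher for small cohorts), and Benjamini–Hochberg
adjusts across the battery; the exact roster is config-driven because
published batteries vary in composition. Cells with no carriers anywhere
(including empty gene partitions) are flagged and excluded from the FDR
family. Case-only candidates are genes in the no-known-association
intolerant set with ≥ 1 case carrier and 0 control carriers, sorted by
case carrier count then gene id.

### De novo enrichment

Expected counts use the two-copies-per-trio convention: E = 2 × n_trios ×
Σ μ_{g,class}, rates being per-chromosome per-generation probabilities
(rate tables expressed per individual can absorb the factor into the
rates). Composite classes sum their parts. The test is the upper-tail
Poisson probability P(X ≥ observed) only — the enrichment direction,
matching trio-study convention; depletion is visible in the ratio but not
tested. Degenerate inputs: expected 0 with observed 0 gives p = 1 and an
undefined ratio; expected 0 with observed > 0 is flagged with p = 0.

### Ancestry clusters

PCA (mean-centred, full SVD, components by decreasing explained variance;
6 components by default) on common variants (internal MAF ≥ 5% when no
predefined list is supplied) followed by Louvain community detection on a
symmetric k-nearest-neighbour graph (k = 20, unit weights) of the
coordinates. Louvain's node order is fixed by a seed. Louvain tends to
subdivide large communities; sub-clusters of a homogeneous population are
harmless for stratified tests (the strata remain internally homogeneous),
and clusters lacking a case or a control are dropped before testing. The
genomic-inflation factor λ — median χ²₁ quantile of the per-gene p-values
over 0.4549 — on the ultrarare synonymous model is the pipeline's
negative control; the pipeline warns above 1.2.

## The synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, at the
gene level: carrier status per (gene, individual) is Bernoulli, because
every downstream computation consumes the collapsed indicator. A
variant-level emitter (one singleton site per carried gene and
individual, ALT allele count 1) exists for I/O round trips. Defaults are
the emulated study conditions:

| parameter | default | why |
|---|---|---|
| n_cases / n_controls | 231 / 5322 | the combined cohort scale |
| n_clusters, mixture | 3; (0.40, 0.35, 0.25) | three ancestry clusters of unequal size |
| n_genes | 2000 | desk-scale panel; scan granularity ~10³ unique scores |
| LOEUF | Uniform(0.03, 2.0), 3 decimals | observed score range and printed precision (shared values collapse thresholds, as in real panels) |
| baseline carrier rate | (3.2, 4.0, 4.8) ×10⁻⁴ per gene | anchored to ~24% of controls carrying rare LOF across the ~650 genes under the 0.68 cap; distinct per cluster so the ancestry confound is real |
| enrichment | OR 2.0 on the odds scale, genes with LOEUF ≤ 0.68 | effect confined below an intolerance boundary; odds-scale so the configured value is comparable to reported ORs |
| ultrarare fraction | 0.6 | most rare LOF carriers are absent from references |
| synonymous multiplier | 5× | synonymous ultrarare carriers are severalfold more common than LOF (more sites, weaker selection) |
| de novo rates | gamma(shape 2) around class means (0.74, 1.6, 0.22) ×10⁻⁵ | class sums chosen so ~114 trios expect ~23 synonymous, ~51 missense, ~7 LOF events in the no-disease gene universe |
| case_cluster_mixture | = cluster_mixture | set differently to confound phenotype with ancestry |

Dosages for the clustering stage follow a Balding–Nichols model
(default Fst 0.1). The generator does **not** model linkage
disequilibrium, site-frequency spectra, relatedness, per-variant
sequencing error, or gene length variation; passing tests demonstrate the
statistical machinery is correct under the assumed carrier process, not
that any real cohort satisfies those assumptions.

## Numerical and design notes

* All randomness flows from a single seed through named substreams per
  stage (CRC-keyed `numpy` Generators), so stages are independently
  reproducible and bit-identical under a fixed seed.
* The exact CMH convolution clips sub-machine-epsilon negatives from
  `np.convolve` and never reports a p below the point probability of the
  observed S.
* Empirical p-values are conservative in small cohorts where the discrete
  statistic ties often (the add-one estimator counts ties as hits); the
  calibration suite uses cohort sizes where ties are rare.
* λ on per-gene tests needs moderate carrier counts to be interpretable;
  at a handful of carriers per gene the median statistic is dominated by
  discreteness and λ fluctuates widely on small panels.
* Threshold-scan localisation: the optimum's position around a true
  enrichment boundary has jitter of tens of genes (argmax of a drifting
  random walk scales as (noise/drift)² per gene, with drift/noise set by
  the case fraction and OR, not the carrier rate). At desk scale the scan
  reliably detects the enrichment and brackets the boundary to within a
  few hundredths of LOEUF, but recovery to a handful of grid steps at
  3-decimal granularity is not achievable; raising carrier rates worsens
  it through saturation bias.
* Problem sizes in the test and acceptance suites (e.g. 300/3000 × 2000
  genes × 1000 permutations; 100-replicate null suites at 500
  permutations) are the package's desk-scale study conditions; the
  flip-index permutation engine makes each scan replicate roughly a
  second of work.

## Known limitations

Genotype-quality/coverage-based QV criteria, consequence annotation,
liftover, multi-allelic normalisation, admixture estimation and
geographic-ancestry labelling of clusters are out of scope; gene lists
and disease flags are consumed as inputs. Conditional-ML odds ratios and
mid-p exact variants are documented future options. The headline
real-data results of the motivating study (its LOEUF optimum 0.680 and
battery ORs) are documentation context only — the underlying exomes are
not deposited, so they are not reproduction targets.
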