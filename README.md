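# rvburden

Ancestry-stratified rare-variant collapsing burden analysis for
case-control cohorts, built around the design used to study critically ill
children without a genetic diagnosis: qualifying-variant (QV) collapsing,
exact stratified association tests, an intolerance-threshold scan over
LOEUF-defined gene sets with permutation empirical p-values, gene-set
enrichment batteries with FDR control, and Poisson de novo enrichment for
trio cohorts. A first-class synthetic-cohort generator reproduces the
statistical structure these analyses assume, so every stage is testable
end to end without access to protected exome data.

## Who this is for

Statistical geneticists running gene-level collapsing analyses on
case-control exome cohorts — situations where individually rare variants
are aggregated per gene into 0/1 carrier indicators and carrier
proportions are compared between cases and controls within ancestry
strata.

## The methods

**Collapsing.** A QV model selects variants by consequence class and
frequency: the *ultrarare* LOF model keeps loss-of-function variants absent
from external population references; the *flex* LOF model admits external
minor allele frequency < 0.1%. Individual *i* gets indicator 1 for gene
*g* if it carries ≥ 1 QV in *g*, giving a gene × individual matrix per
ancestry cluster (clusters from PCA on common variants + Louvain
communities on a kNN graph of the first 6 PCs).

**Stratified testing.** For a gene or gene set, each cluster *k*
contributes a 2×2 table (aₖ, bₖ; cₖ, dₖ) of case/control ×
carrier/non-carrier counts. The pooled effect is the Mantel–Haenszel odds
ratio

    OR_MH = Σₖ (aₖ dₖ / nₖ) / Σₖ (bₖ cₖ / nₖ)

with a Robins–Breslow–Greenland Wald interval; significance is the exact
conditional CMH test: S = Σₖ aₖ against the convolution of per-stratum
central hypergeometric laws given the margins, doubled smaller tail.

**Intolerance scan.** Genes harbouring QVs are ordered by LOEUF; every
unique score t defines the cumulative set {g : LOEUF(g) ≤ t}. Each set is
tested by CMH; empirical p-values come from case/control label
permutations *within* clusters (one shuffle yields the whole p-vector);
Bonferroni correction uses the number of unique thresholds; the optimum is
the threshold with the smallest empirical p. A synonymous-model analysis
serves as the negative control, summarised by the genomic-inflation factor
λ = median(χ²₁-quantile of p) / 0.4549.

**De novo enrichment.** With per-gene per-class mutation rates μ, the
expected count in a gene universe over n trios is 2 · n · Σ μ; observed
counts get an upper-tail Poisson p and an observed/expected enrichment
ratio.

## Worked example

```bash
rvburden run-all --seed 1 --out-dir demo --n-permutations 500
```

simulates a cohort of 231 cases and 5322 controls across three ancestry
clusters (2000 genes, enrichment OR 2 confined to LOEUF ≤ 0.68), clusters
it, collapses, scans, runs the batteries and the de novo test, and logs:

```
INFO rvburden: analyzed 5553 samples in 6 clusters
INFO rvburden: 1772 genes with >= 1 qualifying variant (flex LOF)
INFO rvburden: synonymous-control genomic inflation lambda = 1.064
INFO rvburden: scan: 1178 thresholds, 500 permutations; optimum LOEUF <= 0.583 (empirical p 0.002, significant)
INFO rvburden: intolerance cap 0.68: 168 disease-associated, 488 no-known-association
```

Louvain splits the three simulated populations into six strata (it tends
to subdivide large communities; stratifying on sub-clusters is harmless).
The scan's empirical p hits the permutation floor (0.002 at 500 shuffles)
over a run of thresholds around the injected boundary, and the reported
optimum — the strongest nominal p on that plateau — lands at LOEUF 0.583,
inside the enriched region below 0.68. λ ≈ 1 on the synonymous control
indicates the stratification absorbs the simulated ancestry structure
(each cluster has a different background carrier rate). `demo/` then
holds `scan.tsv`, `burden_battery.tsv`,
`case_only_candidates.tsv`, `denovo.tsv`, the carrier matrices and a scan
plot. The same stages run individually (`rvburden simulate / cluster /
collapse / scan / battery / denovo`) on TSV/VCF inputs.

As a library:

```python
import rvburden as rv

cfg = rv.SimulationConfig(seed=1)
panel = rv.simulate_gene_panel(cfg)
cohort = rv.simulate_cohort(cfg, panel)
matrix = rv.matrix_from_arrays(cohort.genes, cohort.samples, cohort.X_all)
scan = rv.run_scan(matrix, panel, n_permutations=500, seed=1)
print(rv.optimal_threshold(scan))   # (0.583, 0.001996..., True)
```

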