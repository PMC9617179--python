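"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a case-control exome collapsing study of critically
ill children (hundreds of cases, thousands of controls) with:

* several ancestry clusters with cluster-specific background carrier rates
  (so confounding by ancestry is real and stratification is testable);
* per-gene rare-LOF carrier indicators whose case enrichment, on the odds
  scale, is confined to genes at or below a LOEUF intolerance threshold;
* ultrarare (absent from external references) vs rare-but-present status
  per carried gene;
* per-trio de novo counts per consequence class driven by per-gene
  mutation rates.

Carrier status is simulated directly at the gene level as a Bernoulli
indicator, because every downstream computation consumes the collapsed 0/1
state; :func:`emit_variants` provides a thin variant-level view (one
synthetic site per gene and frequency class) for I/O round-trip tests.

Defaults mirror the study scale: 231 cases vs 5322 controls across three
ancestry clusters, a panel of 2000 genes, enrichment odds ratio 2 confined
to LOEUF <= 0.68. Mean per-gene mutation rates are set so that ~114 trios
yield expected de novo counts of the magnitude seen in cohort studies
(a few LOF, tens of missense events).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import VariantRecord

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "SimulatedCohort",
    "simulate_gene_panel",
    "simulate_cohort",
    "simulate_null_carrier_matrix",
    "simulate_dosage_matrix",
    "simulate_trio_denovo_counts",
    "simulate_denovo_calls",
    "emit_variants",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    n_cases: int = 231
    n_controls: int = 5322
    n_clusters: int = 3
    #: proportion of the cohort in each cluster (must sum to 1)
    cluster_mixture: tuple = (0.40, 0.35, 0.25)
    #: case share of each cluster; defaults to cluster_mixture (no
    #: confounding); distinct values confound phenotype with ancestry
    case_cluster_mixture: tuple | None = None
    n_genes: int = 2000
    loeuf_range: tuple = (0.03, 2.0)
    disease_flag_prob: float = 0.25
    #: per-gene per-individual rare-LOF carrier probability, one value per
    #: cluster; distinct values make the ancestry confound testable. The
    #: magnitude is anchored so the cumulative carrier fraction at the
    #: intolerance cap matches cohort-scale collapsing studies (roughly a
    #: quarter of controls carrying at LOEUF <= 0.68 over ~650 such genes).
    baseline_carrier_rate: tuple = (3.2e-4, 4.0e-4, 4.8e-4)
    #: ultrarare synonymous carriers are severalfold more common per gene
    #: than rare LOF carriers (more sites, weaker selection); multiplier
    #: applied to the baselines for the synonymous negative control
    synonymous_rate_multiplier: float = 5.0
    #: odds multiplier applied to case carrier odds in enriched genes
    enrichment_or: float = 2.0
    #: enrichment applies to genes with LOEUF <= this threshold
    enrichment_loeuf_max: float = 0.68
    #: probability a carried gene's qualifying variant is absent from
    #: external reference datasets
    ultrarare_fraction: float = 0.6
    n_trios: int = 114
    #: mean per-gene per-class de novo mutation probability
    #: (per chromosome per generation)
    mean_mutation_rates: tuple = (
        ("synonymous", 7.4e-6), ("missense", 1.6e-5), ("LOF", 2.2e-6),
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("n_cases and n_controls must be >= 0")
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if len(self.cluster_mixture) != self.n_clusters:
            raise ConfigurationError(
                "cluster_mixture must have one proportion per cluster"
            )
        if abs(sum(self.cluster_mixture) - 1.0) > 1e-9:
            raise ConfigurationError("cluster_mixture must sum to 1")
        if any(p < 0 for p in self.cluster_mixture):
            raise ConfigurationError("cluster_mixture proportions must be >= 0")
        if self.case_cluster_mixture is not None:
            if len(self.case_cluster_mixture) != self.n_clusters:
                raise ConfigurationError(
                    "case_cluster_mixture must have one proportion per cluster"
                )
            if abs(sum(self.case_cluster_mixture) - 1.0) > 1e-9:
                raise ConfigurationError("case_cluster_mixture must sum to 1")
            if any(p < 0 for p in self.case_cluster_mixture):
                raise ConfigurationError(
                    "case_cluster_mixture proportions must be >= 0"
                )
        if self.synonymous_rate_multiplier <= 0:
            raise ConfigurationError("synonymous_rate_multiplier must be > 0")
        lo, hi = self.loeuf_range
        if not (0 < lo < hi):
            raise ConfigurationError("loeuf_range lower bound must be > 0 and < upper")
        rates = self.rates_per_cluster()
        if any(not 0 <= r <= 1 for r in rates):
            raise ConfigurationError("baseline_carrier_rate values must be in [0, 1]")
        for name in ("disease_flag_prob", "ultrarare_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.enrichment_or < 1:
            raise ConfigurationError("enrichment_or must be >= 1")
        if self.n_trios < 0:
            raise ConfigurationError("n_trios must be >= 0")

    def rates_per_cluster(self) -> tuple:
        r = self.baseline_carrier_rate
        if np.isscalar(r):
            return (float(r),) * self.n_clusters
        if len(r) != self.n_clusters:
            raise ConfigurationError(
                "baseline_carrier_rate must be scalar or one value per cluster"
            )
        return tuple(float(x) for x in r)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CohortTruth:
    """Ground-truth labels for recovery tests."""

    true_threshold: float
    enriched_genes: frozenset
    cluster_labels: pd.Series = field(repr=False)
    case_labels: pd.Series = field(repr=False)


@dataclass
class SimulatedCohort:
    """Gene-level carrier indicators plus sample metadata and truth.

    ``X_all`` is the genes x individuals 0/1 matrix of rare qualifying
    variants; ``X_ultrarare`` and ``X_rare`` partition it by presence in
    external reference datasets (disjoint; union = ``X_all``).
    """

    genes: list
    samples: pd.DataFrame  # sample_id, phenotype, cluster
    X_all: np.ndarray
    X_ultrarare: np.ndarray
    X_rare: np.ndarray
    truth: CohortTruth


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # named substreams: same seed + stage name -> independent, reproducible
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng([config.seed, tag])


def simulate_gene_panel(config: SimulationConfig) -> pd.DataFrame:
    """Gene panel with LOEUF ~ Uniform(loeuf_range), a Bernoulli disease
    flag and per-class gamma-distributed mutation rates; deterministic
    under the config seed."""
    rng = _rng(config, "panel")
    n = config.n_genes
    lo, hi = config.loeuf_range
    # real LOEUF scores carry 3 decimals, so distinct genes share values
    panel = pd.DataFrame(
        {
            "gene": [f"GENE{i:05d}" for i in range(n)],
            "loeuf": np.round(rng.uniform(lo, hi, size=n), 3),
            "disease_associated": rng.random(n) < config.disease_flag_prob,
        }
    )
    # gamma(shape=2) around the class mean: right-skewed, strictly positive
    for cls, mean in config.mean_mutation_rates:
        col = {"synonymous": "mu_syn", "missense": "mu_mis", "LOF": "mu_lof"}[cls]
        panel[col] = rng.gamma(shape=2.0, scale=mean / 2.0, size=n)
    return panel


def simulate_cohort(config: SimulationConfig, panel: pd.DataFrame) -> SimulatedCohort:
    """Simulate cluster labels, phenotypes and gene-level carrier status.

    Controls carry gene g with the cluster baseline probability; cases have
    their carrier *odds* multiplied by ``enrichment_or`` in genes with
    LOEUF <= ``enrichment_loeuf_max``. Each carried (gene, individual) is
    tagged ultrarare with probability ``ultrarare_fraction``.
    """
    if len(panel) == 0:
        raise ConfigurationError("gene panel is empty")
    rng = _rng(config, "cohort")
    n = config.n_cases + config.n_controls
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True
    case_mix = config.case_cluster_mixture or config.cluster_mixture
    cluster = np.where(
        is_case,
        rng.choice(config.n_clusters, size=n, p=list(case_mix)),
        rng.choice(config.n_clusters, size=n, p=list(config.cluster_mixture)),
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "phenotype": np.where(is_case, "case", "control"),
            "cluster": cluster,
        }
    )
    loeuf = panel["loeuf"].to_numpy()
    enriched = loeuf <= config.enrichment_loeuf_max
    rates = np.asarray(config.rates_per_cluster())

    # genes x individuals carrier probability
    p = np.tile(rates[cluster], (len(panel), 1))
    if config.enrichment_or > 1:
        odds = p / (1 - p)
        odds[np.ix_(enriched, is_case)] *= config.enrichment_or
        p = odds / (1 + odds)
    X = (rng.random(p.shape) < p).astype(np.uint8)

    ur_tag = rng.random(X.shape) < config.ultrarare_fraction
    X_ur = (X.astype(bool) & ur_tag).astype(np.uint8)
    X_rare = (X.astype(bool) & ~ur_tag).astype(np.uint8)

    truth = CohortTruth(
        true_threshold=config.enrichment_loeuf_max,
        enriched_genes=frozenset(panel.loc[enriched, "gene"]),
        cluster_labels=pd.Series(cluster, index=samples["sample_id"], name="cluster"),
        case_labels=pd.Series(is_case, index=samples["sample_id"], name="is_case"),
    )
    return SimulatedCohort(panel["gene"].tolist(), samples, X, X_ur, X_rare, truth)


def simulate_null_carrier_matrix(
    config: SimulationConfig,
    samples: pd.DataFrame,
    n_genes: int | None = None,
    stream: str = "synonymous",
) -> np.ndarray:
    """Carrier indicators with the cluster baselines and *no* case
    enrichment — the synonymous negative-control process on the same
    individuals."""
    rng = _rng(config, stream)
    n_genes = config.n_genes if n_genes is None else n_genes
    rates = np.asarray(config.rates_per_cluster()) * config.synonymous_rate_multiplier
    np.clip(rates, 0.0, 1.0, out=rates)
    # cluster labels may come from inference and need not match n_clusters;
    # cycle the configured rates over the observed labels
    labels = samples["cluster"].to_numpy()
    codes = pd.factorize(labels, sort=True)[0]
    p = np.tile(rates[codes % len(rates)], (n_genes, 1))
    return (rng.random(p.shape) < p).astype(np.uint8)


def simulate_dosage_matrix(
    config: SimulationConfig,
    cluster_labels: np.ndarray,
    n_variants: int = 200,
    fst: float = 0.1,
) -> np.ndarray:
    """Common-variant genotype dosages (individuals x variants) with
    Balding-Nichols cluster differentiation, for the PCA + Louvain
    ancestry-clustering stage. Not a linkage-disequilibrium model."""
    rng = _rng(config, "dosage")
    cluster_labels = np.asarray(cluster_labels)
    p0 = rng.uniform(0.1, 0.9, size=n_variants)
    shape = (1 - fst) / fst
    pk = rng.beta(p0 * shape, (1 - p0) * shape,
                  size=(config.n_clusters, n_variants))
    probs = pk[cluster_labels]  # individuals x variants
    return rng.binomial(2, probs).astype(np.float64)


def simulate_trio_denovo_counts(
    config: SimulationConfig,
    panel: pd.DataFrame,
    geneset: set,
    fold: float = 1.0,
) -> dict:
    """Observed de novo counts per consequence class across trios.

    Per class, observed ~ Poisson(fold x 2 x n_trios x sum of per-gene
    rates over the gene set); fold is the simulated true enrichment."""
    if config.n_trios < 0:
        raise ConfigurationError("n_trios must be >= 0")
    missing = set(geneset) - set(panel["gene"])
    if missing:
        raise ValueError(f"no mutation rate for gene {sorted(missing)[0]!r}")
    rng = _rng(config, "denovo")
    sub = panel[panel["gene"].isin(geneset)]
    out = {}
    for cls, col in (("synonymous", "mu_syn"), ("missense", "mu_mis"), ("LOF", "mu_lof")):
        lam = fold * 2.0 * config.n_trios * float(sub[col].sum())
        out[cls] = int(rng.poisson(lam)) if lam > 0 else 0
    return out


def simulate_denovo_calls(
    config: SimulationConfig,
    panel: pd.DataFrame,
    geneset: set,
    fold: float = 1.0,
) -> pd.DataFrame:
    """Per-call de novo table (trio_id, gene, effect_class): class totals
    from :func:`simulate_trio_denovo_counts` distributed over genes in
    proportion to their mutation rates and over trios uniformly."""
    counts = simulate_trio_denovo_counts(config, panel, geneset, fold=fold)
    rng = _rng(config, "denovo-calls")
    sub = panel[panel["gene"].isin(geneset)]
    rows = []
    for cls, col in (("synonymous", "mu_syn"), ("missense", "mu_mis"), ("LOF", "mu_lof")):
        k = counts[cls]
        if k == 0:
            continue
        w = sub[col].to_numpy()
        w = w / w.sum() if w.sum() > 0 else np.full(len(sub), 1 / len(sub))
        genes = rng.choice(sub["gene"].to_numpy(), size=k, p=w)
        trios = rng.integers(0, max(config.n_trios, 1), size=k)
        rows += [
            {"trio_id": f"T{t:04d}", "gene": g, "effect_class": cls}
            for t, g in zip(trios, genes)
        ]
    return pd.DataFrame(rows, columns=["trio_id", "gene", "effect_class"])


def emit_variants(
    cohort: SimulatedCohort,
    effect_class: str = "LOF",
    rare_external_af: float = 5e-4,
) -> list[VariantRecord]:
    """Variant-level view of the carrier matrices for I/O round trips.

    One synthetic singleton site per carried (gene, individual): ALT
    allele count 1, so per-site internal frequencies stay below any rare
    bound. Ultrarare carriers get sites absent from external references;
    rare-but-present carriers get sites with external AF just under the
    0.1% bound. Positions are 1-based and unique per site.
    """
    ids = cohort.samples["sample_id"].to_numpy()
    n = len(ids)
    records = []
    pos = 0
    for gi, gene in enumerate(cohort.genes):
        for X, af in ((cohort.X_ultrarare, 0.0), (cohort.X_rare, rare_external_af)):
            for sid in ids[X[gi].astype(bool)]:
                pos += 1
                records.append(
                    VariantRecord(
                        chrom="1", pos=pos, ref="A", alt="T",
                        gene=gene, effect_class=effect_class,
                        external_af=af, external_present=af > 0,
                        internal_af=1 / (2 * n),
                        carriers=frozenset({sid}),
                    )
                )
    return records
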