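"""Intolerance-threshold scan: nested LOEUF gene sets, CMH per set,
permutation empirical p-values, Bonferroni significance, optimum.

Genes harbouring at least one qualifying variant are ordered from most to
least intolerant by LOEUF; every unique LOEUF value defines a cumulative
gene set {g : LOEUF(g) <= t}. Each set is collapsed to a stratified 2x2
table and tested with the Cochran-Mantel-Haenszel test. Empirical p-values
come from permutations of case/control labels *within* each ancestry
cluster (preserving every cluster's margins, hence the stratification);
one label shuffle yields the whole p-vector, so the scan's dependence
structure across thresholds is preserved. The Bonferroni family size is
the number of unique thresholds.

The incremental structure is exploited throughout: an individual's carrier
state along the scan flips 0 -> 1 at the first threshold whose added genes
it carries, so per-threshold carrier counts are cumulative histograms of
per-individual "flip indices" — the permutation loop costs O(n) per
shuffle rather than O(n x thresholds).

Inside the permutation loop the asymptotic CMH statistic is used by
default (with the margins fixed by within-cluster shuffling, comparing
statistics is equivalent to comparing p-values); ``statistic="exact"``
switches both the observed and permuted p-values to the exact conditional
test for small fixtures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .collapsing import CollapsingMatrix
from .stats import StratifiedTable, bonferroni_alpha, cmh_exact_test

logger = logging.getLogger("rvburden")

__all__ = [
    "ScanResult",
    "nested_genesets",
    "scan_cmh",
    "permutation_empirical",
    "run_scan",
    "optimal_threshold",
    "per_gene_cmh_p",
    "plot_scan",
]


def per_gene_cmh_p(matrix: CollapsingMatrix) -> pd.DataFrame:
    """Asymptotic CMH p-value per gene with >= 1 qualifying variant.

    Vectorized across genes; feeds the genomic-inflation diagnostic on the
    synonymous negative-control model and gene-level result tables.
    """
    X = matrix.X.astype(np.float64)
    cluster = matrix.samples["cluster"].to_numpy()
    cluster_ids = sorted(pd.unique(cluster))
    is_case = (matrix.samples["phenotype"] == "case").to_numpy()
    C = np.stack([(cluster == cl).astype(np.float64) for cl in cluster_ids], axis=1)
    m1 = X @ C                      # genes x clusters carrier counts
    a = X @ (C * is_case[:, None])  # genes x clusters case carriers
    N = C.sum(axis=0)
    n1 = (C * is_case[:, None]).sum(axis=0)
    n0 = N - n1
    expect = (n1 * m1 / N).sum(axis=1)
    var = (n1 * n0 * m1 * (N - m1) / (N**2 * (N - 1))).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (a.sum(axis=1) - expect) ** 2 / var
    p = np.where(var > 0, sps.chi2.sf(stat, df=1), 1.0)
    p = np.maximum(p, np.finfo(float).tiny)
    has_qv = X.sum(axis=1) > 0
    return pd.DataFrame(
        {"gene": np.asarray(matrix.genes)[has_qv], "p": p[has_qv]}
    ).reset_index(drop=True)


def nested_genesets(panel: pd.DataFrame, genes_with_qv) -> list:
    """Ordered (threshold, gene set) pairs, one per unique LOEUF value
    among the QV-harbouring genes; the set at threshold t is every
    QV-harbouring gene with LOEUF <= t."""
    genes_with_qv = set(genes_with_qv)
    if not genes_with_qv:
        raise ValueError("no genes with qualifying variants")
    sub = panel[panel["gene"].isin(genes_with_qv)]
    missing = genes_with_qv - set(sub["gene"])
    if missing or sub["loeuf"].isna().any():
        bad = sorted(missing)[0] if missing else sub.loc[sub["loeuf"].isna(), "gene"].iloc[0]
        raise ValueError(f"gene {bad!r} lacks a LOEUF score")
    sub = sub.sort_values(["loeuf", "gene"])
    genes = sub["gene"].to_numpy()
    loeuf = sub["loeuf"].to_numpy()
    out = []
    for t in np.unique(loeuf):
        stop = np.searchsorted(loeuf, t, side="right")
        out.append((float(t), set(genes[:stop])))
    return out


# ---------------------------------------------------------------------------
# Scan engine: cumulative counts from per-individual flip indices
# ---------------------------------------------------------------------------

@dataclass
class _ScanEngine:
    """Precomputed cumulative structure of one scan."""

    thresholds: np.ndarray          # unique LOEUF values, ascending
    set_sizes: np.ndarray           # genes in the set at each threshold
    flip: np.ndarray                # per individual: first threshold index carried
    cluster_of: np.ndarray          # per individual: cluster index 0..K-1
    cluster_ids: tuple
    is_case: np.ndarray
    m1: np.ndarray                  # K x T cumulative carriers per cluster
    n1: np.ndarray                  # cases per cluster
    n0: np.ndarray                  # controls per cluster

    @property
    def n_thresholds(self) -> int:
        return len(self.thresholds)

    def case_carriers(self, is_case: np.ndarray) -> np.ndarray:
        """K x T cumulative case-carrier counts for a given labelling."""
        T = self.n_thresholds
        out = np.empty((len(self.cluster_ids), T), dtype=np.int64)
        for k in range(len(self.cluster_ids)):
            sel = (self.cluster_of == k) & is_case
            out[k] = np.cumsum(np.bincount(self.flip[sel], minlength=T + 1)[:T])
        return out

    def statistics(self, a: np.ndarray) -> np.ndarray:
        """Asymptotic CMH chi-square statistic per threshold given the
        K x T case-carrier counts; thresholds with zero variance get -inf
        (p = 1)."""
        N = (self.n1 + self.n0).astype(float)[:, None]
        m1 = self.m1.astype(float)
        m0 = N - m1
        n1 = self.n1.astype(float)[:, None]
        n0 = self.n0.astype(float)[:, None]
        expect = (n1 * m1 / N).sum(axis=0)
        var = (n1 * n0 * m1 * m0 / (N**2 * (N - 1))).sum(axis=0)
        S = a.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = (S - expect) ** 2 / var
        return np.where(var > 0, stat, -np.inf)

    def table_at(self, a_obs: np.ndarray, t_idx: int) -> StratifiedTable:
        a = a_obs[:, t_idx]
        m1 = self.m1[:, t_idx]
        return StratifiedTable(
            a, self.n1 - a, m1 - a, self.n0 - (m1 - a), self.cluster_ids
        )


def _build_engine(matrix: CollapsingMatrix, panel: pd.DataFrame) -> _ScanEngine:
    qv_genes = matrix.genes_with_qv()
    loeuf_map = panel.set_index("gene")["loeuf"]
    scored = {g for g in qv_genes if g in loeuf_map.index and pd.notna(loeuf_map[g])}
    dropped = len(qv_genes) - len(scored)
    if dropped:
        logger.warning("%d QV-harbouring genes lack a LOEUF score and are excluded",
                       dropped)
    if not scored:
        raise ValueError("no genes with qualifying variants and a LOEUF score")
    order = sorted(scored, key=lambda g: (loeuf_map[g], g))
    loeuf = np.array([loeuf_map[g] for g in order])
    thresholds = np.unique(loeuf)
    t_index = np.searchsorted(thresholds, loeuf)
    set_sizes = np.cumsum(np.bincount(t_index, minlength=len(thresholds)))

    rows = matrix.gene_rows(order)  # preserves the LOEUF order
    Xs = matrix.X[rows].astype(bool)
    any_carried = Xs.any(axis=0)
    first = np.argmax(Xs, axis=0)
    flip = np.where(any_carried, t_index[first], len(thresholds)).astype(np.int64)

    cluster = matrix.samples["cluster"].to_numpy()
    cluster_ids = tuple(sorted(pd.unique(cluster)))
    cluster_of = np.searchsorted(np.array(cluster_ids), cluster)
    is_case = (matrix.samples["phenotype"] == "case").to_numpy()

    T = len(thresholds)
    K = len(cluster_ids)
    m1 = np.empty((K, T), dtype=np.int64)
    n1 = np.empty(K, dtype=np.int64)
    n0 = np.empty(K, dtype=np.int64)
    for k in range(K):
        sel = cluster_of == k
        m1[k] = np.cumsum(np.bincount(flip[sel], minlength=T + 1)[:T])
        n1[k] = int((sel & is_case).sum())
        n0[k] = int((sel & ~is_case).sum())
    eng = _ScanEngine(thresholds, set_sizes, flip, cluster_of, cluster_ids,
                      is_case, m1, n1, n0)
    return eng


def _nominal_p(engine: _ScanEngine, a_obs: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "asymptotic":
        stat = engine.statistics(a_obs)
        p = sps.chi2.sf(stat, df=1)
        return np.where(np.isfinite(stat), np.maximum(p, np.finfo(float).tiny), 1.0)
    if statistic == "exact":
        return np.array([
            cmh_exact_test(engine.table_at(a_obs, t)).p_two_sided
            for t in range(engine.n_thresholds)
        ])
    raise ValueError("statistic must be 'asymptotic' or 'exact'")


def scan_cmh(
    matrix: CollapsingMatrix,
    panel: pd.DataFrame,
    statistic: str = "exact",
) -> tuple[np.ndarray, np.ndarray]:
    """Nominal CMH p-value per LOEUF threshold (thresholds, p)."""
    engine = _build_engine(matrix, panel)
    a_obs = engine.case_carriers(engine.is_case)
    return engine.thresholds, _nominal_p(engine, a_obs, statistic)


def permutation_empirical(
    matrix: CollapsingMatrix,
    panel: pd.DataFrame,
    n_permutations: int,
    seed: int = 0,
    statistic: str = "asymptotic",
    estimator: str = "add-one",
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical p-value per threshold from within-cluster label shuffles.

    With the add-one estimator (default), empirical p at threshold t is
    (1 + #{permutations with p_perm(t) <= p_obs(t)}) / (n_permutations +
    1); ``estimator="plugin"`` uses r/n instead.
    """
    engine = _build_engine(matrix, panel)
    emp = _empirical(engine, n_permutations, seed, statistic, estimator)
    return engine.thresholds, emp


def _empirical(engine, n_permutations, seed, statistic, estimator) -> np.ndarray:
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    a_obs = engine.case_carriers(engine.is_case)
    K = len(engine.cluster_ids)
    members = [np.flatnonzero(engine.cluster_of == k) for k in range(K)]
    hits = np.zeros(engine.n_thresholds, dtype=np.int64)

    if statistic == "asymptotic":
        # margins are permutation-invariant, so p_perm <= p_obs iff
        # stat_perm >= stat_obs
        stat_obs = engine.statistics(a_obs)
        for _ in range(n_permutations):
            labels = _shuffle_within_clusters(rng, members, engine)
            stat_perm = engine.statistics(engine.case_carriers(labels))
            hits += stat_perm >= stat_obs
    elif statistic == "exact":
        p_obs = _nominal_p(engine, a_obs, "exact")
        for _ in range(n_permutations):
            labels = _shuffle_within_clusters(rng, members, engine)
            p_perm = _nominal_p(engine, engine.case_carriers(labels), "exact")
            hits += p_perm <= p_obs
    else:
        raise ValueError("statistic must be 'asymptotic' or 'exact'")

    if estimator == "add-one":
        return (hits + 1) / (n_permutations + 1)
    if estimator == "plugin":
        return hits / n_permutations
    raise ValueError("estimator must be 'add-one' or 'plugin'")


def _shuffle_within_clusters(rng, members, engine) -> np.ndarray:
    labels = np.zeros(len(engine.flip), dtype=bool)
    for k, idx in enumerate(members):
        chosen = rng.choice(idx, size=engine.n1[k], replace=False)
        labels[chosen] = True
    return labels


# ---------------------------------------------------------------------------
# Full scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Thresholds in ascending LOEUF order (most to least intolerant
    cumulative sets) with nominal and permutation-empirical p-values."""

    thresholds: np.ndarray
    set_sizes: np.ndarray
    nominal_p: np.ndarray
    empirical_p: np.ndarray
    n_permutations: int
    bonferroni_alpha: float
    seed: int
    statistic: str
    estimator: str = "add-one"
    tables: list = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loeuf_threshold": self.thresholds,
                "set_size": self.set_sizes,
                "nominal_p": self.nominal_p,
                "empirical_p": self.empirical_p,
            }
        )


def run_scan(
    matrix: CollapsingMatrix,
    panel: pd.DataFrame,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "asymptotic",
    estimator: str = "add-one",
    keep_tables: bool = False,
) -> ScanResult:
    """The full intolerance-threshold scan on a collapsing matrix."""
    engine = _build_engine(matrix, panel)
    a_obs = engine.case_carriers(engine.is_case)
    nominal = _nominal_p(engine, a_obs, statistic)
    empirical = _empirical(engine, n_permutations, seed, statistic, estimator)
    bonf = bonferroni_alpha(alpha, engine.n_thresholds)
    floor = 1.0 / (n_permutations + 1)
    if estimator == "add-one" and floor > bonf:
        warnings.warn(
            f"empirical p floor {floor:.3g} exceeds the Bonferroni threshold "
            f"{bonf:.3g}; Bonferroni significance is unattainable from the "
            "empirical p at this permutation count",
            stacklevel=2,
        )
    tables = (
        [engine.table_at(a_obs, t) for t in range(engine.n_thresholds)]
        if keep_tables else []
    )
    return ScanResult(
        engine.thresholds, engine.set_sizes, nominal, empirical,
        n_permutations, bonf, seed, statistic, estimator, tables,
    )


def optimal_threshold(scan: ScanResult) -> tuple[float, float, bool]:
    """The LOEUF threshold attaining the minimum empirical p and whether
    it is Bonferroni-significant.

    A strong signal drives the empirical p to its floor 1/(n_perm+1) over
    a whole run of thresholds; ties on the empirical p are therefore
    broken by the nominal p (the quantity the permutations rank), and any
    remaining tie by the smallest threshold. Significance is assessed on
    the empirical p when the permutation count makes the Bonferroni bar
    attainable (floor <= alpha/m); otherwise the nominal CMH p stands in,
    with a warning — the empirical floor can never beat the bar no matter
    how strong the signal.
    """
    best = scan.empirical_p == scan.empirical_p.min()
    cand = np.flatnonzero(best)
    idx = int(cand[np.argmin(scan.nominal_p[cand])])
    emp = float(scan.empirical_p[idx])
    floor = 1.0 / (scan.n_permutations + 1)
    attainable = scan.estimator == "plugin" or floor <= scan.bonferroni_alpha
    if attainable:
        significant = emp < scan.bonferroni_alpha
    else:
        warnings.warn(
            "Bonferroni significance unattainable from the empirical p at "
            f"{scan.n_permutations} permutations; using the nominal p",
            stacklevel=2,
        )
        significant = float(scan.nominal_p[idx]) < scan.bonferroni_alpha
    return float(scan.thresholds[idx]), emp, bool(significant)


def plot_scan(scan: ScanResult, path, panel: pd.DataFrame | None = None):
    """-log10 empirical p against LOEUF threshold with the Bonferroni line
    and the optimum marked; optional intolerance-decile ticks from the
    panel's LOEUF distribution."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    y = -np.log10(scan.empirical_p)
    ax.plot(scan.thresholds, y, lw=1, color="steelblue")
    ax.axhline(-np.log10(scan.bonferroni_alpha), color="orange", lw=1,
               label="Bonferroni")
    opt, emp, _ = optimal_threshold(scan)
    ax.plot([opt], [-np.log10(emp)], "o", color="darkorange", label="optimum")
    if panel is not None:
        deciles = np.nanquantile(panel["loeuf"], np.arange(0.1, 1.0, 0.1))
        sec = ax.secondary_xaxis("top")
        sec.set_xticks(deciles, labels=[str(i) for i in range(1, 10)])
        sec.set_xlabel("intolerance decile")
    ax.set_xlabel("LOEUF threshold (genes with LOEUF ≤ t)")
    ax.set_ylabel(r"$-\log_{10}$ empirical $P$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
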