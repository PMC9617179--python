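"""Qualifying-variant models and the gene x individual collapsing matrix.

A qualifying-variant (QV) model names the consequence classes it accepts
and the frequency filters a variant must pass. The two LOF models mirror
standard collapsing practice: the *ultrarare* model keeps only variants
absent from external population references; the *flex* model allows
variants with external minor allele frequency strictly below 0.1%. An
ultrarare synonymous model serves as the negative control.

Collapsing assigns individual i an indicator 1 for gene g if i carries at
least one QV in g, building a gene x individual 0/1 matrix per ancestry
cluster; stratified 2x2 tables (case/control x carrier/non-carrier) are
extracted from it for genes or gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EFFECT_CLASSES, VariantRecord
from .stats import StratifiedTable

logger = logging.getLogger("rvburden")

__all__ = [
    "QVModel",
    "QV_MODELS",
    "CollapsingMatrix",
    "qualify_variants",
    "build_collapsing_matrix",
    "collapse_to_table",
    "matrix_from_arrays",
]


@dataclass(frozen=True)
class QVModel:
    """Class and frequency filters defining a collapsing model.

    Frequency bounds are exclusive ("less than"); if
    ``require_absent_external`` is set the external bound is ignored and
    only variants with ``external_present == False`` qualify.
    """

    name: str
    allowed_classes: frozenset
    max_external_af: float = 1.0
    require_absent_external: bool = False
    max_internal_af: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "allowed_classes", frozenset(self.allowed_classes))
        unknown = self.allowed_classes - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect class {sorted(unknown)[0]!r}")
        for bound in (self.max_external_af, self.max_internal_af):
            if not 0 <= bound <= 1:
                raise ValueError("frequency bounds must lie in [0, 1]")

    def accepts(self, v: VariantRecord) -> bool:
        if v.effect_class not in self.allowed_classes:
            return False
        if self.require_absent_external:
            if v.external_present:
                return False
        elif not v.external_af < self.max_external_af:
            return False
        return v.internal_af < self.max_internal_af


#: built-in models; the internal bound of the flex models mirrors the
#: external one (applied on the combined case+control cohort)
QV_MODELS = {
    m.name: m
    for m in (
        QVModel("ultrarare_lof", frozenset({"LOF"}), require_absent_external=True),
        QVModel("flex_lof", frozenset({"LOF"}), max_external_af=0.001,
                max_internal_af=0.001),
        QVModel("ultrarare_synonymous", frozenset({"synonymous"}),
                require_absent_external=True),
        QVModel("flex_synonymous", frozenset({"synonymous"}),
                max_external_af=0.001, max_internal_af=0.001),
    )
}


def qualify_variants(variants, model: QVModel) -> list[VariantRecord]:
    """Variants passing the model's class and frequency filters, in input
    order."""
    return [v for v in variants if model.accepts(v)]


@dataclass
class CollapsingMatrix:
    """Gene x individual 0/1 qualifying-variant indicators.

    One matrix spans all clusters; the sample table's ``cluster`` column
    partitions the columns, and each individual belongs to exactly one
    cluster block.
    """

    genes: list
    samples: pd.DataFrame  # sample_id, phenotype, cluster
    X: np.ndarray  # genes x individuals, uint8 in {0, 1}
    model_name: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.uint8)
        if self.X.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape must be (n_genes, n_samples)")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("collapsing matrix entries must be 0/1")
        for col in ("sample_id", "phenotype", "cluster"):
            if col not in self.samples.columns:
                raise ValueError(f"sample table lacks column {col!r}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("an individual appears in more than one column")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def cluster_ids(self) -> list:
        return sorted(self.samples["cluster"].unique())

    def gene_rows(self, geneset) -> np.ndarray:
        return np.array(
            [self._gene_index[g] for g in geneset if g in self._gene_index],
            dtype=int,
        )

    def genes_with_qv(self) -> set:
        """Genes harbouring >= 1 QV in any analyzed case or control."""
        return {g for g, row in zip(self.genes, self.X) if row.any()}


def matrix_from_arrays(genes, samples, X, model_name="") -> CollapsingMatrix:
    """Wrap pre-computed indicator arrays (e.g. from the simulator)."""
    return CollapsingMatrix(list(genes), samples.reset_index(drop=True), X, model_name)


def build_collapsing_matrix(
    qualified_variants,
    samples: pd.DataFrame,
    assignment=None,
    model_name: str = "",
) -> CollapsingMatrix:
    """Collapse qualifying variants to gene-level indicators.

    Entry (g, i) is 1 iff individual i carries >= 1 qualifying variant in
    gene g. If a cluster assignment is given, samples are restricted to
    assigned individuals and given its cluster labels; otherwise the sample
    table must already carry a ``cluster`` column.
    """
    samples = samples.copy()
    if assignment is not None:
        samples = samples[samples["sample_id"].isin(assignment.labels.index)]
        samples["cluster"] = assignment.labels.loc[samples["sample_id"]].to_numpy()
    samples = samples.reset_index(drop=True)
    ids = samples["sample_id"]
    col_of = {sid: j for j, sid in enumerate(ids)}
    genes = sorted({v.gene for v in qualified_variants})
    row_of = {g: i for i, g in enumerate(genes)}
    X = np.zeros((len(genes), len(ids)), dtype=np.uint8)
    analyzed = set(ids)
    for v in qualified_variants:
        stray = v.carriers - analyzed
        if stray and assignment is None:
            raise ValueError(
                f"carrier {sorted(stray)[0]!r} of {v.gene} is not an analyzed sample"
            )
        for sid in v.carriers & analyzed:
            X[row_of[v.gene], col_of[sid]] = 1
    return CollapsingMatrix(genes, samples, X, model_name)


def collapse_to_table(
    matrix: CollapsingMatrix, geneset, phenotypes=None
) -> StratifiedTable:
    """Per-cluster 2x2 carrier counts for a gene set (union semantics: an
    individual is a carrier iff it has state 1 in >= 1 gene of the set)."""
    geneset = set(geneset)
    if not geneset:
        raise ValueError("geneset must be nonempty")
    rows = matrix.gene_rows(geneset)
    if len(rows) == 0:
        logger.warning("gene set is disjoint from the matrix genes")
        carrier = np.zeros(len(matrix.samples), dtype=bool)
    else:
        carrier = matrix.X[rows].any(axis=0)
    if phenotypes is None:
        is_case = (matrix.samples["phenotype"] == "case").to_numpy()
    else:
        is_case = (
            pd.Series(phenotypes).loc[matrix.samples["sample_id"]].to_numpy()
            == "case"
        )
    cluster = matrix.samples["cluster"].to_numpy()
    cluster_ids = sorted(pd.unique(cluster))
    a = np.empty(len(cluster_ids), dtype=np.int64)
    b = np.empty_like(a)
    c = np.empty_like(a)
    d = np.empty_like(a)
    for k, cl in enumerate(cluster_ids):
        in_cl = cluster == cl
        a[k] = int((carrier & is_case & in_cl).sum())
        b[k] = int((~carrier & is_case & in_cl).sum())
        c[k] = int((carrier & ~is_case & in_cl).sum())
        d[k] = int((~carrier & ~is_case & in_cl).sum())
    return StratifiedTable(a, b, c, d, tuple(cluster_ids))
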