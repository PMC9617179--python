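"""Gene-set enrichment batteries over intolerant genes.

Intolerant genes (LOEUF at or below a cap, default 0.680) are partitioned
by known disease association, and qualifying variants by ultrarare
(absent from external references) versus rare-but-present status. Each
cell of the battery collapses its matrix over its gene set, tests
case/control carrier enrichment (exact CMH across ancestry clusters, or
Fisher on the pooled table for small cohorts), and the whole battery is
Benjamini-Hochberg adjusted. Case-only candidate genes are intolerant
genes without a known disease association carried by cases only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .collapsing import CollapsingMatrix, collapse_to_table
from .stats import bh_adjust, cmh_exact_test, fisher_exact_test

logger = logging.getLogger("rvburden")

__all__ = [
    "BurdenCell",
    "DEFAULT_INTOLERANCE_CAP",
    "partition_by_disease_association",
    "run_burden_battery",
    "case_only_candidates",
]

DEFAULT_INTOLERANCE_CAP = 0.680

VARIANT_PARTITIONS = ("all_rare", "ultrarare", "rare_but_present")


@dataclass
class BurdenCell:
    """One test of the battery: a gene partition crossed with a variant
    partition, under one test kind."""

    label: str
    gene_partition: str
    variant_partition: str
    test_kind: str
    n_genes_with_qv: int
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted_p: float = np.nan
    excluded: bool = False


def partition_by_disease_association(
    panel: pd.DataFrame, intolerance_cap: float = DEFAULT_INTOLERANCE_CAP
) -> tuple[set, set]:
    """(disease-associated, no-known-association) gene sets among genes
    with LOEUF <= cap."""
    under = panel[panel["loeuf"] <= intolerance_cap]
    if under.empty:
        raise ValueError(
            f"intolerance cap {intolerance_cap} excludes every panel gene"
        )
    flagged = set(under.loc[under["disease_associated"], "gene"])
    unflagged = set(under.loc[~under["disease_associated"], "gene"])
    logger.info(
        "intolerance cap %.3g: %d disease-associated, %d no-known-association",
        intolerance_cap, len(flagged), len(unflagged),
    )
    return flagged, unflagged


def _test_cell(matrix: CollapsingMatrix, geneset: set, test_kind: str):
    table = collapse_to_table(matrix, geneset)
    a, b = int(table.a.sum()), int(table.b.sum())
    c, d = int(table.c.sum()), int(table.d.sum())
    if test_kind == "cmh_exact":
        r = cmh_exact_test(table)
        res = (r.pooled_or, r.ci_low, r.ci_high, r.p_two_sided)
    elif test_kind == "fisher":
        f = fisher_exact_test(a, b, c, d)
        res = (f.odds_ratio, f.ci_low, f.ci_high, f.p_two_sided)
    else:
        raise ValueError("test_kind must be 'cmh_exact' or 'fisher'")
    return res, (a, a + b, c, c + d)


def run_burden_battery(
    matrices: dict,
    gene_partitions: dict,
    test_kind: str = "cmh_exact",
    cells: list | None = None,
) -> list[BurdenCell]:
    """Run every configured cell and BH-adjust across the battery.

    ``matrices`` maps variant-partition name -> CollapsingMatrix (built
    under the flex model and split by external presence); the ultrarare and
    rare_but_present matrices must partition all_rare. ``gene_partitions``
    maps partition name -> gene set. ``cells`` restricts the battery to
    explicit (gene_partition, variant_partition, test_kind) triples;
    by default every gene partition is crossed with every available
    variant partition under ``test_kind``. Cells with no carriers anywhere
    are flagged and excluded from the FDR adjustment.
    """
    if cells is None:
        cells = [
            (gp, vp, test_kind)
            for gp in gene_partitions
            for vp in matrices
        ]
    out: list[BurdenCell] = []
    for gp, vp, kind in cells:
        matrix = matrices[vp]
        geneset = set(gene_partitions[gp])
        if not geneset:
            # an empty gene partition can carry nothing: flag and exclude
            n_case = int((matrix.samples["phenotype"] == "case").sum())
            n_ctrl = int((matrix.samples["phenotype"] == "control").sum())
            out.append(BurdenCell(
                label=f"{gp}|{vp}", gene_partition=gp, variant_partition=vp,
                test_kind=kind, n_genes_with_qv=0,
                case_carriers=0, case_total=n_case,
                control_carriers=0, control_total=n_ctrl,
                odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                p_value=np.nan, excluded=True,
            ))
            continue
        rows = matrix.gene_rows(geneset)
        if len(rows):
            sub = matrix.X[rows]
            n_qv = int((sub.sum(axis=1) > 0).sum())
        else:
            n_qv = 0
        (or_, lo, hi, p), (a, nt, c, ct) = _test_cell(matrix, geneset, kind)
        excluded = (a + c) == 0
        out.append(
            BurdenCell(
                label=f"{gp}|{vp}", gene_partition=gp, variant_partition=vp,
                test_kind=kind, n_genes_with_qv=n_qv,
                case_carriers=a, case_total=nt,
                control_carriers=c, control_total=ct,
                odds_ratio=or_, ci_low=lo, ci_high=hi, p_value=p,
                excluded=excluded,
            )
        )
    testable = [c for c in out if not c.excluded]
    if testable:
        adj = bh_adjust([c.p_value for c in testable])
        for c, q in zip(testable, adj):
            c.adjusted_p = float(q)
    n_excluded = len(out) - len(testable)
    if n_excluded:
        logger.warning("%d battery cell(s) had no carriers and were excluded "
                       "from FDR adjustment", n_excluded)
    return out


def battery_frame(cells: list[BurdenCell]) -> pd.DataFrame:
    rows = [
        {
            "set_label": c.label, "n_genes_with_qv": c.n_genes_with_qv,
            "case_carriers": c.case_carriers, "case_total": c.case_total,
            "control_carriers": c.control_carriers, "control_total": c.control_total,
            "odds_ratio": c.odds_ratio, "ci_low": c.ci_low, "ci_high": c.ci_high,
            "p_value": c.p_value, "adjusted_p": c.adjusted_p,
        }
        for c in cells
    ]
    return pd.DataFrame(rows)


def case_only_candidates(matrix: CollapsingMatrix, geneset: set) -> pd.DataFrame:
    """Genes of the set carried by >= 1 case and 0 controls, sorted by
    descending case carrier count then gene id — the candidate list for
    ultrarare LOF variants in intolerant genes without a known disease
    association."""
    is_case = (matrix.samples["phenotype"] == "case").to_numpy()
    rows = []
    index = {g: i for i, g in enumerate(matrix.genes)}
    for g in sorted(set(geneset) & set(matrix.genes)):
        row = matrix.X[index[g]].astype(bool)
        n_case = int((row & is_case).sum())
        n_ctrl = int((row & ~is_case).sum())
        if n_case >= 1 and n_ctrl == 0:
            rows.append({"gene": g, "case_carriers": n_case})
    df = pd.DataFrame(rows, columns=["gene", "case_carriers"])
    return df.sort_values(
        ["case_carriers", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
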