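"""Poisson enrichment of de novo variants per consequence class.

Given per-gene per-class mutation probabilities (per chromosome per
generation), the expected de novo count in a gene universe is
2 x n_trios x sum of rates — two transmitted copies per trio. Observed
counts from trio calls are compared with the expectation by an upper-tail
Poisson test (the enrichment direction only, matching the convention of
trio-study tooling). Composite classes sum their components:
missense_and_LOF = missense + LOF, all = synonymous + missense + LOF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MU_COLUMNS

logger = logging.getLogger("rvburden")

__all__ = [
    "DeNovoResult",
    "VARIANT_CLASSES",
    "expected_count",
    "poisson_test",
    "denovo_battery",
]

BASE_CLASSES = ("synonymous", "missense", "LOF")
COMPOSITE_CLASSES = {
    "missense_and_LOF": ("missense", "LOF"),
    "all": ("synonymous", "missense", "LOF"),
}
#: reporting order
VARIANT_CLASSES = ("synonymous", "missense", "LOF", "missense_and_LOF", "all")


@dataclass(frozen=True)
class DeNovoResult:
    variant_class: str
    observed: int
    expected: float
    enrichment: float
    p: float
    degenerate: bool = False


def expected_count(
    panel: pd.DataFrame, geneset, n_trios: int, variant_class: str
) -> float:
    """Expected de novo count: 2 x n_trios x sum of per-gene rates over
    the gene set, composite classes summing their components."""
    if n_trios < 0:
        raise ValueError("n_trios must be >= 0")
    geneset = set(geneset)
    missing = geneset - set(panel["gene"])
    if missing:
        raise ValueError(f"no mutation rates for gene {sorted(missing)[0]!r}")
    if variant_class in COMPOSITE_CLASSES:
        return sum(
            expected_count(panel, geneset, n_trios, part)
            for part in COMPOSITE_CLASSES[variant_class]
        )
    try:
        col = MU_COLUMNS[variant_class]
    except KeyError:
        raise ValueError(f"unknown variant class {variant_class!r}") from None
    sub = panel[panel["gene"].isin(geneset)]
    if sub[col].isna().any():
        gene = sub.loc[sub[col].isna(), "gene"].iloc[0]
        raise ValueError(f"missing {variant_class} rate for gene {gene!r}")
    return float(2.0 * n_trios * sub[col].sum())


def poisson_test(observed: int, expected: float,
                 variant_class: str = "") -> DeNovoResult:
    """Upper-tail Poisson test: p = P(X >= observed) for X ~
    Poisson(expected); enrichment = observed/expected."""
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if expected < 0:
        raise ValueError("expected count must be >= 0")
    if expected == 0:
        if observed == 0:
            return DeNovoResult(variant_class, 0, 0.0, np.nan, 1.0, degenerate=True)
        return DeNovoResult(variant_class, observed, 0.0, np.inf, 0.0,
                            degenerate=True)
    p = float(sps.poisson.sf(observed - 1, expected))
    return DeNovoResult(variant_class, int(observed), float(expected),
                        observed / expected, p)


def denovo_battery(
    panel: pd.DataFrame,
    geneset,
    calls: pd.DataFrame,
    n_trios: int,
) -> list[DeNovoResult]:
    """One Poisson enrichment result per variant class.

    ``calls`` has columns trio_id, gene, effect_class; calls outside the
    gene universe are excluded with a warning, calls in genes missing from
    the panel likewise.
    """
    geneset = set(geneset)
    for col in ("trio_id", "gene", "effect_class"):
        if col not in calls.columns:
            raise ValueError(f"de novo call table lacks column {col!r}")
    known = set(panel["gene"])
    in_universe = calls["gene"].isin(geneset & known)
    n_out = int((~in_universe).sum())
    if n_out:
        logger.warning("excluded %d de novo call(s) outside the gene universe",
                       n_out)
    kept = calls[in_universe]
    base_counts = {
        cls: int((kept["effect_class"] == cls).sum()) for cls in BASE_CLASSES
    }
    results = []
    for cls in VARIANT_CLASSES:
        if cls in COMPOSITE_CLASSES:
            obs = sum(base_counts[p] for p in COMPOSITE_CLASSES[cls])
        else:
            obs = base_counts[cls]
        exp = expected_count(panel, geneset, n_trios, cls)
        results.append(poisson_test(obs, exp, variant_class=cls))
    return results


def denovo_frame(results: list[DeNovoResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_class": r.variant_class, "observed": r.observed,
                "expected": r.expected, "enrichment": r.enrichment, "p": r.p,
            }
            for r in results
        ]
    )
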