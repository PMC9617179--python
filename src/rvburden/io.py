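"""Readers and writers for the tabular formats the pipeline touches.

Everything on disk is plain text: TSV for sample tables, gene panels,
carrier matrices and result tables; minimal sites+GT VCF for variant-level
round trips. Coordinates are 1-based VCF-style throughout. Gene identity is
by symbol string — no alias resolution.

Allele-frequency convention: ``internal_af`` = carrier count / (2 x
analyzed samples), i.e. at most one qualifying allele per individual per
gene is assumed; the binary collapsed indicator is unaffected either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("rvburden")

EFFECT_CLASSES = ("LOF", "missense", "synonymous", "other")

#: gene-panel columns holding per-class de novo mutation probabilities
#: (per chromosome per generation)
MU_COLUMNS = {"synonymous": "mu_syn", "missense": "mu_mis", "LOF": "mu_lof"}

PANEL_REQUIRED = ("gene", "loeuf", "disease_associated", "mu_syn", "mu_mis", "mu_lof")


@dataclass
class VariantRecord:
    """One annotated variant joined to its carriers.

    ``external_present`` marks presence in public reference datasets;
    ``external_af = 0`` if and only if the variant is absent there.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect_class: str
    external_af: float
    external_present: bool
    internal_af: float = 0.0
    carriers: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if not 0.0 <= self.external_af <= 1.0:
            raise ValueError("external_af outside [0, 1]")
        if self.external_present != (self.external_af > 0):
            raise ValueError(
                "external_present must be True exactly when external_af > 0"
            )
        self.carriers = frozenset(self.carriers)

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

def read_sample_table(path) -> pd.DataFrame:
    """Sample table: sample_id, phenotype (case/control), optional cluster."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"sample table {path} lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    bad = set(df["phenotype"]) - {"case", "control"}
    if bad:
        raise ValueError(f"phenotype values must be case/control, got {sorted(bad)}")
    return df


def write_sample_table(df: pd.DataFrame, path, header_comment: str | None = None):
    _write_tsv(df, path, header_comment)


# ---------------------------------------------------------------------------
# Variants: VCF or 3-column carrier table, joined to TSV annotations
# ---------------------------------------------------------------------------

def read_variants(variant_file, annotation_file, sample_file) -> list[VariantRecord]:
    """Read variants (VCF or carrier TSV), join to annotations, compute
    internal allele frequencies over the analyzed samples.

    Every variant must join to exactly one annotation row (key: chrom, pos,
    ref, alt); unjoined variants are dropped with a logged count. Carriers
    not present in the sample table raise a data error.
    """
    samples = read_sample_table(sample_file)
    sample_ids = set(samples["sample_id"])
    n_analyzed = len(sample_ids)

    ann = pd.read_csv(
        annotation_file, sep="\t", comment="#",
        dtype={"chrom": str, "ref": str, "alt": str, "gene": str},
    )
    required = ("chrom", "pos", "ref", "alt", "gene", "effect_class", "external_af")
    for col in required:
        if col not in ann.columns:
            raise ValueError(f"annotation file lacks required column {col!r}")
    ann_key = list(zip(ann["chrom"], ann["pos"], ann["ref"], ann["alt"]))
    if len(set(ann_key)) != len(ann_key):
        raise ValueError("duplicate variant key in annotation file")
    ann_map = dict(zip(ann_key, ann.to_dict("records")))

    raw = _read_raw_carriers(variant_file)
    seen = set()
    records: list[VariantRecord] = []
    n_unjoined = 0
    for key, carriers in raw:
        if key in seen:
            raise ValueError(f"duplicate variant key {key} in {variant_file}")
        seen.add(key)
        row = ann_map.get(key)
        if row is None:
            n_unjoined += 1
            continue
        unknown = carriers - sample_ids
        if unknown:
            raise ValueError(
                f"carrier id {sorted(unknown)[0]!r} for variant {key} "
                "is not in the sample table"
            )
        af_ext = float(row["external_af"])
        records.append(
            VariantRecord(
                chrom=str(key[0]), pos=int(key[1]), ref=key[2], alt=key[3],
                gene=str(row["gene"]), effect_class=str(row["effect_class"]),
                external_af=af_ext, external_present=af_ext > 0,
                internal_af=len(carriers) / (2 * n_analyzed),
                carriers=frozenset(carriers),
            )
        )
    if n_unjoined:
        logger.warning("dropped %d variants without an annotation row", n_unjoined)
    return records


def _read_raw_carriers(path):
    """Yield ((chrom, pos, ref, alt), carrier-id set) from a VCF or from a
    TSV with columns chrom, pos, ref, alt, sample_id (one row per carrier)."""
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf_carriers(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "sample_id": str})
    if df.empty:
        return []
    for col in ("chrom", "pos", "ref", "alt", "sample_id"):
        if col not in df.columns:
            raise ValueError(f"carrier table lacks required column {col!r}")
    out = []
    for key, grp in df.groupby(["chrom", "pos", "ref", "alt"], sort=False):
        out.append(((str(key[0]), int(key[1]), key[2], key[3]), set(grp["sample_id"])))
    return out


def _read_vcf_carriers(path):
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        ids = list(vcf.header.samples)
        for rec in vcf:
            carriers = {
                sid for sid in ids
                if any(al not in (0, None) for al in rec.samples[sid]["GT"])
            }
            for alt in rec.alts or ():
                out.append(((rec.chrom, rec.pos, rec.ref, alt), carriers))
    return out


def write_vcf(records: list[VariantRecord], sample_ids: list[str], path):
    """Minimal sites+GT VCF (uncompressed text) for round-trip tests."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({r.chrom for r in recs}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for r in recs:
            gts = ["0/1" if sid in r.carriers else "0/0" for sid in sample_ids]
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return Path(path)


def write_annotations(records: list[VariantRecord], path):
    rows = [
        {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
         "gene": r.gene, "effect_class": r.effect_class, "external_af": r.external_af}
        for r in records
    ]
    cols = ["chrom", "pos", "ref", "alt", "gene", "effect_class", "external_af"]
    _write_tsv(pd.DataFrame(rows, columns=cols), path)


# ---------------------------------------------------------------------------
# Gene panels and gene lists
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


def read_gene_panel(path) -> pd.DataFrame:
    """Gene panel: gene, LOEUF score, disease-association flag and
    per-class de novo mutation rates. Genes lacking a LOEUF score are kept
    but flagged (NaN) and excluded from the intolerance scan downstream."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    for col in PANEL_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"gene panel {path} lacks required column {col!r}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in gene panel")
    df["disease_associated"] = df["disease_associated"].map(_parse_flag)
    n_missing = int(df["loeuf"].isna().sum())
    if n_missing:
        logger.warning("%d panel genes lack a LOEUF score", n_missing)
    if (df[["mu_syn", "mu_mis", "mu_lof"]].fillna(0) < 0).any().any():
        raise ValueError("mutation rates must be non-negative")
    return df.reset_index(drop=True)


def _parse_flag(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot parse boolean flag {value!r}")


def write_gene_panel(panel: pd.DataFrame, path, header_comment: str | None = None):
    out = panel.copy()
    out["disease_associated"] = out["disease_associated"].astype(int)
    _write_tsv(out, path, header_comment)


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; '#' comments and blank lines ignored;
    duplicates collapse. An empty file yields an empty set with a warning."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    if not genes:
        logger.warning("gene list %s is empty", path)
    return genes


# ---------------------------------------------------------------------------
# Carrier matrices and result tables
# ---------------------------------------------------------------------------

def write_matrix_tsv(genes, sample_ids, X, path, header_comment: str | None = None):
    """Serialize a genes x individuals 0/1 indicator matrix."""
    df = pd.DataFrame(np.asarray(X, dtype=np.uint8), index=pd.Index(genes, name="gene"),
                      columns=sample_ids)
    _write_tsv(df.reset_index(), path, header_comment)


def read_matrix_tsv(path):
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    genes = df["gene"].tolist()
    sample_ids = [c for c in df.columns if c != "gene"]
    X = df[sample_ids].to_numpy(dtype=np.uint8)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("carrier matrix entries must be 0/1")
    return genes, sample_ids, X


REPORT_COLUMNS = [
    "set_label", "n_genes_with_qv", "case_carriers", "case_total",
    "control_carriers", "control_total", "odds_ratio", "ci_low", "ci_high",
    "p_value", "adjusted_p",
]


def write_report_tables(results: pd.DataFrame, out_dir, name="burden_battery.tsv",
                        header_comment: str | None = None) -> Path:
    """Write a battery result table with the fixed column order used by the
    forest-plot style reports. An empty battery yields a header-only file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = results.copy() if len(results) else pd.DataFrame(columns=REPORT_COLUMNS)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result table lacks columns {missing}")
    path = out_dir / name
    _write_tsv(df[REPORT_COLUMNS], path, header_comment)
    return path


def _write_tsv(df: pd.DataFrame, path, header_comment: str | None = None):
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
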