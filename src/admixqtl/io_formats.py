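"""Readers, writers and in-memory containers for the pipeline's file formats.

Genotypes travel as dense sample x SNP dosage matrices (alt-allele counts
0/1/2, NaN for missing), the natural shape for SNP-array data.  Two on-disk
dialects are supported: VCF (GT field only) and a plain ``dosage_tsv`` with a
sample-id first column, a header row of SNP ids and entries 0/1/2/NA.
Expression comes as a traits TSV (rows = samples) plus a gene-annotation TSV
(trait_id, gene_symbol, chrom, pos).  All coordinates are 1-based, VCF style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

ASSOCIATION_COLUMNS = [
    "trait_id",
    "snp_id",
    "chrom_trait",
    "pos_trait",
    "chrom_snp",
    "pos_snp",
    "K",
    "p",
    "relation",
    "r2",
]


class FormatError(ValueError):
    """Raised when a file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


@dataclass(frozen=True)
class SNPRecord:
    """One biallelic SNP: identity, 1-based position and alleles."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"SNP {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"SNP {self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class GeneRecord:
    """An expression trait's gene: trait id, symbol and representative position."""

    trait_id: str
    gene_symbol: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"trait {self.trait_id}: pos must be >= 1")


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix (samples x SNPs) with SNP metadata.

    ``dosage`` holds alt-allele counts as floats so missing calls can be NaN;
    every non-missing entry is 0, 1 or 2.  Optional per-sample population
    labels support reference panels.
    """

    sample_ids: list[str]
    snps: list[SNPRecord]
    dosage: np.ndarray
    pop_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.snps):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len({s.id for s in self.snps}) != m:
            raise ValidationError("duplicate SNP ids")
        called = self.dosage[~np.isnan(self.dosage)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosage entries must be 0, 1, 2 or missing")
        if self.pop_labels is not None and len(self.pop_labels) != n:
            raise ValidationError("pop_labels length != number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps], dtype=object)

    def take_snps(self, index: Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to the SNPs at ``index`` (order preserved)."""
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=[self.snps[i] for i in index],
            dosage=self.dosage[:, index].copy(),
            pop_labels=None if self.pop_labels is None else list(self.pop_labels),
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            snps=list(self.snps),
            dosage=self.dosage[index, :].copy(),
            pop_labels=None
            if self.pop_labels is None
            else [self.pop_labels[i] for i in index],
        )


@dataclass
class ExpressionMatrix:
    """Real-valued expression (samples x traits) with per-trait gene metadata."""

    sample_ids: list[str]
    genes: list[GeneRecord]
    values: np.ndarray
    batch_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, t = self.values.shape
        if n != len(self.sample_ids) or t != len(self.genes):
            raise ValidationError("values shape inconsistent with ids/genes")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite")
        if self.batch_labels is not None and len(self.batch_labels) != n:
            raise ValidationError("batch_labels length != number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_traits(self) -> int:
        return len(self.genes)

    @property
    def trait_ids(self) -> list[str]:
        return [g.trait_id for g in self.genes]

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            genes=list(self.genes),
            values=np.asarray(values, dtype=float),
            batch_labels=None if self.batch_labels is None else list(self.batch_labels),
        )


@dataclass
class CovariateTable:
    """Per-sample age (years) and sex (0/1)."""

    sample_ids: list[str]
    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        n = len(self.sample_ids)
        if self.age.shape != (n,) or self.sex.shape != (n,):
            raise ValidationError("covariate arrays must be one row per sample")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if (self.age <= 0).any():
            raise ValidationError("age must be positive")
        if not np.isin(self.sex, (0.0, 1.0)).all():
            raise ValidationError("sex must be coded 0/1")


# ---------------------------------------------------------------------------
# genotype I/O


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    snps: list[SNPRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    seen: set[str] = set()
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        vid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        if vid in seen:
            raise ValidationError(f"duplicate SNP id {vid!r} in {path}")
        seen.add(vid)
        # gts012: 0/1/2 = alt count, 3 = missing
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = MISSING
        snps.append(
            SNPRecord(id=vid, chrom=var.CHROM, pos=var.POS,
                      ref_allele=var.REF, alt_allele=var.ALT[0])
        )
        columns.append(gt)
    if n_skipped:
        logger.info("read_genotypes: skipped %d non-biallelic-SNP records", n_skipped)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, dosage=dosage)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.columns.duplicated().any():
        raise ValidationError(f"duplicate SNP ids in header of {path}")
    map_path = Path(str(path) + ".map")
    if map_path.exists():
        snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
        snp_map = snp_map.set_index("id").loc[list(df.columns)]
        snps = [
            SNPRecord(id=str(i), chrom=str(r.chrom), pos=int(r.pos),
                      ref_allele=str(r.ref_allele), alt_allele=str(r.alt_allele))
            for i, r in snp_map.iterrows()
        ]
    else:
        logger.info("no .map sidecar for %s; using placeholder SNP coordinates", path)
        snps = [
            SNPRecord(id=str(c), chrom="0", pos=j + 1, ref_allele="A", alt_allele="G")
            for j, c in enumerate(df.columns)
        ]
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        snps=snps,
        dosage=df.to_numpy(dtype=float),
    )


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``dosage_tsv``.

    Dosages are alt-allele counts; missing calls ("./." in VCF, NA in TSV)
    stay missing.  VCF records that are not biallelic SNPs are skipped and
    counted in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path) -> None:
    """Write the dosage_tsv dialect plus a ``.map`` sidecar of SNP metadata."""
    path = Path(path)
    # write by hand to keep integer appearance for called genotypes
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(G.snp_ids) + "\n")
        for sid, row in zip(G.sample_ids, G.dosage):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")
    snp_map = pd.DataFrame(
        {
            "id": G.snp_ids,
            "chrom": [s.chrom for s in G.snps],
            "pos": [s.pos for s in G.snps],
            "ref_allele": [s.ref_allele for s in G.snps],
            "alt_allele": [s.alt_allele for s in G.snps],
        }
    )
    snp_map.to_csv(Path(str(path) + ".map"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression I/O


def read_expression(path, annotation_path) -> ExpressionMatrix:
    """Read a traits TSV (rows = samples) and its gene-annotation TSV.

    Traits without an annotation row are dropped with a logged count.  An
    optional ``batch`` column in the expression file (first data column) is
    honoured if named exactly "batch".
    """
    path, annotation_path = Path(path), Path(annotation_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    batch = None
    if "batch" in df.columns:
        batch = [str(b) for b in df["batch"]]
        df = df.drop(columns=["batch"])
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        raise FormatError(
            f"non-numeric expression value in column {col!r}, "
            f"row {bad.index[0]!r} of {path}"
        )
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str}).set_index(
        "trait_id"
    )
    keep, genes = [], []
    n_dropped = 0
    for trait in df.columns:
        if trait in ann.index:
            r = ann.loc[trait]
            genes.append(
                GeneRecord(trait_id=trait, gene_symbol=str(r.gene_symbol),
                           chrom=str(r.chrom), pos=int(r.pos))
            )
            keep.append(trait)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("read_expression: dropped %d unannotated traits", n_dropped)
    return ExpressionMatrix(
        sample_ids=[str(s) for s in df.index],
        genes=genes,
        values=df[keep].to_numpy(dtype=float),
        batch_labels=batch,
    )


def write_expression(E: ExpressionMatrix, path, annotation_path) -> None:
    df = pd.DataFrame(E.values, index=E.sample_ids, columns=E.trait_ids)
    if E.batch_labels is not None:
        df.insert(0, "batch", E.batch_labels)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    ann = pd.DataFrame(
        {
            "trait_id": E.trait_ids,
            "gene_symbol": [g.gene_symbol for g in E.genes],
            "chrom": [g.chrom for g in E.genes],
            "pos": [g.pos for g in E.genes],
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def read_covariates(path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t")
    return CovariateTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        age=df["age"].to_numpy(dtype=float),
        sex=df["sex"].to_numpy(dtype=float),
    )


def write_covariates(cov: CovariateTable, path) -> None:
    pd.DataFrame(
        {"sample_id": cov.sample_ids, "age": cov.age, "sex": cov.sex.astype(int)}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# association tables


def write_association_table(records: pd.DataFrame, path) -> None:
    """Write association records as TSV, sorted by (trait_id, p).

    ``records`` is a DataFrame with the :data:`ASSOCIATION_COLUMNS` schema
    (as produced by :func:`admixqtl.eqtl.scan_eqtls`); an empty frame yields
    a header-only file.
    """
    df = records.loc[:, ASSOCIATION_COLUMNS].copy()
    if len(df):
        df = df.sort_values(["trait_id", "p"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_association_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom_trait": str, "chrom_snp": str}
    )
    missing = set(ASSOCIATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"association table {path} lacks columns {sorted(missing)}")
    return df
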