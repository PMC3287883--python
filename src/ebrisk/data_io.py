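"""Dataset model and TSV readers/writers.

All tables are tab-separated with a header row.  The genotype file's sample
order is canonical: phenotype and covariate tables are re-aligned to it by
sample id on read.  Genotypes are minor-allele counts in {0, 1, 2}; missing
entries (an explicit ``missing_code`` token) are imputed to 0 with a logged
count, which is conservative for burden scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CLASSES = frozenset({"synonymous", "nonsynonymous"})


class DataValidationError(ValueError):
    """Raised when an input table violates the documented schema."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class GenotypeDataset:
    """Individuals x SNPs minor-allele count matrix with ordered ids."""

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    G: np.ndarray
    n_imputed: int = 0

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.G = np.asarray(self.G)
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.snp_ids, "snp_ids")
        if self.G.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise DataValidationError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if not np.issubdtype(self.G.dtype, np.integer):
            raise DataValidationError("genotype matrix must be integer-valued")
        bad = (self.G < 0) | (self.G > 2)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DataValidationError(
                f"genotype out of range {{0,1,2}} at sample "
                f"{self.sample_ids[r]!r}, SNP {self.snp_ids[c]!r}: {self.G[r, c]}"
            )

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class AnnotationTable:
    """SNP -> gene mapping plus a synonymous/nonsynonymous class flag."""

    table: pd.DataFrame  # columns: snp_id, gene_id, functional_class

    def __post_init__(self) -> None:
        required = {"snp_id", "gene_id", "functional_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataValidationError(f"annotation missing columns: {sorted(missing)}")
        _check_unique(self.table["snp_id"], "annotation snp_id")
        bad = ~self.table["functional_class"].isin(VALID_CLASSES)
        if bad.any():
            tok = self.table.loc[bad, "functional_class"].iloc[0]
            raise DataValidationError(f"unknown functional_class token: {tok!r}")
        self.table = self.table.reset_index(drop=True)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy(dtype=object)

    @property
    def gene_ids(self) -> np.ndarray:
        return pd.unique(self.table["gene_id"]).astype(object)

    def subset_class(self, functional_class: str) -> "AnnotationTable":
        if functional_class == "all":
            return self
        if functional_class not in VALID_CLASSES:
            raise DataValidationError(f"unknown class filter: {functional_class!r}")
        sub = self.table[self.table["functional_class"] == functional_class]
        return AnnotationTable(sub.copy())


@dataclass
class PhenotypeReplicates:
    """Binary disease status, one column per phenotype replicate."""

    sample_ids: np.ndarray
    replicate_ids: np.ndarray
    Y: np.ndarray  # (n, R) in {0,1}

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=object)
        self.Y = np.asarray(self.Y)
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.replicate_ids, "replicate_ids")
        if self.Y.shape != (len(self.sample_ids), len(self.replicate_ids)):
            raise DataValidationError("phenotype matrix shape mismatch")
        if self.Y.shape[1] < 1:
            raise DataValidationError("need at least one phenotype replicate")
        if not np.isin(self.Y, (0, 1)).all():
            raise DataValidationError("phenotype values must be 0 or 1")
        n = self.Y.shape[0]
        n1 = self.Y.sum(axis=0)
        for r, cases in zip(self.replicate_ids, n1):
            if cases == 0:
                raise DataValidationError(f"no cases in replicate {r!r}")
            if cases == n:
                raise DataValidationError(f"no controls in replicate {r!r}")

    @property
    def R(self) -> int:
        return self.Y.shape[1]


@dataclass
class CovariateTable:
    """Per-individual numeric covariates aligned to genotype sample order."""

    sample_ids: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        _check_unique(self.sample_ids, "sample_ids")
        if len(self.table) != len(self.sample_ids):
            raise DataValidationError("covariate row count mismatch")
        if self.table.isna().any().any():
            col = self.table.columns[self.table.isna().any()][0]
            raise DataValidationError(f"missing covariate values in column {col!r}")
        for col in self.table.columns:
            if not np.issubdtype(self.table[col].dtype, np.number):
                raise DataValidationError(f"covariate column {col!r} is not numeric")
        self.table = self.table.reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)

    def matrix(self, names=None) -> np.ndarray:
        cols = self.names if names is None else list(names)
        return self.table[cols].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: expected at least two tab-separated columns")
    return df


def _to_int_matrix(df: pd.DataFrame, sample_col: str, path, missing_code=None,
                   valid=(0, 1, 2)) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    samples = df[sample_col].to_numpy(dtype=object)
    body = df.drop(columns=[sample_col])
    n_imputed = 0
    if missing_code is not None:
        mask = body.to_numpy() == str(missing_code)
        n_imputed = int(mask.sum())
        if n_imputed:
            body = body.mask(pd.DataFrame(mask, index=body.index, columns=body.columns), "0")
            logger.warning("%s: imputed %d missing entries to 0", path, n_imputed)
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r = int(np.argwhere(bad.to_numpy())[0][0])
        c = bad.columns[np.argwhere(bad.to_numpy())[0][1]]
        raise DataValidationError(
            f"{path}: non-integer entry at sample {samples[r]!r}, column {c!r}: "
            f"{body.iloc[r][c]!r}"
        )
    values = numeric.to_numpy()
    if not np.array_equal(values, np.round(values)):
        r, c = np.argwhere(values != np.round(values))[0]
        raise DataValidationError(
            f"{path}: non-integer entry at sample {samples[r]!r}, "
            f"column {body.columns[c]!r}"
        )
    values = values.astype(np.int64)
    out_of_range = ~np.isin(values, valid)
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        raise DataValidationError(
            f"{path}: value {values[r, c]} out of range at sample {samples[r]!r}, "
            f"column {body.columns[c]!r}"
        )
    return samples, body.columns.to_numpy(dtype=object), values, n_imputed


def read_genotypes(path, missing_code=None) -> GenotypeDataset:
    """Read a genotype TSV (header: sample_id, then one column per SNP)."""
    df = _read_tsv(path)
    sample_col = df.columns[0]
    samples, snps, G, n_imputed = _to_int_matrix(df, sample_col, path, missing_code)
    return GenotypeDataset(samples, snps, G, n_imputed=n_imputed)


def read_annotation(path) -> AnnotationTable:
    """Read an annotation TSV (header: snp_id, gene_id, class)."""
    df = _read_tsv(path)
    df = df.rename(columns={df.columns[0]: "snp_id", df.columns[1]: "gene_id",
                            df.columns[2]: "functional_class"})
    return AnnotationTable(df[["snp_id", "gene_id", "functional_class"]])


def read_phenotypes(path, sample_ids=None) -> PhenotypeReplicates:
    """Read phenotype replicates; re-align rows to ``sample_ids`` if given."""
    df = _read_tsv(path)
    sample_col = df.columns[0]
    samples, reps, Y, _ = _to_int_matrix(df, sample_col, path, valid=(0, 1))
    phen = PhenotypeReplicates(samples, reps, Y)
    if sample_ids is not None:
        phen = align_phenotypes(phen, sample_ids)
    return phen


def read_covariates(path, sample_ids=None) -> CovariateTable:
    """Read numeric covariates; re-align rows to ``sample_ids`` if given."""
    df = pd.read_csv(path, sep="\t", comment="#")
    sample_col = df.columns[0]
    samples = df[sample_col].to_numpy(dtype=object)
    body = df.drop(columns=[sample_col])
    for col in body.columns:
        body[col] = pd.to_numeric(body[col], errors="raise")
    cov = CovariateTable(samples, body)
    if sample_ids is not None:
        cov = align_covariates(cov, sample_ids)
    return cov


def _alignment_index(found: np.ndarray, wanted) -> np.ndarray:
    wanted = np.asarray(wanted, dtype=object)
    pos = pd.Series(np.arange(len(found)), index=found)
    missing = ~pd.Index(wanted).isin(pos.index)
    if missing.any():
        raise DataValidationError(
            f"sample ids missing from table: {list(wanted[missing][:5])}"
        )
    if len(found) != len(wanted):
        raise DataValidationError("sample-id sets differ between files")
    return pos.loc[wanted].to_numpy()


def align_phenotypes(phen: PhenotypeReplicates, sample_ids) -> PhenotypeReplicates:
    idx = _alignment_index(phen.sample_ids, sample_ids)
    return PhenotypeReplicates(np.asarray(sample_ids, dtype=object),
                               phen.replicate_ids, phen.Y[idx])


def align_covariates(cov: CovariateTable, sample_ids) -> CovariateTable:
    idx = _alignment_index(cov.sample_ids, sample_ids)
    return CovariateTable(np.asarray(sample_ids, dtype=object),
                          cov.table.iloc[idx].reset_index(drop=True))


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)


def write_genotypes(ds: GenotypeDataset, path) -> None:
    df = pd.DataFrame(ds.G, columns=ds.snp_ids, index=pd.Index(ds.sample_ids, name="sample_id"))
    df.to_csv(path, sep="\t")


def write_annotation(annot: AnnotationTable, path) -> None:
    annot.table.to_csv(path, sep="\t", index=False)


def write_phenotypes(phen: PhenotypeReplicates, path) -> None:
    df = pd.DataFrame(phen.Y, columns=phen.replicate_ids,
                      index=pd.Index(phen.sample_ids, name="sample_id"))
    df.to_csv(path, sep="\t")


def write_covariates(cov: CovariateTable, path) -> None:
    df = cov.table.copy()
    df.insert(0, "sample_id", cov.sample_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# joins and conversion


@dataclass
class JoinReport:
    annotation: AnnotationTable
    n_unannotated_snps: int
    n_annotation_only: int


def join_annotation(dataset: GenotypeDataset, annotation: AnnotationTable) -> JoinReport:
    """Restrict annotation to SNPs present in the genotype matrix.

    Unannotated genotype SNPs are excluded from scoring with a reported count;
    annotation rows for SNPs absent from the genotypes are likewise counted,
    never dropped silently.
    """
    in_data = pd.Index(annotation.table["snp_id"]).isin(dataset.snp_ids)
    n_annotation_only = int((~in_data).sum())
    kept = annotation.table[in_data]
    n_unannot = int((~pd.Index(dataset.snp_ids).isin(kept["snp_id"])).sum())
    if n_annotation_only:
        logger.warning("%d annotation rows refer to SNPs absent from genotypes",
                       n_annotation_only)
    if n_unannot:
        logger.warning("%d genotype SNPs are unannotated and excluded from scoring",
                       n_unannot)
    return JoinReport(AnnotationTable(kept.copy()), n_unannot, n_annotation_only)


def vcf_to_genotypes(path) -> GenotypeDataset:
    """Convert a biallelic VCF (GT field) to a GenotypeDataset.

    Multi-allelic records are skipped; missing genotypes are imputed to 0.
    Requires cyvcf2.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingest requires cyvcf2") from exc

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_imputed = 0
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        counts = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=0)
        n_imputed += int((gt == 2).sum())
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        columns.append(counts.astype(np.int64))
    if not columns:
        raise DataValidationError(f"{path}: no biallelic records found")
    G = np.column_stack(columns)
    return GenotypeDataset(samples, np.asarray(snp_ids, dtype=object), G,
                           n_imputed=n_imputed)
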