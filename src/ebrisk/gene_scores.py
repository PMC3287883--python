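"""Madsen-Browning burden scores per gene.

The score for individual j in gene i is

    X_ij = sum_l G'_lj / sqrt(n * q_l * (1 - q_l))

over the gene's qualifying SNPs, where q_l is the empirical MAF estimated
from all n individuals and G'_lj the folded minor-allele count (G' = 2 - G
when the counted allele has frequency > 0.5, so rare alleles are always the
ones counted).  Weights are strictly decreasing in q on (0, 0.5], so rarer
variants contribute more per copy.  Monomorphic SNPs carry no information
and are excluded; genes left with no polymorphic qualifying SNP are omitted
from the score matrix rather than zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AnnotationTable, DataValidationError, GenotypeDataset, join_annotation

logger = logging.getLogger(__name__)

CLASS_FILTERS = ("all", "synonymous", "nonsynonymous")


@dataclass
class GeneScoreMatrix:
    """Individuals x genes burden-score matrix for one class filter."""

    sample_ids: np.ndarray
    gene_ids: np.ndarray
    X: np.ndarray
    class_filter: str
    snp_summary: pd.DataFrame = field(repr=False)  # snp_id, gene_id, maf, weight
    dropped_genes: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.gene_ids,
                            index=pd.Index(self.sample_ids, name="sample_id"))


def empirical_maf(genotypes, fold: bool = True, pseudocount: bool = False):
    """Empirical minor allele frequency of one SNP column.

    Returns ``(maf, monomorphic)``.  With ``fold`` the frequency is folded to
    ``min(q, 1-q)``; a SNP is monomorphic when the folded frequency is 0.
    """
    g = np.asarray(genotypes)
    n = g.shape[0]
    if n < 1:
        raise DataValidationError("empirical_maf needs at least one individual")
    q = g.sum() / (2 * n)
    if pseudocount:
        q = (g.sum() + 1) / (2 * n + 2)
    if fold:
        q = min(q, 1 - q)
    return float(q), bool(q == 0)


def madsen_browning_scores(dataset: GenotypeDataset, annotation: AnnotationTable,
                           class_filter: str = "all",
                           pseudocount: bool = False) -> GeneScoreMatrix:
    """Compute the weighted burden-score matrix for one functional class."""
    if class_filter not in CLASS_FILTERS:
        raise DataValidationError(f"class_filter must be one of {CLASS_FILTERS}")
    annot = join_annotation(dataset, annotation).annotation.subset_class(class_filter)
    table = annot.table
    if table.empty:
        raise DataValidationError(
            f"no annotated SNPs pass class filter {class_filter!r}")

    n = dataset.n
    col_of = pd.Series(np.arange(dataset.n_snps), index=dataset.snp_ids)
    cols = col_of.loc[table["snp_id"]].to_numpy()
    G = dataset.G[:, cols]

    q = G.sum(axis=0) / (2 * n)
    if pseudocount:
        q = (G.sum(axis=0) + 1) / (2 * n + 2)
    folded = q > 0.5
    if folded.any():
        G = np.where(folded[None, :], 2 - G, G)
        q = np.where(folded, 1 - q, q)
    polymorphic = q > 0
    n_mono = int((~polymorphic).sum())
    if n_mono:
        logger.info("excluding %d monomorphic SNPs from %s scores", n_mono, class_filter)

    genes = table["gene_id"].to_numpy(dtype=object)
    snps = table["snp_id"].to_numpy(dtype=object)
    keep = polymorphic
    all_genes = pd.unique(genes)

    genes, snps, q, G = genes[keep], snps[keep], q[keep], G[:, keep]
    weights = 1.0 / np.sqrt(n * q * (1 - q))

    # sum weighted counts per gene via reduceat on gene-sorted columns
    order = np.argsort(genes, kind="stable")
    genes_s, snps_s, q_s, w_s = genes[order], snps[order], q[order], weights[order]
    Gw = G[:, order] * w_s[None, :]
    gene_ids, starts = np.unique(genes_s, return_index=True)
    if len(gene_ids) == 0:
        raise DataValidationError(
            f"all SNPs monomorphic under class filter {class_filter!r}")
    X = np.add.reduceat(Gw, starts, axis=1)

    dropped = sorted(set(all_genes) - set(gene_ids))
    if dropped:
        logger.info("genes with no polymorphic qualifying SNPs omitted: %s", dropped)

    summary = pd.DataFrame({"snp_id": snps_s, "gene_id": genes_s,
                            "maf": q_s, "weight": w_s})
    return GeneScoreMatrix(dataset.sample_ids, gene_ids.astype(object), X,
                           class_filter, summary, dropped)


def write_scores(scores: GeneScoreMatrix, path, summary_path=None) -> None:
    scores.to_frame().to_csv(path, sep="\t")
    if summary_path is not None:
        scores.snp_summary.to_csv(summary_path, sep="\t", index=False)
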