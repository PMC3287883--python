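"""Synthetic mini-exome datasets with known ground truth.

Structure emulated: a rare-skewed MAF spectrum (Beta(0.1, 2) truncated to
[1/(2n), 0.5], so most SNPs are rare), genes of 1-40 independent SNPs with
mixed synonymous/nonsynonymous annotation, covariates (Age, Sex, Smoke)
shared across replicates, and phenotype replicates redrawn on the fixed
genotypes.  Disease status follows a liability threshold: a fixed genetic
plus covariate liability, fresh N(0,1) noise per replicate, cases above the
per-replicate empirical quantile matching the target prevalence.  Because
genotypes and covariates are fixed while only the noise is redrawn, case
sets overlap across replicates and per-gene Z statistics are positively
correlated — the structure the replicate-correlation correction targets.

Causal genes act through their standardized nonsynonymous burden score by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (AnnotationTable, CovariateTable, GenotypeDataset,
                      PhenotypeReplicates, write_annotation, write_covariates,
                      write_genotypes, write_phenotypes)
from .gene_scores import madsen_browning_scores


@dataclass
class SimConfig:
    n: int = 700
    n_genes: int = 500
    snps_per_gene: tuple = (1, 40)
    maf_beta: tuple = (0.1, 2.0)
    maf_min: float | None = None          # default 1/(2n)
    maf_max: float = 0.5
    frac_nonsyn: float = 0.6
    n_causal: int = 0
    effect_size: float | list = 1.5       # per causal gene, liability scale
    covariate_effects: dict = field(default_factory=lambda: {
        "Age": 0.0, "Sex": 0.0, "Smoke": 0.0})
    prevalence: float = 0.3
    R: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal cannot exceed n_genes")
        if not 0 <= self.frac_nonsyn <= 1:
            raise ValueError("frac_nonsyn must be in [0, 1]")

    def effects(self) -> np.ndarray:
        e = self.effect_size
        if np.isscalar(e):
            return np.full(self.n_causal, float(e))
        e = np.asarray(e, dtype=float)
        if len(e) != self.n_causal:
            raise ValueError("effect_size list length must equal n_causal")
        return e

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snps_per_gene"] = list(self.snps_per_gene)
        d["maf_beta"] = list(self.maf_beta)
        if not np.isscalar(d["effect_size"]):
            d["effect_size"] = list(map(float, d["effect_size"]))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "snps_per_gene" in d:
            d["snps_per_gene"] = tuple(d["snps_per_gene"])
        if "maf_beta" in d:
            d["maf_beta"] = tuple(d["maf_beta"])
        return cls(**d)


@dataclass
class GroundTruth:
    causal_genes: list
    effects: list
    covariate_effects: dict
    case_counts: list

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _draw_maf(config: SimConfig, size: int, rng) -> np.ndarray:
    lo = config.maf_min if config.maf_min is not None else 1.0 / (2 * config.n)
    a, b = config.maf_beta
    maf = rng.beta(a, b, size=size)
    # redraw values above the cap; floor the low tail at lo (keeping its mass
    # at the rarest observable frequency preserves the rare-skewed spectrum)
    for _ in range(1000):
        bad = maf > config.maf_max
        if not bad.any():
            break
        maf[bad] = rng.beta(a, b, size=int(bad.sum()))
    return np.clip(maf, lo, config.maf_max)


def simulate_genotypes(config: SimConfig, rng=None):
    """Draw genotypes Binomial(2, MAF) i.i.d. and a gene/class annotation."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo_k, hi_k = config.snps_per_gene
    snps_per_gene = rng.integers(lo_k, hi_k + 1, size=config.n_genes)
    p = int(snps_per_gene.sum())
    maf = _draw_maf(config, p, rng)
    G = rng.binomial(2, maf[None, :], size=(config.n, p)).astype(np.int64)

    snp_ids = np.array([f"snp{i:06d}" for i in range(p)], dtype=object)
    gene_ids = np.repeat([f"gene{i:04d}" for i in range(config.n_genes)],
                         snps_per_gene).astype(object)
    nonsyn = rng.random(p) < config.frac_nonsyn
    classes = np.where(nonsyn, "nonsynonymous", "synonymous").astype(object)

    sample_ids = np.array([f"s{j:04d}" for j in range(config.n)], dtype=object)
    dataset = GenotypeDataset(sample_ids, snp_ids, G)
    annot = AnnotationTable(pd.DataFrame({
        "snp_id": snp_ids, "gene_id": gene_ids, "functional_class": classes}))
    return dataset, annot


def simulate_phenotypes(dataset: GenotypeDataset, annot: AnnotationTable,
                        config: SimConfig, rng=None):
    """Liability-threshold phenotype replicates on fixed genotypes/covariates."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = dataset.n

    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n)
    smoke = (rng.random(n) < 0.3).astype(int)
    cov = CovariateTable(dataset.sample_ids, pd.DataFrame({
        "Age": age, "Sex": sex.astype(float), "Smoke": smoke.astype(float)}))

    ce = config.covariate_effects
    base = (ce.get("Age", 0.0) * (age - 50.0) / 10.0
            + ce.get("Sex", 0.0) * sex
            + ce.get("Smoke", 0.0) * smoke)

    if config.n_causal > 0:
        # eligible genes must have a polymorphic nonsynonymous burden
        nonsyn_scores = madsen_browning_scores(dataset, annot, "nonsynonymous")
        variable = nonsyn_scores.X.std(axis=0) > 0
        eligible = nonsyn_scores.gene_ids[variable]
        if len(eligible) < config.n_causal:
            raise ValueError("not enough genes with polymorphic nonsynonymous SNPs")
        causal = sorted(rng.choice(eligible, size=config.n_causal, replace=False),
                        key=str)
        frame = nonsyn_scores.to_frame()[list(causal)]
        B = ((frame - frame.mean()) / frame.std(ddof=0)).to_numpy()
        effects = config.effects()
        base = base + B @ effects
    else:
        causal, effects = [], np.zeros(0)

    Y = np.empty((n, config.R), dtype=np.int8)
    case_counts = []
    for r in range(config.R):
        liab = base + rng.normal(size=n)
        thresh = np.quantile(liab, 1.0 - config.prevalence)
        y = (liab > thresh).astype(np.int8)
        n1 = int(y.sum())
        if n1 == 0 or n1 == n:
            raise ValueError(f"replicate {r}: unattainable prevalence "
                             f"{config.prevalence} ({n1} cases of {n})")
        Y[:, r] = y
        case_counts.append(n1)

    phen = PhenotypeReplicates(dataset.sample_ids,
                               np.array([f"rep{r + 1}" for r in range(config.R)],
                                        dtype=object), Y)
    truth = GroundTruth([str(g) for g in causal], list(map(float, effects)),
                        dict(ce), case_counts)
    return phen, cov, truth


def simulate_dataset(config: SimConfig):
    """One-call generator: (genotypes, annotation, phenotypes, covariates, truth)."""
    rng = np.random.default_rng(config.seed)
    geno, annot = simulate_genotypes(config, rng)
    phen, cov, truth = simulate_phenotypes(geno, annot, config, rng)
    return geno, annot, phen, cov, truth


def generate_dataset(config: SimConfig, outdir) -> dict:
    """Write the four TSVs plus ground_truth.json; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno, annot, phen, cov, truth = simulate_dataset(config)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "annotation": outdir / "annotation.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "covariates": outdir / "covariates.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "sim_config.json",
    }
    write_genotypes(geno, paths["genotypes"])
    write_annotation(annot, paths["annotation"])
    write_phenotypes(phen, paths["phenotypes"])
    write_covariates(cov, paths["covariates"])
    paths["ground_truth"].write_text(truth.to_json())
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}
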