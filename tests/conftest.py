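import numpy as np
import pandas as pd
import pytest

from ebrisk.data_io import (AnnotationTable, CovariateTable, GenotypeDataset,
                            PhenotypeReplicates)
from ebrisk.synthetic import SimConfig, simulate_dataset


@pytest.fixture
def tiny_genotypes():
    """3 samples x 2 SNPs with hand-written entries ((0,1),(2,0),(1,1))."""
    return GenotypeDataset(
        sample_ids=["a", "b", "c"],
        snp_ids=["snpA", "snpB"],
        G=np.array([[0, 1], [2, 0], [1, 1]]),
    )


@pytest.fixture
def tiny_annotation():
    return AnnotationTable(pd.DataFrame({
        "snp_id": ["snpA", "snpB"],
        "gene_id": ["g1", "g1"],
        "functional_class": ["nonsynonymous", "synonymous"],
    }))


def write_tiny_files(tmp_path, genotypes, annotation):
    from ebrisk.data_io import write_annotation, write_genotypes
    gpath = tmp_path / "genotypes.tsv"
    apath = tmp_path / "annotation.tsv"
    write_genotypes(genotypes, gpath)
    write_annotation(annotation, apath)
    return gpath, apath


@pytest.fixture(scope="session")
def sim_bundle():
    """Moderate simulated dataset with signal, reused across test modules."""
    cfg = SimConfig(n=300, n_genes=80, snps_per_gene=(1, 20), R=10,
                    n_causal=3, effect_size=1.5,
                    covariate_effects={"Age": 0.4, "Sex": 0.1, "Smoke": 0.6},
                    prevalence=0.3, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_null_bundle():
    """Pure-null simulated dataset (no causal genes, no covariate effects)."""
    cfg = SimConfig(n=250, n_genes=2000, snps_per_gene=(1, 8), R=8,
                    n_causal=0, covariate_effects={"Age": 0, "Sex": 0, "Smoke": 0},
                    prevalence=0.3, seed=11)
    return simulate_dataset(cfg)
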