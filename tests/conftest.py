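import numpy as np
import pytest

from aspenscan.demography import DemographicModel, SampleConfig
from aspenscan.genotype_io import GenotypeMatrix


@pytest.fixture(scope="session")
def one_pop_model():
    return DemographicModel(populations=["A"], Ne={"A": 1000.0})


@pytest.fixture(scope="session")
def two_pop_model():
    """2-population IM model with migration and an ancestral size change."""
    return DemographicModel(
        populations=["A", "B"],
        Ne={"A": 1000.0, "B": 500.0},
        splits=[(2000.0, "B", "A")],
        migration={("A", "B"): 1e-4, ("B", "A"): 5e-4},
        size_changes={"A": [(2000.0, 3000.0)]},
    )


@pytest.fixture(scope="session")
def three_pop_model():
    """Scaled-down three-population IM topology (N,C,S + outgroup)."""
    return DemographicModel(
        populations=["N", "C", "S", "OUT"],
        Ne={"N": 8000.0, "C": 10000.0, "S": 3000.0, "OUT": 10000.0},
        splits=[(2000.0, "C", "N"), (12000.0, "N", "S"), (400000.0, "OUT", "S")],
        migration={
            ("C", "N"): 2e-4, ("N", "C"): 1e-4,
            ("S", "N"): 1e-5, ("N", "S"): 1e-5,
            ("S", "C"): 1e-4, ("C", "S"): 5e-5,
        },
        size_changes={"S": [(12000.0, 20000.0)]},
    )


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory, three_pop_model):
    """A small simulated dataset shared by I/O and scan tests."""
    from aspenscan.coalescent_sim import simulate_dataset

    out = tmp_path_factory.mktemp("sim") / "sim"
    cfg = SampleConfig({"N": 8, "C": 8, "S": 8, "OUT": 2})
    truth = simulate_dataset(three_pop_model, cfg, n_windows=40, out_prefix=str(out), seed=5)
    return {
        "prefix": str(out),
        "vcf": f"{out}.vcf",
        "popmap": f"{out}.popmap.tsv",
        "bed": f"{out}.windows.bed",
        "truth": truth,
        "model": three_pop_model,
        "config": cfg,
    }


def make_gm(genotypes, gq=None, positions=None, contig="chr1", n_alleles=None,
            haplotypes=None, sample_prefix="s"):
    """Small GenotypeMatrix from a (samples x sites) dosage list."""
    g = np.array(genotypes, dtype=np.int8)
    ns, S = g.shape
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(ns)],
        contigs=np.array([contig] * S, dtype=object),
        positions=(
            np.arange(1, S + 1, dtype=np.int64) if positions is None
            else np.array(positions, dtype=np.int64)
        ),
        ref_allele=np.array(["A"] * S, dtype=object),
        alt_allele=np.array(["T"] * S, dtype=object),
        genotypes=g,
        gq=None if gq is None else np.array(gq, dtype=np.int16),
        n_alleles=(
            None if n_alleles is None else np.array(n_alleles, dtype=np.int16)
        ),
        haplotypes=None if haplotypes is None else np.array(haplotypes, dtype=np.int8),
    )
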