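import numpy as np
import pytest

from gbcpipe.model import Cohort, GeneModel, SomaticMutation
from gbcpipe.simulate import GeneSpec, SimulationConfig, generate_cohort


def make_cds(n_codons: int, seed: int = 0) -> str:
    """Random stop-free CDS of n_codons codons (incl. ATG and final TAA)."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops and c != "ATG":
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


@pytest.fixture
def toy_gene() -> GeneModel:
    # ATG AAA CAA GGG CTT TGC CCA TAA  ->  M K Q G L C P *
    return GeneModel("TOY", "ATGAAACAAGGGCTTTGCCCATAA", flank5="TT", flank3="GC")


@pytest.fixture
def toy_cohort(toy_gene) -> Cohort:
    muts = [
        SomaticMutation("m1", "S1", "TOY", 7, "SNV", "popA",
                        ref_base="C", alt_base="T", expressed_read_count=5),
        SomaticMutation("m2", "S2", "TOY", 11, "DEL", "popB",
                        del_length=1, expressed_read_count=3),
    ]
    return Cohort(
        samples=[("S1", "popA"), ("S2", "popB")],
        mutations=muts,
        gene_models={"TOY": toy_gene},
    )


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast, reduced cohort keeping the generator's full structure."""
    defaults = dict(
        seed=seed,
        n_samples={"India": 12, "Korea": 18},
        genes=[GeneSpec("ELF3", 120), GeneSpec("TP53", 130), GeneSpec("NFE2L2", 110),
               GeneSpec("KEAP1", 100), GeneSpec("OTHER", 140)],
        burden_mean=4.0,
        n_filler_expression_genes=5,
        n_clonotypes=40,
        clonotype_reads=800,
        n_msi_samples=1,
        msi_burden=60,
        rate_overrides={"NFE2L2": 0.3, "KEAP1": 0.3},
        frameshift_rate={"India": 0.1, "Korea": 0.4},
        frameshift_hotspot_codon=60,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort_and_truth():
    return generate_cohort(small_sim_config(seed=7))


@pytest.fixture
def small_cohort(small_cohort_and_truth):
    return small_cohort_and_truth[0]
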