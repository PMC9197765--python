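import numpy as np
import pytest

from famimpute.pedigree import build_families
from famimpute.simulate import SimConfig, run_simulation


def hide_parents(sim):
    """Mark simulated parents as ungenotyped (the typical sib-pair setting)."""
    ped = sim.pedigree
    ped.table["genotyped"] = ~ped.table.individual_id.str.startswith(
        ("father", "mother"))
    genotyped = set(ped.table.loc[ped.table.genotyped, "individual_id"])
    return build_families(ped, genotyped)


@pytest.fixture(scope="session")
def sib_sim():
    """400 sibling-pair families, 300 SNPs, direct effects only."""
    return run_simulation(SimConfig(n_families=400, n_snps=300,
                                    h2_direct=0.4, seed=101))


@pytest.fixture(scope="session")
def sib_families(sib_sim):
    return hide_parents(sib_sim)


@pytest.fixture(scope="session")
def dense_sim():
    """Dense map for IBD accuracy checks: one SNP per 0.02 cM."""
    return run_simulation(SimConfig(n_families=30, n_snps=3000,
                                    chrom_length_cM=60.0, h2_direct=0.4,
                                    seed=77))
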