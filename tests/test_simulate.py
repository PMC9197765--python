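import numpy as np
import pytest

from famimpute.genio import MISSING
from famimpute.simulate import (SimConfig, mate_assortatively, run_simulation,
                                simulate_meiosis)


def test_same_seed_reproduces_identically():
    cfg = SimConfig(n_families=50, n_snps=80, h2_direct=0.4, seed=9)
    a = run_simulation(cfg)
    b = run_simulation(cfg)
    assert np.array_equal(a.gset.haplotypes, b.gset.haplotypes)
    assert a.phenotypes.values == b.phenotypes.values


def test_mendelian_consistency_of_trios():
    sim = run_simulation(SimConfig(n_families=100, n_snps=60, seed=10))
    H = sim.gset.haplotypes
    idx = sim.gset.index_of
    for rec in sim.families.itertuples():
        fa, mo = H[idx(rec.father)], H[idx(rec.mother)]
        for child in (rec.offspring1, rec.offspring2):
            c = H[idx(child)]
            # paternal allele (haplotype 0) must occur in the father, etc.
            assert np.all((c[:, 0] == fa[:, 0]) | (c[:, 0] == fa[:, 1]))
            assert np.all((c[:, 1] == mo[:, 0]) | (c[:, 1] == mo[:, 1]))


def test_recorded_ibd_matches_genotype_sharing():
    sim = run_simulation(SimConfig(n_families=50, n_snps=100, seed=11))
    H = sim.gset.haplotypes
    idx = sim.gset.index_of
    for (o1, o2), path in sim.true_ibd.items():
        g1, g2 = H[idx(o1)], H[idx(o2)]
        ibd2 = path.states == 2
        assert np.all(g1.sum(1)[ibd2] == g2.sum(1)[ibd2])
        ibd1 = path.states == 1
        opp = (np.minimum(g1.sum(1), g2.sum(1)) == 0) \
            & (np.maximum(g1.sum(1), g2.sum(1)) == 2)
        assert not np.any(opp[ibd1])


def test_meiosis_crossover_rate():
    rng = np.random.default_rng(12)
    pos = np.linspace(0, 1.0, 10)  # 1 cM map
    parent = rng.integers(0, 2, size=(10, 2)).astype(np.int8)
    n_with_xo = sum(
        len(simulate_meiosis(parent, pos, rng)[2]) > 0 for _ in range(20000))
    # P(>= 1 crossover) = 1 - exp(-0.01) ~ 0.00995
    p = n_with_xo / 20000
    assert p == pytest.approx(1 - np.exp(-0.01), abs=3 * np.sqrt(0.01 / 20000))


def test_homozygous_parent_gamete_deterministic():
    rng = np.random.default_rng(13)
    parent = np.ones((20, 2), dtype=np.int8)
    gam, _, _ = simulate_meiosis(parent, np.linspace(0, 50, 20), rng)
    assert np.all(gam == 1)


def test_assortative_mating_calibration():
    rng = np.random.default_rng(14)
    y = rng.normal(size=10000)
    _, realized = mate_assortatively(y, 0.5, rng)
    assert 0.46 <= realized <= 0.54
    _, r0 = mate_assortatively(y, 0.0, rng)
    assert abs(r0) < 0.05
    with pytest.raises(ValueError):
        mate_assortatively(y, 1.0, rng)


def test_am_induces_spousal_genetic_correlation():
    sim = run_simulation(SimConfig(n_families=2000, n_snps=300,
                                   h2_direct=0.5, am_target_corr=0.6,
                                   n_generations=5, seed=15))
    assert sim.realized_r_am > 0.1


def test_vertical_transmission_reaches_equilibrium():
    corrs = []
    for gens in (6, 10):
        sim = run_simulation(SimConfig(n_families=3000, n_snps=100,
                                       h2_direct=0.3, v_vt=0.3,
                                       n_generations=gens, seed=16))
        y_o = np.array([sim.phenotypes[r.offspring1]
                        for r in sim.families.itertuples()])
        y_p = np.array([sim.phenotypes[r.father] + sim.phenotypes[r.mother]
                        for r in sim.families.itertuples()])
        corrs.append(np.corrcoef(y_o, y_p)[0, 1])
    assert abs(corrs[1] - corrs[0]) < 0.05  # stabilized across generations


def test_stratified_config_realizes_structure():
    sim = run_simulation(SimConfig(n_families=500, n_snps=200, n_demes=2,
                                   fst=0.05, deme_offset_sd=0.5, seed=17))
    assert sim.realized_fst > 0.01


def test_direct_only_population_effect_identity():
    """Under random mating with parental IGEs, the simple genotype-phenotype
    regression slope approximates delta + alpha per SNP (averaged over SNPs)."""
    sim = run_simulation(SimConfig(n_families=4000, n_snps=120,
                                   h2_direct=0.3, share_parental_ige=0.1,
                                   cor_direct_parental=1.0, seed=18))
    gset = sim.gset
    off = [i for i in gset.individual_ids if i.startswith("off_")]
    G = gset.genotypes().astype(float)[[gset.index_of(i) for i in off]]
    y = np.array([sim.phenotypes[i] for i in off])
    Gc = G - G.mean(0)
    slopes = Gc.T @ (y - y.mean()) / (Gc ** 2).sum(0)
    # beta = delta + (alpha_p + alpha_m)/2 and the simulator applies the
    # same per-SNP IGE weight to each parent, so beta = delta + alpha
    want = sim.true_delta + sim.true_alpha
    # regress realized slopes on expectations: slope ~ 1
    fit = np.polyfit(want, slopes, 1)[0]
    assert fit == pytest.approx(1.0, abs=0.15)


def test_ascertainment_pushes_rdelta_alpha_negative():
    """Selecting families on phenotype induces collider bias: with truly
    uncorrelated direct and parental effects, the estimated effect
    correlation r(direct, NTC) goes negative."""
    from famimpute.famlmm import gwas
    from famimpute.impute import impute_families
    from famimpute.sumcor import effect_correlation_from_sumstats
    from conftest import hide_parents

    def run(ascertain, seed):
        sim = run_simulation(SimConfig(
            n_families=4000, n_snps=400, h2_direct=0.3,
            share_parental_ige=0.15, cor_direct_parental=0.0,
            ascertain=ascertain, ascertain_slope=8.0, ascertain_center=0.6,
            seed=seed))
        fams = hide_parents(sim)
        imputed = impute_families(sim.gset, fams, sim.true_ibd, phased=True)
        rows = gwas(sim.gset, fams, imputed, sim.phenotypes)
        return effect_correlation_from_sumstats(rows, "direct", "alpha",
                                                n_blocks=40)

    est = run(True, 19)
    assert est.r_hat < 0
    assert est.r_hat + 2 * est.se < 0.15  # clearly pushed below the truth 0
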