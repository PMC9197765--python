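import numpy as np
import pytest

from famimpute.experiments import (draw_sib_pairs, fit_imputed_sibpair,
                                   _sib_phenotypes, _stack_pairs)
from famimpute.famlmm import (DesignSpec, Model, VarianceComponents,
                              assemble_design, estimate_snp_effects,
                              fit_null_varcomps, population_effect,
                              robust_split_estimate, sibdiff_estimate)
from famimpute.impute import impute_families


def test_varcomp_recovery():
    rng = np.random.default_rng(0)
    n = 5000
    fam = np.repeat(np.arange(n), 2)
    y = np.repeat(rng.normal(0, np.sqrt(0.3), n), 2) \
        + rng.normal(0, np.sqrt(0.7), 2 * n)
    vc = fit_null_varcomps(y, fam)
    # SEs of ML variance components at n = 5000 pairs are ~0.01
    assert vc.sigma2_F == pytest.approx(0.3, abs=0.04)
    assert vc.sigma2_e == pytest.approx(0.7, abs=0.04)


def test_varcomp_independent_phenotypes_give_zero_family_variance():
    rng = np.random.default_rng(1)
    fam = np.repeat(np.arange(2000), 2)
    vc = fit_null_varcomps(rng.normal(size=4000), fam)
    assert vc.r < 0.05


def test_varcomp_duplicated_sib_phenotypes_drive_r_to_bound():
    rng = np.random.default_rng(2)
    y = np.repeat(rng.normal(size=1000), 2)
    vc = fit_null_varcomps(y, np.repeat(np.arange(1000), 2))
    assert vc.r > 0.95


def test_varcomp_no_sibships_warns():
    rng = np.random.default_rng(3)
    with pytest.warns(UserWarning, match="sigma_F"):
        vc = fit_null_varcomps(rng.normal(size=100), np.arange(100))
    assert vc.sigma2_F == 0.0


def test_gls_equals_ols_when_family_variance_zero():
    rng = np.random.default_rng(4)
    n = 500
    X = rng.normal(size=(2 * n, 2))
    y = X @ [0.5, -0.2] + rng.normal(size=2 * n)
    fam = np.repeat(np.arange(n), 2)
    est = estimate_snp_effects(y, X, fam, VarianceComponents(0.0, 1.0),
                               ("a", "b"))
    Xc = X - X.mean(axis=0)
    ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
    np.testing.assert_allclose(est.estimates, ols, atol=1e-10)


def test_trio_effect_recovery_within_3se():
    rng = np.random.default_rng(5)
    n = 20000
    f = 0.3
    par = (rng.random((n, 4)) < f).astype(float)
    g_o = par[np.arange(n), rng.integers(0, 2, n)] \
        + par[np.arange(n), 2 + rng.integers(0, 2, n)]
    g_p, g_m = par[:, 0] + par[:, 1], par[:, 2] + par[:, 3]
    true = np.array([0.1, 0.05, 0.0])
    y = np.column_stack([g_o, g_p, g_m]) @ true + rng.normal(size=n)
    est = estimate_snp_effects(y, np.column_stack([g_o, g_p, g_m]),
                               np.arange(n), VarianceComponents(0, 1.0),
                               ("direct", "alpha_p", "alpha_m"))
    for lab, t in zip(est.labels, true):
        assert abs(est.get(lab) - t) < 3 * est.se(lab)


def test_sibling_ige_separately_identified():
    """With the imputed parental sum in the model, delta and eta_s are
    separately estimable from sibling pairs (the sib-difference method only
    sees delta - eta_s)."""
    rng = np.random.default_rng(6)
    s = draw_sib_pairs(30000, 0.3, rng)
    y1, y2 = _sib_phenotypes(s, delta=0.1, eta_s=0.05, alpha=0.0, r=0.2,
                             rng=rng)
    est = fit_imputed_sibpair(s, y1, y2, r=0.2, with_sib=True)
    assert abs(est.get("direct") - 0.1) < 3 * est.se("direct")
    assert abs(est.get("eta_s") - 0.05) < 3 * est.se("eta_s")


def test_population_effect_arithmetic():
    from famimpute.famlmm import EffectEstimate
    est = EffectEstimate(("direct", "alpha_p", "alpha_m"),
                         np.array([0.10, 0.05, 0.03]), np.eye(3) * 4e-4)
    beta, var = population_effect(est)
    assert beta == pytest.approx(0.14)
    assert var == pytest.approx(4e-4 + (4e-4 + 4e-4) / 4)
    est2 = EffectEstimate(("direct", "alpha"), np.array([0.10, 0.04]),
                          np.eye(2) * 4e-4)
    assert population_effect(est2)[0] == pytest.approx(0.14)


def test_sibdiff_estimates_delta_minus_eta():
    rng = np.random.default_rng(7)
    for eta in (0.0, 0.05):
        s = draw_sib_pairs(30000, 0.3, rng)
        y1, y2 = _sib_phenotypes(s, 0.1, eta, 0.0, 0.0, rng)
        est, se = sibdiff_estimate(np.column_stack([y1, y2]),
                                   np.column_stack([s.g1, s.g2]))
        assert abs(est - (0.1 - eta)) < 3 * se


def test_sibdiff_undefined_for_identical_genotypes():
    with pytest.raises(ValueError, match="genotype variation"):
        sibdiff_estimate(np.zeros((10, 2)), np.ones((10, 2)))


def test_robust_split_single_group_reduces_to_gls():
    rng = np.random.default_rng(8)
    s = draw_sib_pairs(4000, 0.3, rng)
    y1, y2 = _sib_phenotypes(s, 0.1, 0.0, 0.0, 0.0, rng)
    y, X, fam = _stack_pairs(y1, y2, (s.g1, s.ghat_phased),
                             (s.g2, s.ghat_phased))
    vc = VarianceComponents(0, 1.0)
    delta, se = robust_split_estimate(
        {3: (y, X, fam, ("direct", "alpha"))}, vc)
    ref = estimate_snp_effects(y, X, fam, vc, ("direct", "alpha"))
    assert delta == pytest.approx(ref.get("direct"), abs=1e-10)


def test_robust_split_merges_small_groups():
    rng = np.random.default_rng(9)
    s = draw_sib_pairs(2000, 0.3, rng)
    y1, y2 = _sib_phenotypes(s, 0.1, 0.0, 0.0, 0.0, rng)
    big = _stack_pairs(y1[:-10], y2[:-10],
                       (s.g1[:-10], s.ghat_phased[:-10]),
                       (s.g2[:-10], s.ghat_phased[:-10]))
    small = _stack_pairs(y1[-10:], y2[-10:],
                         (s.g1[-10:], s.ghat_phased[-10:]),
                         (s.g2[-10:], s.ghat_phased[-10:]))
    labels = ("direct", "alpha")
    with pytest.warns(UserWarning, match="merged"):
        robust_split_estimate({4: (*big, labels), 3: (*small, labels)},
                              VarianceComponents(0, 1.0))


# ---------------------------------------------------------------------------
# design assembly per data type
# ---------------------------------------------------------------------------

def _design_for(sim, families, fam, spec):
    imputed = impute_families(sim.gset, families, sim.true_ibd, phased=True)
    return assemble_design(fam, 0, sim.gset, imputed, spec)


def test_assemble_design_sib_pair_columns(sib_sim, sib_families):
    fam = sib_families[0]
    X, labels, ids = _design_for(sib_sim, sib_families, fam,
                                 DesignSpec(Model.WITH_SIB_IGE,
                                            separate_ntc=False))
    assert labels == ("direct", "eta_s", "alpha")
    assert X.shape == (2, 3)
    G = sib_sim.gset.genotypes()
    assert X[0, 0] == G[sib_sim.gset.index_of(ids[0]), 0]
    assert X[0, 1] == G[sib_sim.gset.index_of(ids[1]), 0]
    assert X[0, 2] == X[1, 2]  # shared imputed parental sum


def test_assemble_design_proband_only_label():
    import pandas as pd

    from famimpute.genio import PedigreeTable, PhasedGenotypeSet, VariantInfo
    from famimpute.pedigree import build_families
    haps = np.zeros((1, 2, 2), dtype=np.int8)
    haps[0, :, 0] = 1
    gset = PhasedGenotypeSet(["solo"], [VariantInfo("v0", "1", 1, freq=0.5),
                                        VariantInfo("v1", "1", 2, freq=0.5)],
                             haps)
    ped = PedigreeTable(pd.DataFrame([("solo", "", "")], columns=[
        "individual_id", "father_id", "mother_id"]))
    fam = build_families(ped, {"solo"})[0]
    X, labels, ids = assemble_design(fam, 0, gset, {}, DesignSpec())
    assert labels == ("direct_plus_avg_ntc",)
    assert X.shape == (1, 1)


def test_assemble_design_trio_and_quad(trio_quad_setup):
    gset, families, imputed = trio_quad_setup
    by_class = {f.design_class.name: f for f in families}
    X, labels, _ = assemble_design(by_class["TRIO"], 0, gset, imputed,
                                   DesignSpec(Model.NO_SIB_IGE))
    assert labels == ("direct", "alpha_p", "alpha_m")
    Xq, labq, _ = assemble_design(by_class["QUAD_BOTH_PARENTS_SIBS"], 0, gset,
                                  imputed, DesignSpec(Model.WITH_SIB_IGE))
    assert labq == ("direct", "eta_s", "alpha_p", "alpha_m")
    assert Xq.shape[1] == 4


@pytest.fixture()
def trio_quad_setup():
    import pandas as pd

    from famimpute.genio import PedigreeTable, PhasedGenotypeSet, VariantInfo
    from famimpute.pedigree import build_families
    rng = np.random.default_rng(10)
    ids = ["p1", "m1", "c1", "p2", "m2", "c2", "c3"]
    haps = rng.integers(0, 2, size=(7, 3, 2)).astype(np.int8)
    variants = [VariantInfo(f"v{j}", "1", j + 1, freq=0.5) for j in range(3)]
    gset = PhasedGenotypeSet(ids, variants, haps)
    ped = PedigreeTable(pd.DataFrame([
        ("p1", "", ""), ("m1", "", ""), ("c1", "p1", "m1"),
        ("p2", "", ""), ("m2", "", ""), ("c2", "p2", "m2"),
        ("c3", "p2", "m2"),
    ], columns=["individual_id", "father_id", "mother_id"]))
    families = build_families(ped, set(ids))
    return gset, families, {}


def test_mother_child_pair_uses_imputed_father(sib_sim):
    """Mother-child pairs regress on (g_child, imputed father, g_mother)."""
    import pandas as pd

    from famimpute.genio import PedigreeTable
    from famimpute.pedigree import build_families
    ped = sib_sim.pedigree
    tab = ped.table.copy()
    tab["genotyped"] = ~tab.individual_id.str.startswith("father") \
        & ~tab.individual_id.str.endswith("_2")
    ped2 = PedigreeTable(tab)
    genotyped = set(tab.loc[tab.genotyped, "individual_id"])
    fams = build_families(ped2, genotyped)
    from famimpute.pedigree import DesignClass
    po = [f for f in fams
          if f.design_class == DesignClass.ONE_PARENT_ONE_OFFSPRING]
    assert po, "expected mother-child pairs"
    imputed = impute_families(sib_sim.gset, fams, {}, phased=True)
    X, labels, _ = assemble_design(po[0], 0, sib_sim.gset, imputed,
                                   DesignSpec(Model.NO_SIB_IGE))
    assert labels == ("direct", "alpha_p", "alpha_m")
    from famimpute.impute import ImputedKind
    assert imputed[po[0].family_id].kind == ImputedKind.FATHER
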