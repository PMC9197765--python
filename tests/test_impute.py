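import itertools

import numpy as np
import pytest

from famimpute.impute import (ImputedKind, SibPairSnpView,
                              imputation_diagnostics, impute_families,
                              impute_parent_from_parent_offspring,
                              impute_parent_from_sibs_and_parent,
                              impute_parsum_nsibs, impute_parsum_sibs,
                              linear_impute_baseline, resolve_shared_allele)
from famimpute.pedigree import DesignClass


# ---------------------------------------------------------------------------
# exact enumeration oracle over parental alleles x transmissions
# ---------------------------------------------------------------------------

def _family_draws(f):
    """All (weight, parental alleles, transmissions) configurations."""
    for alleles in itertools.product((0, 1), repeat=4):
        w0 = np.prod([f if a else 1 - f for a in alleles])
        for trans in itertools.product((0, 1), repeat=4):
            yield w0 / 16.0, alleles, trans


def _sib_imputation_moments(f, phased):
    ws, vals, gpars, ibds = [], [], [], []
    for w, (p1, p2, m1, m2), (x1, y1, x2, y2) in _family_draws(f):
        g1 = (p1, p2)[x1] + (m1, m2)[y1]
        g2 = (p1, p2)[x2] + (m1, m2)[y2]
        ibd = int(x1 == x2) + int(y1 == y2)
        ns2 = (m1, m2)[y2] if x1 == x2 else (p1, p2)[x2]
        view = SibPairSnpView(g1, g2, ibd,
                              g2_notshared=ns2 if phased else None)
        ws.append(w)
        vals.append(impute_parsum_sibs(view, f))
        gpars.append(p1 + p2 + m1 + m2)
        ibds.append(ibd)
    ws = np.array(ws)
    vals = np.array(vals)
    gpars = np.array(gpars, dtype=float)
    return ws, vals, gpars, np.array(ibds)


def _moments(ws, a, b):
    mu_a, mu_b = ws @ a, ws @ b
    var_a = ws @ (a - mu_a) ** 2
    var_b = ws @ (b - mu_b) ** 2
    cov = ws @ ((a - mu_a) * (b - mu_b))
    return cov / var_a, cov ** 2 / (var_a * var_b)  # slope of b on a, R^2


@pytest.mark.parametrize("f", [0.1, 0.3, 0.5])
def test_sibpair_phased_unbiased_with_r2_three_quarters(f):
    ws, vals, gpars, _ = _sib_imputation_moments(f, phased=True)
    slope, r2 = _moments(ws, vals, gpars)
    assert slope == pytest.approx(1.0, abs=1e-12)
    assert r2 == pytest.approx(0.75, abs=1e-12)


@pytest.mark.parametrize("f", [0.1, 0.3, 0.5])
def test_sibpair_unphased_unbiased_and_below_phased(f):
    ws, vals, gpars, _ = _sib_imputation_moments(f, phased=False)
    slope, r2 = _moments(ws, vals, gpars)
    assert slope == pytest.approx(1.0, abs=1e-12)
    assert 2.0 / 3.0 < r2 < 0.75  # between linear baseline and phased


def test_sibpair_unphased_approaches_phased_at_extreme_freq():
    _, r2_low = _moments(*_sib_imputation_moments(0.01, phased=False)[:3])
    assert r2_low == pytest.approx(0.75, abs=2e-3)


@pytest.mark.parametrize("f", [0.1, 0.3, 0.5])
def test_sibpair_per_state_r2_contributions(f):
    """IBD0 recovers g_par exactly; IBD1 (phased) has R^2 3/4; IBD2 1/2."""
    ws, vals, gpars, ibds = _sib_imputation_moments(f, phased=True)
    for state, want in ((0, 1.0), (1, 0.75), (2, 0.5)):
        sel = ibds == state
        w = ws[sel] / ws[sel].sum()
        _, r2 = _moments(w, vals[sel], gpars[sel])
        assert r2 == pytest.approx(want, abs=1e-12), state


@pytest.mark.parametrize("f", [0.1, 0.3, 0.5])
def test_po_phased_r2_half_and_linear_baselines(f):
    ws, vals, gps, base = [], [], [], []
    for w, (p1, p2, m1, m2), (x1, y1, _, _) in _family_draws(f):
        ap, am = (p1, p2)[x1], (m1, m2)[y1]
        g_o, g_m = ap + am, m1 + m2
        ws.append(w)
        vals.append(impute_parent_from_parent_offspring(g_o, g_m, ap, f))
        gps.append(p1 + p2)
        base.append(linear_impute_baseline((g_o, g_m), f,
                                           DesignClass.ONE_PARENT_ONE_OFFSPRING))
    ws, vals, gps, base = map(np.array, (ws, vals, gps, base))
    ws /= ws.sum()
    slope, r2 = _moments(ws, vals, gps.astype(float))
    assert slope == pytest.approx(1.0, abs=1e-12)
    assert r2 == pytest.approx(0.5, abs=1e-12)
    slope_b, r2_b = _moments(ws, base, gps.astype(float))
    assert slope_b == pytest.approx(1.0, abs=1e-12)
    assert r2_b == pytest.approx(1.0 / 3.0, abs=1e-12)


@pytest.mark.parametrize("f", [0.1, 0.3, 0.5])
def test_sib_linear_baseline_r2_two_thirds(f):
    ws, vals, gpars = [], [], []
    for w, (p1, p2, m1, m2), (x1, y1, x2, y2) in _family_draws(f):
        g1 = (p1, p2)[x1] + (m1, m2)[y1]
        g2 = (p1, p2)[x2] + (m1, m2)[y2]
        ws.append(w)
        vals.append(linear_impute_baseline((g1, g2), f,
                                           DesignClass.SIB_PAIRS_NO_PARENTS))
        gpars.append(p1 + p2 + m1 + m2)
    ws, vals, gpars = map(np.array, (ws, vals, gpars))
    slope, r2 = _moments(ws, vals, gpars.astype(float))
    assert slope == pytest.approx(1.0, abs=1e-12)
    assert r2 == pytest.approx(2.0 / 3.0, abs=1e-12)


# ---------------------------------------------------------------------------
# closed-form spot values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("g1,g2,ibd,ns,f,want", [
    (1, 2, 0, None, 0.3, 3.0),       # IBD0: all four alleles observed
    (1, 1, 2, None, 0.5, 2.0),       # IBD2: g1 + 2f
    (1, 1, 1, None, 0.25, 1.5),      # IBD1 both het, unphased: 1 + 2f
    (1, 1, 1, 1, 0.2, 2.2),          # IBD1 resolved: g1 + ns + f
    (1, 0, 1, None, 0.2, 1.2),       # IBD1, non-shared determined from g
])
def test_impute_parsum_sibs_values(g1, g2, ibd, ns, f, want):
    v = SibPairSnpView(g1, g2, ibd, g2_notshared=ns)
    assert impute_parsum_sibs(v, f) == pytest.approx(want)


def test_impute_parsum_sibs_inconsistent_falls_back_to_ibd0():
    v = SibPairSnpView(0, 2, 2)  # opposite homozygotes cannot be IBD2
    assert impute_parsum_sibs(v, 0.3) == pytest.approx(2.0)


@pytest.mark.parametrize("g_o,g_obs,t,f,want", [
    (1, 1, None, 0.2, 0.4),   # doubly heterozygous, unphased: 2f
    (0, 1, None, 0.2, 0.2),   # transmitted allele forced to 0: f
    (1, 0, None, 0.2, 1.2),   # transmitted allele forced to 1: 1 + f
    (1, 1, 1, 0.2, 1.2),      # phase-resolved transmission
])
def test_impute_parent_from_parent_offspring_values(g_o, g_obs, t, f, want):
    assert impute_parent_from_parent_offspring(g_o, g_obs, t, f) == \
        pytest.approx(want)


def test_po_mendelian_inconsistency_imputed_missing():
    assert np.isnan(impute_parent_from_parent_offspring(2, 0, None, 0.3))


def test_po_baseline_coefficients():
    # predictor 2f + (2/3)(g_o - 2f) - (1/3)(g_m - 2f)
    f = 0.3
    v0 = linear_impute_baseline((0, 0), f, DesignClass.ONE_PARENT_ONE_OFFSPRING)
    vo = linear_impute_baseline((1, 0), f, DesignClass.ONE_PARENT_ONE_OFFSPRING)
    vm = linear_impute_baseline((0, 1), f, DesignClass.ONE_PARENT_ONE_OFFSPRING)
    assert vo - v0 == pytest.approx(2.0 / 3.0)
    assert vm - v0 == pytest.approx(-1.0 / 3.0)


# ---------------------------------------------------------------------------
# phase resolution
# ---------------------------------------------------------------------------

def test_resolve_shared_allele_informative_neighbor():
    # Neighbor SNP 0: A homozygous 0, B heterozygous with hap1 = (1, 0);
    # B's haplotype carrying the 0 allele is the shared one, and it carries
    # allele 1 at the target SNP -> shared allele 1.
    hapA = np.array([[0, 0], [1, 0]], dtype=np.int8)
    hapB = np.array([[1, 0], [0, 1]], dtype=np.int8)
    assert resolve_shared_allele(hapA, hapB, target=1, seg_lo=0, seg_hi=2) == 1


def test_resolve_shared_allele_no_informative_neighbor():
    hapA = np.array([[1, 0], [1, 0]], dtype=np.int8)  # both het everywhere
    hapB = np.array([[0, 1], [0, 1]], dtype=np.int8)
    assert resolve_shared_allele(hapA, hapB, 1, 0, 2) is None


# ---------------------------------------------------------------------------
# n-sibling generalization
# ---------------------------------------------------------------------------

def test_nsib_pair_matches_closed_forms():
    f = 0.3
    for g1, g2, ibd in ((1, 2, 0), (1, 1, 2), (0, 1, 1)):
        v = SibPairSnpView(g1, g2, ibd)
        want = impute_parsum_sibs(v, f)
        got, n_obs = impute_parsum_nsibs([g1, g2], {(0, 1): ibd}, f)
        assert got == pytest.approx(want)
        assert n_obs == 4 - ibd


def _simulate_sibship(n_sibs, f, rng):
    par = (rng.random(4) < f).astype(int)
    trans = rng.integers(0, 2, size=(n_sibs, 2))
    gs = [par[t[0]] + par[2 + t[1]] for t in trans]
    ibd = {(j, k): int(trans[j, 0] == trans[k, 0]) + int(trans[j, 1] == trans[k, 1])
           for j in range(n_sibs) for k in range(j + 1, n_sibs)}
    g_par = int(par.sum())
    n_obs_true = len(set(trans[:, 0])) + len(set(trans[:, 1]))
    return gs, ibd, g_par, n_obs_true


@pytest.mark.parametrize("n_sibs, expected", [(2, 3.0), (3, 3.5), (4, 3.75)])
def test_nsib_mean_observed_alleles(n_sibs, expected):
    """On average 4(1 - 2^-n) parental alleles are observed."""
    rng = np.random.default_rng(42)
    n_obs = []
    for _ in range(3000):
        trans = rng.integers(0, 2, size=(n_sibs, 2))
        n_obs.append(len(set(trans[:, 0])) + len(set(trans[:, 1])))
    se = np.std(n_obs) / np.sqrt(len(n_obs))
    assert np.mean(n_obs) == pytest.approx(expected, abs=3 * se)


def test_nsib_imputation_unbiased_and_improves_with_n():
    rng = np.random.default_rng(7)
    f = 0.3
    for n_sibs in (2, 4):
        vals, truths = [], []
        for _ in range(800):
            gs, ibd, g_par, _ = _simulate_sibship(n_sibs, f, rng)
            v, _ = impute_parsum_nsibs(gs, ibd, f)
            vals.append(v)
            truths.append(g_par)
        slope, r2 = imputation_diagnostics(vals, truths)
        assert slope == pytest.approx(1.0, abs=0.1)
        if n_sibs == 2:
            r2_pair = r2
    assert r2 > r2_pair  # more siblings recover more of g_par


def test_sibs_plus_parent_cases():
    f = 0.25
    # sibs IBD0, transmissions resolvable: missing parent fully observed
    v, n = impute_parent_from_sibs_and_parent([0, 2], {(0, 1): 0}, 1, f)
    assert v == pytest.approx(round(v))  # integer: both alleles observed
    # fully ambiguous: expectation stays within (0, 2)
    v2, _ = impute_parent_from_sibs_and_parent([1, 1], {(0, 1): 2}, 1, f)
    assert 0 < v2 < 2


# ---------------------------------------------------------------------------
# family-level driver on simulated data
# ---------------------------------------------------------------------------

def test_impute_families_slope_one_r2_three_quarters(sib_sim, sib_families):
    imputed = impute_families(sib_sim.gset, sib_families, sib_sim.true_ibd,
                              phased=True)
    G = sib_sim.gset.genotypes()
    vals, truth = [], []
    for fam in sib_families:
        imp = imputed.get(fam.family_id)
        if imp is None:
            continue
        assert imp.kind == ImputedKind.PAR_SUM
        fa = sib_sim.gset.index_of(fam.father_id)
        mo = sib_sim.gset.index_of(fam.mother_id)
        vals.append(imp.values)
        truth.append(G[fa].astype(float) + G[mo])
    vals = np.stack(vals)    # (families, SNPs)
    truth = np.stack(truth).astype(float)
    # center per SNP: allele-frequency differences between SNPs would
    # otherwise inflate the pooled correlation
    vals -= vals.mean(axis=0)
    truth -= truth.mean(axis=0)
    slope, r2 = imputation_diagnostics(vals.ravel(), truth.ravel())
    assert slope == pytest.approx(1.0, abs=0.03)
    assert r2 == pytest.approx(0.75, abs=0.03)


def test_phased_beats_unphased_family_driver(sib_sim, sib_families):
    G = sib_sim.gset.genotypes()

    def overall_r2(phased):
        imputed = impute_families(sib_sim.gset, sib_families,
                                  sib_sim.true_ibd, phased=phased)
        vals, truth = [], []
        for fam in sib_families:
            imp = imputed.get(fam.family_id)
            if imp is None:
                continue
            fa = sib_sim.gset.index_of(fam.father_id)
            mo = sib_sim.gset.index_of(fam.mother_id)
            vals.append(imp.values)
            truth.append(G[fa].astype(float) + G[mo])
        return imputation_diagnostics(np.concatenate(vals),
                                      np.concatenate(truth))[1]

    assert overall_r2(True) >= overall_r2(False)


def test_diagnostics_identity_and_zero_variance():
    x = np.array([1.0, 2.0, 0.0, 1.0])
    slope, r2 = imputation_diagnostics(x, x)
    assert slope == pytest.approx(1.0) and r2 == pytest.approx(1.0)
    with pytest.raises(ValueError, match="zero variance"):
        imputation_diagnostics(np.ones(5), np.arange(5.0))
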