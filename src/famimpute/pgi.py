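"""Polygenic-index scoring and family-level PGI effect models.

A PGI is a weighted sum of effect-allele dosages, PGI_i = sum_l w_l g_il.
Parental PGIs use observed genotypes when available and imputed dosages
otherwise. The family regression of phenotype on (own PGI, mean sibling
PGI, paternal PGI, maternal PGI) under the family random-effect model
separates the PGI's direct effect from parental and sibling channels;
variance components are estimated jointly with the fixed effects here,
because a PGI (unlike a single SNP) can explain a non-trivial share of
phenotypic variance.

Under assortative mating (AM), per-SNP imputation ignores the cross-SNP
correlations AM induces, so parental PGIs imputed from phased sibling pairs
overstate the NTC by a factor (1 + r_am)/(1 + r_am/2), where r_am is the
equilibrium spousal PGI correlation; :func:`adjust_ntc_for_am` divides that
factor out. Direct-effect estimates are unaffected.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .famlmm import EffectEstimate, Model, VarianceComponents, _family_blocks, \
    _vinv_apply
from .genio import MISSING, PhasedGenotypeSet
from .impute import ImputedKind, ImputedParentalGenotypes
from .pedigree import DesignClass, FamilyUnit
from .theory import am_ntc_inflation

__all__ = [
    "score_pgi",
    "compute_family_pgis",
    "fit_pgi_model",
    "estimate_r_am",
    "adjust_ntc_for_am",
]

_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}


def _match_weights(variants, weights: pd.DataFrame, drop_ambiguous: bool = True):
    """Align a weight table with variant metadata.

    Returns (variant indices, signed weights, flip mask) where a flipped
    SNP's effect allele is allele0, so the effect-allele dosage is
    (max_count - dosage). Strand-ambiguous weight SNPs (A/T, C/G) are
    dropped by default. Errors when over half the weights cannot be matched.
    """
    by_id = {v.snp_id: (j, v) for j, v in enumerate(variants)}
    idx, w, flip = [], [], []
    n_unmatched = 0
    for rec in weights.itertuples():
        hit = by_id.get(rec.snp_id)
        if hit is None:
            n_unmatched += 1
            continue
        j, v = hit
        if drop_ambiguous and frozenset((v.allele0, v.allele1)) in _AMBIGUOUS:
            n_unmatched += 1
            continue
        if rec.effect_allele == v.allele1:
            fl = False
        elif rec.effect_allele == v.allele0:
            fl = True
        else:
            n_unmatched += 1
            continue
        idx.append(j)
        w.append(rec.weight)
        flip.append(fl)
    if n_unmatched > 0.5 * len(weights):
        raise ValueError(
            f"{n_unmatched}/{len(weights)} weight SNPs unmatched")
    if n_unmatched:
        warnings.warn(f"{n_unmatched} weight SNP(s) dropped during matching")
    return np.array(idx, dtype=int), np.array(w, dtype=float), \
        np.array(flip, dtype=bool)


def score_pgi(dosages: np.ndarray, variants, weights: pd.DataFrame,
              max_count: float = 2.0, drop_ambiguous: bool = True) -> np.ndarray:
    """PGI = sum_l w_l * (effect-allele dosage) for each row of ``dosages``.

    ``dosages`` is (n, L) aligned with ``variants`` (may be imputed real
    values); ``max_count`` is the per-SNP dosage ceiling (2 for a person,
    4 for a parental-sum), used to flip SNPs whose effect allele is allele0.
    """
    idx, w, flip = _match_weights(variants, weights, drop_ambiguous)
    d = np.asarray(dosages, dtype=float)[:, idx]
    d = np.where(flip[None, :], max_count - d, d)
    return d @ w


def compute_family_pgis(gset: PhasedGenotypeSet, families,
                        imputed: dict[str, ImputedParentalGenotypes],
                        weights: pd.DataFrame, phenotypes=None):
    """Per-proband PGI columns for the family PGI regression.

    Returns a DataFrame with columns (proband, family, pgi, pgi_sib,
    pgi_father, pgi_mother); for parental-sum families the imputed parental
    PGI sum is split evenly between the father and mother columns. Probands
    whose family carries no parental information are skipped, as are
    unphenotyped probands when ``phenotypes`` is given.
    """
    idx, w, flip = _match_weights(gset.variants, weights)
    G = gset.genotypes().astype(float)
    G[G == MISSING] = np.nan
    d = np.where(flip[None, :], 2.0 - G[:, idx], G[:, idx])
    person_pgi = d @ w

    def imputed_pgi(imp: ImputedParentalGenotypes):
        mx = 4.0 if imp.kind == ImputedKind.PAR_SUM else 2.0
        vals = np.where(flip, mx - imp.values[idx], imp.values[idx])
        return float(np.nansum(vals * w))

    rows = []
    for fam in families:
        if fam.design_class in (DesignClass.PROBAND_ONLY,
                                DesignClass.NOT_IMPUTABLE):
            continue
        sibs = [s for s in fam.genotyped_offspring if s in gset]
        imp = imputed.get(fam.family_id)
        pgi_f = pgi_m = None
        if fam.father_id and fam.genotyped.get(fam.father_id) \
                and fam.father_id in gset:
            pgi_f = person_pgi[gset.index_of(fam.father_id)]
        if fam.mother_id and fam.genotyped.get(fam.mother_id) \
                and fam.mother_id in gset:
            pgi_m = person_pgi[gset.index_of(fam.mother_id)]
        if imp is not None:
            v = imputed_pgi(imp)
            if imp.kind == ImputedKind.FATHER:
                pgi_f = v
            elif imp.kind == ImputedKind.MOTHER:
                pgi_m = v
            else:
                pgi_f = pgi_m = v / 2.0
        if pgi_f is None or pgi_m is None:
            continue
        for p in sibs:
            if not fam.phenotyped.get(p, False):
                continue
            if phenotypes is not None and p not in phenotypes:
                continue
            others = [s for s in sibs if s != p]
            pgi_sib = (float(np.mean([person_pgi[gset.index_of(s)]
                                      for s in others]))
                       if others else np.nan)
            rows.append((p, fam.family_id, person_pgi[gset.index_of(p)],
                         pgi_sib, pgi_f, pgi_m))
    return pd.DataFrame(rows, columns=["proband", "family", "pgi", "pgi_sib",
                                       "pgi_father", "pgi_mother"])


def fit_pgi_model(y, pgi_proband, pgi_sib_mean, pgi_father, pgi_mother,
                  fam_index, model: Model = Model.WITH_SIB_IGE):
    """Joint ML fit of the family PGI model; effects per PGI SD.

    Columns are the proband PGI, optionally the mean sibling PGI, and the
    paternal and maternal PGIs, all standardized by the proband-PGI SD of
    the estimation sample. Variance components and fixed effects are
    estimated jointly (profiled 1-D optimization over the sibling residual
    correlation r). Returns an :class:`EffectEstimate` with labels
    (direct[, eta_s], alpha_p, alpha_m) and the fitted
    :class:`VarianceComponents`.
    """
    y = np.asarray(y, dtype=float)
    cols = [np.asarray(pgi_proband, dtype=float)]
    labels = ["direct"]
    if model == Model.WITH_SIB_IGE:
        cols.append(np.asarray(pgi_sib_mean, dtype=float))
        labels.append("eta_s")
    fa = np.asarray(pgi_father, dtype=float)
    mo = np.asarray(pgi_mother, dtype=float)
    if np.allclose(fa, mo, equal_nan=True):
        # all parental PGIs come from parental-sum imputation: only the
        # combined NTC is identifiable
        cols.append(fa + mo)
        labels.append("alpha")
    else:
        cols += [fa, mo]
        labels += ["alpha_p", "alpha_m"]
    X = np.column_stack(cols)
    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    y, X = y[ok], X[ok]
    fam_index = np.asarray(fam_index)[ok]
    sd = X[:, 0].std()
    if sd == 0:
        raise ValueError("zero variance in proband PGI")
    X = (X - X.mean(axis=0)) / sd
    y = y - y.mean()
    order = np.argsort(fam_index, kind="stable")
    y, X, fam_index = y[order], X[order], fam_index[order]
    starts, sizes = _family_blocks(fam_index)
    N = len(y)

    def fit_given_r(r):
        vc = VarianceComponents(r, 1.0 - r)  # unit total variance
        VinvX = _vinv_apply(X, starts, sizes, vc)
        A = X.T @ VinvX
        theta = np.linalg.solve(A, VinvX.T @ y)
        e = y - X @ theta
        Vinv_e = _vinv_apply(e[:, None], starts, sizes, vc)[:, 0]
        quad = float(e @ Vinv_e)
        lam_top = 1 - r + sizes * r
        logdet = np.sum(np.log(lam_top)) + (N - len(sizes)) * np.log(1 - r)
        s2 = quad / N
        nll = 0.5 * (N * np.log(s2) + logdet)
        return nll, theta, A, s2

    res = minimize_scalar(lambda r: fit_given_r(r)[0], bounds=(0.0, 0.99),
                          method="bounded", options={"xatol": 1e-8})
    r = float(res.x)
    if fit_given_r(0.0)[0] <= res.fun:
        r = 0.0
    _, theta, A, s2 = fit_given_r(r)
    cov = s2 * np.linalg.inv(A)
    est = EffectEstimate(tuple(labels), theta, cov,
                         n_families=len(sizes), n_individuals=N)
    return est, VarianceComponents(r * s2, (1 - r) * s2)


def estimate_r_am(gset: PhasedGenotypeSet, families, weights: pd.DataFrame):
    """Spousal PGI correlation among families with both parents genotyped.

    Raises when no such family exists; in that case r_am must be supplied
    by the user for the AM adjustment.
    """
    G = gset.genotypes().astype(float)
    idx, w, flip = _match_weights(gset.variants, weights)
    d = np.where(flip[None, :], 2.0 - G[:, idx], G[:, idx])
    pgi = d @ w
    pf, pm = [], []
    for fam in families:
        if (fam.father_id and fam.mother_id
                and fam.genotyped.get(fam.father_id)
                and fam.genotyped.get(fam.mother_id)
                and fam.father_id in gset and fam.mother_id in gset):
            pf.append(pgi[gset.index_of(fam.father_id)])
            pm.append(pgi[gset.index_of(fam.mother_id)])
    if len(pf) < 2:
        raise ValueError(
            "no fully genotyped parent pairs; supply r_am explicitly")
    return float(np.corrcoef(pf, pm)[0, 1])


def adjust_ntc_for_am(alpha_hat: float, se: float, r_am: float,
                      design_class: DesignClass = DesignClass.SIB_PAIRS_NO_PARENTS):
    """Deflate an average-NTC estimate for the AM-induced imputation bias.

    Valid for parental PGIs imputed from phased sibling pairs (the combined
    NTC); other imputation classes have different factors and are returned
    unadjusted with a warning. Direct-effect estimates need no adjustment.
    """
    factor = am_ntc_inflation(r_am)
    if design_class != DesignClass.SIB_PAIRS_NO_PARENTS:
        warnings.warn(
            f"AM inflation factor is derived for phased sibling-pair "
            f"imputation; {design_class} left unadjusted")
        return alpha_hat, se
    return alpha_hat / factor, se / factor
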