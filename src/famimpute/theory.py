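"""Closed-form efficiency, bias and accuracy references.

These are the analytic counterparts of the estimators in :mod:`famlmm` and
the imputations in :mod:`impute`, used as diagnostics and as oracles for the
simulation cross-checks. Throughout, ``r`` is the correlation of siblings'
phenotype residuals, sigma_F^2/(sigma_F^2 + sigma_eps^2) under the family
random-effect model. Effective-sample-size factors are relative to the
sibling-difference estimator (for sibling designs) or to fully observed
trios (for parent-offspring designs).
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "effn_direct_sib_phased",
    "effn_ntc_sib_phased",
    "effn_direct_split",
    "bias_delta_assuming_no_sibige",
    "structure_bias_delta",
    "effn_po_relative",
    "am_ntc_inflation",
]


def _check_r(r: float):
    if not (0 <= r < 1):
        raise ValueError("r must be in [0, 1)")


def effn_direct_sib_phased(r: float) -> float:
    """Effective-n gain for the direct effect from phased sibling-pair
    imputation over the sibling-difference estimator: 1 + (1-r)/(3(1+r)),
    maximum 4/3 at r = 0."""
    _check_r(r)
    return 1.0 + (1.0 - r) / (3.0 * (1.0 + r))


def effn_ntc_sib_phased(r: float) -> float:
    """Effective-n gain for the average NTC from phased sibling-pair
    imputation: 1 + (1 - r/2)/(2(1+r)), maximum 1.5 at r = 0 and always
    above 1.125."""
    _check_r(r)
    return 1.0 + (1.0 - r / 2.0) / (2.0 * (1.0 + r))


def effn_direct_split(r: float) -> float:
    """Effective-n gain of the structure-robust split estimator over the
    sibling-difference estimator: 1 + (1-r)/(6(1+r)), maximum 7/6 at r = 0."""
    _check_r(r)
    return 1.0 + (1.0 - r) / (6.0 * (1.0 + r))


def bias_delta_assuming_no_sibige(r: float, eta_s: float) -> float:
    """Bias of the direct-effect estimate when a true sibling indirect
    effect eta_s is omitted from the sibling-pair model:
    -((1+2r)/(2+r)) * eta_s. Smaller in magnitude than the sibling-difference
    bias (-eta_s) for r < 1."""
    _check_r(r)
    return -((1.0 + 2.0 * r) / (2.0 + r)) * eta_s


def structure_bias_delta(f_st: float, alpha: float) -> float:
    """Approximate bias of the pooled sibling-pair direct-effect estimate
    under population structure: F_st * alpha / 2 (small F_st)."""
    if f_st < 0:
        raise ValueError("f_st must be >= 0")
    return f_st * alpha / 2.0


def _po_information_ratio(f: float, phased: bool) -> float:
    """var(delta_hat | trio) / var(delta_hat | one parent + imputation).

    Deterministic enumeration of the expected single-proband information
    matrices over the finite joint genotype distribution at frequency
    ``f``: the design is (g_offspring, imputed-or-observed father, mother),
    and the ratio of the inverted-information delta entries gives the
    relative effective sample size.
    """
    configs = []
    probs = []
    for p1, p2, m1, m2, xp, xm in itertools.product((0, 1), (0, 1), (0, 1),
                                                    (0, 1), (0, 1), (0, 1)):
        w = np.prod([f if a else 1 - f for a in (p1, p2, m1, m2)]) / 4.0
        ap = (p1, p2)[xp]
        am = (m1, m2)[xm]
        g_o = ap + am
        g_p = p1 + p2
        g_m = m1 + m2
        configs.append((g_o, g_p, g_m, ap))
        probs.append(w)
    configs = np.array(configs, dtype=float)
    probs = np.array(probs)
    g_o, g_p, g_m, ap = configs.T

    if phased:
        ghat = ap + f
    else:
        # conditional expectation given (g_o, g_m): transmitted paternal
        # allele determined unless both are heterozygous, then 2f
        ghat = np.where((g_o == 1) & (g_m == 1), 2 * f,
                        np.where(g_m == 0, g_o + f,
                                 np.where(g_m == 2, g_o - 1 + f,
                                          np.where(g_o == 0, f,
                                                   np.where(g_o == 2, 1 + f,
                                                            np.nan)))))

    def info_inv00(cols):
        Xm = np.column_stack(cols)
        mu = probs @ Xm
        Xc = Xm - mu
        M = (Xc * probs[:, None]).T @ Xc
        return np.linalg.inv(M)[0, 0]

    v_trio = info_inv00([g_o, g_p, g_m])
    v_imp = info_inv00([g_o, ghat, g_m])
    return v_trio / v_imp


def effn_po_relative(maf: float, phased: bool) -> float:
    """Effective sample size of one-parent-plus-offspring imputation for the
    direct effect, relative to fully observed trios.

    Phased imputation gives 1/2 regardless of allele frequency; unphased
    imputation is evaluated numerically by enumeration, running from 1/6 at
    MAF 0.5 up to 1/2 as MAF approaches 0.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    return _po_information_ratio(maf, phased)


def am_ntc_inflation(r_am: float) -> float:
    """Inflation factor of the average NTC of a PGI imputed from phased
    sibling pairs under assortative mating: (1 + r_am)/(1 + r_am/2), where
    r_am is the equilibrium spousal PGI correlation."""
    if not (-1 < r_am < 1):
        raise ValueError("r_am must be in (-1, 1)")
    return (1.0 + r_am) / (1.0 + r_am / 2.0)
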