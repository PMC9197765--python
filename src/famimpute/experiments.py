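"""Single-SNP replicate experiments: efficiency, bias and calibration.

Each experiment draws many independent replicate samples of nuclear
families at one SNP, runs the package's estimators on each, and summarizes
the sampling distribution. They are the simulation counterparts of the
closed forms in :mod:`theory`:

* sibling pairs, phased imputation vs the sibling-difference estimator:
  effective-n gain 1 + (1-r)/(3(1+r)) for the direct effect (4/3 at r=0);
* sibling pairs, phased imputation vs the no-imputation (g1, g2) regression:
  effective-n gain 1 + (1-r/2)/(2(1+r)) for the average NTC (1.5 at r=0);
* the observed-allele-split robust estimator vs sibling differences:
  1 + (1-r)/(6(1+r)) (7/6 at r=0);
* one parent + offspring with imputation vs a fully genotyped trio: 1/2
  (phased) and down to 1/6 at MAF 0.5 (unphased).

Sampling here is direct at the single-locus level (parental alleles,
Mendelian transmissions, and the implied IBD state), which makes thousands
of replicates at tens of thousands of families cheap; the genome-scale
simulator in :mod:`simulate` covers the multi-locus processes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .famlmm import VarianceComponents, estimate_snp_effects, sibdiff_estimate

__all__ = [
    "SibPairSample",
    "draw_sib_pairs",
    "fit_imputed_sibpair",
    "fit_noimpute_sibpair",
    "sibpair_efficiency",
    "po_efficiency",
    "sibpair_bias_experiment",
    "calibration_experiment",
]


@dataclass
class SibPairSample:
    """One replicate of n sibling-pair families at a single SNP."""

    g1: np.ndarray
    g2: np.ndarray
    g_par: np.ndarray          # true parental genotype sum
    ibd: np.ndarray
    ghat_phased: np.ndarray    # E[g_par | g1, g2, IBD, phase]
    ghat_unphased: np.ndarray
    n_obs: np.ndarray          # observed parental alleles = 4 - IBD


def draw_sib_pairs(n: int, f, rng: np.random.Generator,
                   f_impute=None) -> SibPairSample:
    """Sample families under HWE and Mendelian transmission at frequency f.

    ``f`` may be a scalar or a per-family array (e.g. deme-specific
    frequencies under stratification); ``f_impute`` is the frequency the
    imputation plugs in for unobserved alleles (defaults to ``f`` — pass the
    pooled frequency to emulate imputation that ignores structure). The
    phased imputation uses the true non-shared allele in IBD1 (what perfect
    phase resolution recovers); the unphased one falls back to 1 + 2f for
    the doubly heterozygous case.
    """
    draw_f = np.broadcast_to(np.asarray(f, dtype=float), (n,))
    f = (np.broadcast_to(np.asarray(f_impute, dtype=float), (n,))
         if f_impute is not None else draw_f)
    par = (rng.random((n, 4)) < draw_f[:, None]).astype(np.int8)  # p1 p2 m1 m2
    x1, y1, x2, y2 = (rng.integers(0, 2, size=n) for _ in range(4))
    g1 = par[np.arange(n), x1] + par[np.arange(n), 2 + y1]
    g2 = par[np.arange(n), x2] + par[np.arange(n), 2 + y2]
    g_par = par.sum(axis=1)
    ibd = (x1 == x2).astype(np.int8) + (y1 == y2).astype(np.int8)

    # sibling 2's allele not shared with sibling 1 (defined in IBD1)
    pat_shared = x1 == x2
    ns2 = np.where(pat_shared, par[np.arange(n), 2 + y2],
                   par[np.arange(n), x2])

    ghat_p = np.where(ibd == 0, (g1 + g2).astype(float),
                      np.where(ibd == 2, g1 + 2 * f, g1 + ns2 + f))
    both_het = (g1 == 1) & (g2 == 1) & (ibd == 1)
    ghat_u = np.where(both_het, 1 + 2 * f, ghat_p)
    return SibPairSample(g1.astype(float), g2.astype(float),
                         g_par.astype(float), ibd, ghat_p, ghat_u,
                         (4 - ibd).astype(int))


def _sib_phenotypes(s: SibPairSample, delta, eta_s, alpha, r,
                    rng: np.random.Generator):
    """Phenotypes for both siblings under the two-sibling model with
    residual correlation r (family effect + independent noise)."""
    n = len(s.g1)
    fam = rng.normal(0, np.sqrt(r), n)
    e1 = rng.normal(0, np.sqrt(1 - r), n)
    e2 = rng.normal(0, np.sqrt(1 - r), n)
    base = alpha * s.g_par
    y1 = delta * s.g1 + eta_s * s.g2 + base + fam + e1
    y2 = delta * s.g2 + eta_s * s.g1 + base + fam + e2
    return y1, y2


def _stack_pairs(y1, y2, c1, c2):
    """Interleave per-sibling rows family-by-family (rows sorted by family)."""
    n = len(y1)
    y = np.empty(2 * n)
    y[0::2], y[1::2] = y1, y2
    X = np.empty((2 * n, len(c1)))
    for j, (a, b) in enumerate(zip(c1, c2)):
        X[0::2, j], X[1::2, j] = a, b
    fam = np.repeat(np.arange(n), 2)
    return y, X, fam


def fit_imputed_sibpair(s: SibPairSample, y1, y2, r, phased=True,
                        with_sib=False):
    """GLS fit of the imputed-parental-genotype regression; both siblings
    phenotyped. Columns: own genotype [, sibling genotype], imputed g_par."""
    ghat = s.ghat_phased if phased else s.ghat_unphased
    if with_sib:
        cols1 = (s.g1, s.g2, ghat)
        cols2 = (s.g2, s.g1, ghat)
        labels = ("direct", "eta_s", "alpha")
    else:
        cols1 = (s.g1, ghat)
        cols2 = (s.g2, ghat)
        labels = ("direct", "alpha")
    y, X, fam = _stack_pairs(y1, y2, cols1, cols2)
    vc = VarianceComponents(r, 1 - r) if r > 0 else VarianceComponents(0, 1)
    return estimate_snp_effects(y, X, fam, vc, labels)


def fit_noimpute_sibpair(s: SibPairSample, y1, y2, r):
    """No-imputation reference: regression on (own, sibling) genotype only.

    The sibling-genotype coefficient converges to (2/3) * alpha under the
    parental-effects model, so alpha is recovered as 1.5 x that coefficient
    (delta-method SE scales the same way)."""
    y, X, fam = _stack_pairs(y1, y2, (s.g1, s.g2), (s.g2, s.g1))
    vc = VarianceComponents(r, 1 - r) if r > 0 else VarianceComponents(0, 1)
    est = estimate_snp_effects(y, X, fam, vc, ("own", "sib"))
    return 1.5 * est.get("sib"), 1.5 * est.se("sib")


def _split_delta(s: SibPairSample, y1, y2, r):
    """Observed-parental-allele split estimator of the direct effect."""
    vc = VarianceComponents(r, 1 - r) if r > 0 else VarianceComponents(0, 1)
    # IBD2 families are excluded: there the imputed parental sum is
    # g1 + 2f, exactly collinear with the proband genotype (g1 = g2), so
    # that group identifies no direct-effect information on its own.
    ests, ws = [], []
    for k in (0, 1):
        sel = s.ibd == k
        if sel.sum() < 10:
            continue
        cols1 = (s.g1[sel], s.ghat_phased[sel])
        cols2 = (s.g2[sel], s.ghat_phased[sel])
        y, X, fam = _stack_pairs(y1[sel], y2[sel], cols1, cols2)
        est = estimate_snp_effects(y, X, fam, vc, ("direct", "alpha"))
        i = est.labels.index("direct")
        ests.append(est.estimates[i])
        ws.append(1 / est.covariance[i, i])
    ests, ws = np.array(ests), np.array(ws)
    delta = float(np.sum(ws * ests) / ws.sum())
    return delta, float(np.sqrt(1 / ws.sum()))


def sibpair_efficiency(target: str, n: int = 20000, n_reps: int = 2000,
                       f: float = 0.25, r: float = 0.0, seed: int = 1):
    """Effective-sample-size ratio of an imputation-based estimator to its
    no-imputation reference, from replicate sampling variances.

    ``target``: "direct" (phased imputation vs sibling differences),
    "ntc" (phased imputation vs the (g1, g2) regression) or "split"
    (observed-allele-split vs sibling differences). Returns (ratio, MC SE):
    the Monte-Carlo SE follows from the chi-squared sampling variance of the
    two empirical variances.
    """
    rng = np.random.default_rng(seed)
    new, ref = np.empty(n_reps), np.empty(n_reps)
    for i in range(n_reps):
        s = draw_sib_pairs(n, f, rng)
        y1, y2 = _sib_phenotypes(s, 0.0, 0.0, 0.0, r, rng)
        if target == "direct":
            est = fit_imputed_sibpair(s, y1, y2, r)
            new[i] = est.get("direct")
            ref[i] = sibdiff_estimate(np.column_stack([y1, y2]),
                                      np.column_stack([s.g1, s.g2]))[0]
        elif target == "ntc":
            est = fit_imputed_sibpair(s, y1, y2, r)
            new[i] = est.get("alpha")
            ref[i] = fit_noimpute_sibpair(s, y1, y2, r)[0]
        elif target == "split":
            new[i] = _split_delta(s, y1, y2, r)[0]
            ref[i] = sibdiff_estimate(np.column_stack([y1, y2]),
                                      np.column_stack([s.g1, s.g2]))[0]
        else:
            raise ValueError(target)
    ratio = float(np.var(ref) / np.var(new))
    mc_se = ratio * np.sqrt(4.0 / n_reps)  # two independent variance estimates
    return ratio, mc_se


def po_efficiency(phased: bool, n: int = 20000, n_reps: int = 2000,
                  f: float = 0.25, seed: int = 1):
    """Effective n of parent-offspring imputation relative to full trios.

    One phenotyped proband per family; the mother is observed, the father
    imputed (phased: from the known transmitted allele; unphased: 2f in the
    doubly heterozygous case). Returns (ratio, MC SE).
    """
    rng = np.random.default_rng(seed)
    vc = VarianceComponents(0, 1)
    imp, trio = np.empty(n_reps), np.empty(n_reps)
    for i in range(n_reps):
        par = (rng.random((n, 4)) < f).astype(float)  # p1 p2 m1 m2
        xp = rng.integers(0, 2, n)
        xm = rng.integers(0, 2, n)
        ap = par[np.arange(n), xp]
        am = par[np.arange(n), 2 + xm]
        g_o = ap + am
        g_p = par[:, 0] + par[:, 1]
        g_m = par[:, 2] + par[:, 3]
        y = rng.normal(0, 1, n)
        if phased:
            ghat = ap + f
        else:
            both_het = (g_o == 1) & (g_m == 1)
            ghat = np.where(both_het, 2 * f, ap + f)
        fam = np.arange(n)
        e1 = estimate_snp_effects(y, np.column_stack([g_o, ghat, g_m]), fam,
                                  vc, ("direct", "alpha_p", "alpha_m"))
        e2 = estimate_snp_effects(y, np.column_stack([g_o, g_p, g_m]), fam,
                                  vc, ("direct", "alpha_p", "alpha_m"))
        imp[i] = e1.get("direct")
        trio[i] = e2.get("direct")
    ratio = float(np.var(trio) / np.var(imp))
    return ratio, ratio * np.sqrt(4.0 / n_reps)


def sibpair_bias_experiment(eta_s: float, r: float, n: int = 20000,
                            n_reps: int = 20, f: float = 0.25, seed: int = 1):
    """Mean bias of the direct effect when a true sibling IGE is omitted.

    Fits the (own genotype, imputed g_par) model with eta_s absent; returns
    (mean delta-hat - delta, MC SE of the mean, mean sibling-difference
    estimate - (delta - eta_s) + eta_s i.e. sib-difference bias).
    """
    rng = np.random.default_rng(seed)
    delta = 0.1
    d_imp, d_dif = np.empty(n_reps), np.empty(n_reps)
    for i in range(n_reps):
        s = draw_sib_pairs(n, f, rng)
        y1, y2 = _sib_phenotypes(s, delta, eta_s, 0.0, r, rng)
        d_imp[i] = fit_imputed_sibpair(s, y1, y2, r).get("direct") - delta
        d_dif[i] = sibdiff_estimate(np.column_stack([y1, y2]),
                                    np.column_stack([s.g1, s.g2]))[0] - delta
    return (float(d_imp.mean()), float(d_imp.std(ddof=1) / np.sqrt(n_reps)),
            float(d_dif.mean()), float(d_dif.std(ddof=1) / np.sqrt(n_reps)))


def stratification_bias_experiment(f_gap: float = 0.1, offset: float = 0.5,
                                   n: int = 20000, n_reps: int = 40,
                                   fbar: float = 0.3, seed: int = 1):
    """Direct-effect bias of the pooled estimator under two-deme structure.

    Families belong to two equally sized demes with allele frequencies
    fbar +- f_gap/2 (realized F_st = (f_gap/2)^2 / (fbar (1-fbar))) and a
    phenotype offset of ``offset`` between demes; imputation plugs in the
    pooled frequency, as it would without knowledge of the structure.
    Returns a dict with the pooled delta bias, the split-estimator bias,
    their MC SEs, the mean fitted NTC, and the predicted bias
    F_st * alpha / 2.
    """
    rng = np.random.default_rng(seed)
    delta = 0.1
    fst = (f_gap / 2) ** 2 / (fbar * (1 - fbar))
    d_pool, d_split, alphas = (np.empty(n_reps) for _ in range(3))
    for i in range(n_reps):
        deme = rng.integers(0, 2, n)
        f_d = np.where(deme == 0, fbar - f_gap / 2, fbar + f_gap / 2)
        s = draw_sib_pairs(n, f_d, rng, f_impute=fbar)
        y1, y2 = _sib_phenotypes(s, delta, 0.0, 0.0, 0.0, rng)
        y1 = y1 + offset * deme
        y2 = y2 + offset * deme
        est = fit_imputed_sibpair(s, y1, y2, 0.0)
        d_pool[i] = est.get("direct") - delta
        alphas[i] = est.get("alpha")
        d_split[i] = _split_delta(s, y1, y2, 0.0)[0] - delta
    rt = np.sqrt(n_reps)
    return {
        "pooled_bias": float(d_pool.mean()),
        "pooled_bias_se": float(d_pool.std(ddof=1) / rt),
        "split_bias": float(d_split.mean()),
        "split_bias_se": float(d_split.std(ddof=1) / rt),
        "alpha_hat": float(alphas.mean()),
        "fst": fst,
        "predicted_bias": fst * float(alphas.mean()) / 2,
    }


def calibration_experiment(n: int = 4000, n_reps: int = 200, f: float = 0.25,
                           r: float = 0.3, seed: int = 1,
                           delta: float = 0.05, alpha: float = 0.02):
    """Replicate estimates and reported SEs for SE-calibration checks.

    Returns (estimates (n_reps, 2), reported SEs (n_reps, 2)) for
    (direct, alpha) from the phased sibling-pair regression with true
    effects (delta, alpha) and residual correlation r.
    """
    rng = np.random.default_rng(seed)
    ests = np.empty((n_reps, 2))
    ses = np.empty((n_reps, 2))
    for i in range(n_reps):
        s = draw_sib_pairs(n, f, rng)
        y1, y2 = _sib_phenotypes(s, delta, 0.0, alpha, r, rng)
        est = fit_imputed_sibpair(s, y1, y2, r)
        ests[i] = [est.get("direct"), est.get("alpha")]
        ses[i] = [est.se("direct"), est.se("alpha")]
    return ests - np.array([delta, alpha + 0.0]), ses, np.array([delta, alpha])
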