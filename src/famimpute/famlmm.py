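"""SNP-effect estimation under a family random-effect linear mixed model.

Phenotypes of siblings are correlated through shared genes and environment;
we model this with a family-level random effect:

    Y_ij = X_ij theta + mu_i + eps_ij,   mu_i ~ N(0, sigma_F^2),
                                         eps_ij ~ N(0, sigma_eps^2),

so siblings' residuals have correlation r = sigma_F^2/(sigma_F^2 +
sigma_eps^2). Variance components are first estimated by maximum likelihood
under a null model with no SNP effects; they are then held fixed and each
SNP's effects are estimated by generalized least squares. Both steps exploit
the block-diagonal family structure (Woodbury identity per family), so the
cost is linear in the number of individuals and no dense n x n matrix is
ever formed.

The design columns follow the family's data type: probands contribute their
own genotype (direct effect delta), optionally the mean genotype of their
siblings (sibling indirect effect eta_s), and observed-or-imputed parental
genotypes (non-transmitted coefficients alpha_p, alpha_m, or the combined
alpha when only the parental sum is identifiable). The population effect is
derived as beta = delta + (alpha_p + alpha_m)/2.

Also provided: the sibling-difference benchmark estimator of delta - eta_s,
and a structure-robust estimator that splits the regression by the number of
observed parental alleles, which removes the imputation bias that population
stratification otherwise induces (approximately F_st * alpha / 2 for pooled
sibling-pair imputation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import minimize_scalar

from .genio import PhasedGenotypeSet, PhenotypeVector, SummaryStatRow
from .impute import ImputedKind, ImputedParentalGenotypes
from .pedigree import DesignClass, FamilyUnit

__all__ = [
    "Model",
    "VarianceComponents",
    "DesignSpec",
    "EffectEstimate",
    "fit_null_varcomps",
    "assemble_design",
    "assemble_dataset",
    "estimate_snp_effects",
    "population_effect",
    "sibdiff_estimate",
    "robust_split_estimate",
    "gwas",
]


class Model(Enum):
    WITH_SIB_IGE = "sib-ige"
    NO_SIB_IGE = "basic"


@dataclass
class VarianceComponents:
    sigma2_F: float
    sigma2_e: float

    def __post_init__(self):
        if self.sigma2_F < 0 or self.sigma2_e <= 0:
            raise ValueError("need sigma2_F >= 0 and sigma2_e > 0")

    @property
    def r(self) -> float:
        return self.sigma2_F / (self.sigma2_F + self.sigma2_e)


@dataclass
class DesignSpec:
    """Which columns the combined regression carries.

    ``separate_ntc`` fits (alpha_p, alpha_m) with parental-sum families
    contributing g_par/2 to both columns; otherwise a single combined-NTC
    column alpha on the parental sum is fitted (forced when only sibling
    families are present, to avoid collinearity).
    """

    model: Model = Model.NO_SIB_IGE
    separate_ntc: bool = True


@dataclass
class EffectEstimate:
    """Joint estimates for one SNP (or one PGI) with sampling covariance."""

    labels: tuple[str, ...]
    estimates: np.ndarray
    covariance: np.ndarray
    n_families: int = 0
    n_individuals: int = 0

    def get(self, label: str) -> float:
        return float(self.estimates[self.labels.index(label)])

    def se(self, label: str) -> float:
        i = self.labels.index(label)
        return float(np.sqrt(self.covariance[i, i]))


# ---------------------------------------------------------------------------
# Variance components (null model, ML)
# ---------------------------------------------------------------------------

def _family_blocks(fam_index: np.ndarray):
    """Rows must be sorted by family. Returns (starts, sizes)."""
    change = np.flatnonzero(np.diff(fam_index)) + 1
    starts = np.concatenate([[0], change])
    sizes = np.diff(np.concatenate([starts, [len(fam_index)]]))
    return starts, sizes


def fit_null_varcomps(y: np.ndarray, fam_index: np.ndarray,
                      tol: float = 1e-8) -> VarianceComponents:
    """ML variance components of the null (no-SNP) family model.

    ``fam_index`` assigns each phenotype row to a family (rows sorted by
    family). The sibling residual correlation r is profiled: for fixed r the
    total variance has a closed-form ML solution, leaving a 1-D bounded
    optimization over r in [0, 0.99]. With no multi-offspring family,
    sigma_F^2 is unidentified and set to 0 with a warning.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    fam_index = np.asarray(fam_index)
    order = np.argsort(fam_index, kind="stable")
    y = y[order]
    fam_index = fam_index[order]
    starts, sizes = _family_blocks(fam_index)
    N = len(y)
    y = y - y.mean()
    if (sizes >= 2).sum() < 2:
        warnings.warn("fewer than 2 multi-offspring families; sigma_F^2 set to 0")
        return VarianceComponents(0.0, float(np.var(y)) or 1.0)

    fam_sums_at = np.add.reduceat(y, starts)
    sq = float(np.dot(y, y))
    sum_sq_fam = fam_sums_at ** 2

    def negloglik(r):
        # unit-variance covariance (1-r) I + r J per family
        lam_top = 1 - r + sizes * r          # eigenvalue along the family mean
        quad = (sq - np.sum(r / lam_top * sum_sq_fam)) / (1 - r)
        logdet = np.sum(np.log(lam_top)) + (N - len(sizes)) * np.log(1 - r)
        s2 = quad / N
        return 0.5 * (N * np.log(s2) + logdet)

    res = minimize_scalar(negloglik, bounds=(0.0, 0.99), method="bounded",
                          options={"xatol": tol})
    r = float(res.x)
    # recompute total variance at the optimum
    lam_top = 1 - r + sizes * r
    quad = (sq - np.sum(r / lam_top * sum_sq_fam)) / (1 - r)
    s2 = quad / N
    if negloglik(0.0) <= res.fun:
        r, s2 = 0.0, sq / N
    return VarianceComponents(r * s2, (1 - r) * s2)


# ---------------------------------------------------------------------------
# GLS with family blocks
# ---------------------------------------------------------------------------

def _vinv_apply(Z: np.ndarray, starts, sizes, vc: VarianceComponents):
    """V^{-1} Z for block compound-symmetric V, O(rows)."""
    shrink = vc.sigma2_F / (vc.sigma2_e + sizes * vc.sigma2_F)  # per family
    fam_sums = np.add.reduceat(Z, starts, axis=0)
    expand = np.repeat(shrink, sizes)[:, None] * np.repeat(fam_sums, sizes, axis=0)
    return (Z - expand) / vc.sigma2_e


def estimate_snp_effects(y: np.ndarray, X: np.ndarray, fam_index: np.ndarray,
                         vc: VarianceComponents,
                         labels: tuple[str, ...]) -> EffectEstimate:
    """GLS estimate of the SNP effect vector with covariance (X' V^-1 X)^-1.

    Rows must be sorted by family; design columns are mean-centered here
    using the estimation-sample mean. Raises on rank deficiency.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    if not ok.all():
        y, X, fam_index = y[ok], X[ok], fam_index[ok]
    X = X - X.mean(axis=0)
    y = y - y.mean()
    starts, sizes = _family_blocks(fam_index)
    VinvX = _vinv_apply(X, starts, sizes, vc)
    A = X.T @ VinvX
    b = VinvX.T @ y
    if np.linalg.matrix_rank(A) < A.shape[0]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for columns {labels}; "
            "check the mix of family classes")
    cov = np.linalg.inv(A)
    theta = cov @ b
    return EffectEstimate(labels, theta, cov,
                          n_families=len(sizes), n_individuals=len(y))


def population_effect(est: EffectEstimate) -> tuple[float, float]:
    """beta = delta + (alpha_p + alpha_m)/2 (or delta + alpha) with
    delta-method variance from the stored covariance."""
    c = np.zeros(len(est.labels))
    c[est.labels.index("direct")] = 1.0
    if "alpha" in est.labels:
        c[est.labels.index("alpha")] = 1.0
    else:
        c[est.labels.index("alpha_p")] = 0.5
        c[est.labels.index("alpha_m")] = 0.5
    beta = float(c @ est.estimates)
    var = float(c @ est.covariance @ c)
    return beta, var


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

def assemble_design(fam: FamilyUnit, snp_index: int, gset: PhasedGenotypeSet,
                    imputed: dict[str, ImputedParentalGenotypes],
                    spec: DesignSpec):
    """Design rows for one family at one SNP, with coefficient labels.

    One row per phenotyped genotyped offspring. The expected coefficient
    interpretation per data type: trios give (delta, alpha_p, alpha_m);
    sibling pairs give (delta[, eta_s], alpha') with
    alpha' = (alpha_p + alpha_m - eta_s)/2 on the imputed parental sum; a
    proband with no genotyped relatives yields a single column whose
    coefficient is delta + (alpha_p + alpha_m + eta_s)/2.
    """
    G = gset.genotypes()
    rows, ids = [], []
    sibs = [s for s in fam.genotyped_offspring if s in gset]
    probands = [s for s in sibs if fam.phenotyped.get(s, False)]
    imp = imputed.get(fam.family_id)

    father_obs = fam.father_id and fam.genotyped.get(fam.father_id, False) \
        and fam.father_id in gset
    mother_obs = fam.mother_id and fam.genotyped.get(fam.mother_id, False) \
        and fam.mother_id in gset

    if fam.design_class in (DesignClass.PROBAND_ONLY, DesignClass.NOT_IMPUTABLE):
        labels = ("direct_plus_avg_ntc",)
        for p in probands:
            rows.append([float(G[gset.index_of(p), snp_index])])
            ids.append(p)
        return np.array(rows), labels, ids

    def parent_cols(proband):
        gp = gm = None
        if father_obs:
            gp = float(G[gset.index_of(fam.father_id), snp_index])
        if mother_obs:
            gm = float(G[gset.index_of(fam.mother_id), snp_index])
        if imp is not None:
            v = float(imp.values[snp_index])
            if imp.kind == ImputedKind.FATHER:
                gp = v
            elif imp.kind == ImputedKind.MOTHER:
                gm = v
            else:  # PAR_SUM
                return ("parsum", v)
        return ("both", gp, gm)

    sib_col = spec.model == Model.WITH_SIB_IGE
    use_alpha = not spec.separate_ntc
    labels = ["direct"]
    if sib_col:
        labels.append("eta_s")
    labels += ["alpha"] if use_alpha else ["alpha_p", "alpha_m"]

    for p in probands:
        g = float(G[gset.index_of(p), snp_index])
        others = [s for s in sibs if s != p]
        if sib_col and not others:
            continue
        row = [g]
        if sib_col:
            row.append(float(np.mean([G[gset.index_of(s), snp_index]
                                      for s in others])))
        pc = parent_cols(p)
        if pc[0] == "parsum":
            parsum = pc[1]
            row += [parsum] if use_alpha else [parsum / 2.0, parsum / 2.0]
        else:
            gp, gm = pc[1], pc[2]
            if gp is None or gm is None:
                continue  # missing imputation for an ungenotyped parent
            row += [gp + gm] if use_alpha else [gp, gm]
        rows.append(row)
        ids.append(p)
    return np.array(rows), tuple(labels), ids


def assemble_dataset(families, snp_index, gset, imputed, phenotypes,
                     spec: DesignSpec):
    """Stack per-family designs into (y, X, fam_index, labels).

    Families whose class identifies no parental information (proband-only)
    are excluded from the combined regression, as their single column does
    not separate direct effects from NTCs.
    """
    ys, Xs, fidx = [], [], []
    labels = None
    for k, fam in enumerate(families):
        if fam.design_class in (DesignClass.PROBAND_ONLY,
                                DesignClass.NOT_IMPUTABLE):
            continue
        X, lab, ids = assemble_design(fam, snp_index, gset, imputed, spec)
        if len(X) == 0:
            continue
        keep = [i for i, pid in enumerate(ids) if pid in phenotypes]
        if not keep:
            continue
        labels = lab
        Xs.append(X[keep])
        ys.extend(phenotypes[ids[i]] for i in keep)
        fidx.extend([k] * len(keep))
    if labels is None:
        raise ValueError("no usable families for the combined regression")
    return (np.array(ys), np.vstack(Xs), np.array(fidx), labels)


# ---------------------------------------------------------------------------
# Benchmark and robust estimators
# ---------------------------------------------------------------------------

def sibdiff_estimate(y_pairs: np.ndarray, g_pairs: np.ndarray):
    """Within-pair difference regression; unbiased for delta - eta_s.

    ``y_pairs`` and ``g_pairs`` have shape (n_pairs, 2). Returns (estimate,
    SE). Raises when genotype differences are all zero.
    """
    dy = y_pairs[:, 0] - y_pairs[:, 1]
    dg = g_pairs[:, 0] - g_pairs[:, 1]
    ss = float(np.dot(dg, dg))
    if ss == 0:
        raise ValueError("no within-pair genotype variation")
    est = float(np.dot(dg, dy)) / ss
    resid = dy - est * dg
    dof = max(len(dy) - 1, 1)
    se = float(np.sqrt(np.dot(resid, resid) / dof / ss))
    return est, se


def robust_split_estimate(groups, vc: VarianceComponents,
                          min_families: int = 30):
    """Structure-robust direct effect: fit each observed-parental-allele
    group separately and combine the delta estimates by inverse variance.

    ``groups`` maps the number of observed parental alleles to
    (y, X, fam_index, labels) tuples. Groups below ``min_families`` families
    are merged into the nearest group. Unbiased under population structure
    because within each group the imputation error is uncorrelated with the
    within-group genotype variation.
    """
    keys = sorted(groups)
    merged: dict[int, list] = {}
    for k in keys:
        y, X, fidx, labels = groups[k]
        n_fam = len(np.unique(fidx))
        tgt = k
        if n_fam < min_families and len(keys) > 1:
            others = [o for o in keys if o != k]
            tgt = min(others, key=lambda o: abs(o - k))
            warnings.warn(f"group n_obs={k} has {n_fam} families; "
                          f"merged into n_obs={tgt}")
        merged.setdefault(tgt, []).append(groups[k])
    ests, ws = [], []
    for k, parts in merged.items():
        y = np.concatenate([p[0] for p in parts])
        X = np.vstack([p[1] for p in parts])
        # offset family indices so merged groups do not collide
        offs, fidx = 0, []
        for p in parts:
            fidx.append(p[2] + offs)
            offs += p[2].max() + 1
        fidx = np.concatenate(fidx)
        order = np.argsort(fidx, kind="stable")
        try:
            est = estimate_snp_effects(y[order], X[order], fidx[order], vc,
                                       parts[0][3])
        except np.linalg.LinAlgError:
            # e.g. the two-observed-allele (IBD2) group, where the imputed
            # parental sum is collinear with the proband genotype
            warnings.warn(f"group n_obs={k} is rank-deficient; skipped")
            continue
        i = est.labels.index("direct")
        ests.append(est.estimates[i])
        ws.append(1.0 / est.covariance[i, i])
    ests, ws = np.array(ests), np.array(ws)
    delta = float(np.sum(ws * ests) / np.sum(ws))
    se = float(np.sqrt(1.0 / np.sum(ws)))
    return delta, se


# ---------------------------------------------------------------------------
# Genome-wide driver
# ---------------------------------------------------------------------------

def gwas(gset: PhasedGenotypeSet, families, imputed, phenotypes: PhenotypeVector,
         spec: DesignSpec | None = None,
         vc: VarianceComponents | None = None) -> list[SummaryStatRow]:
    """Estimate effects for every SNP and return summary-statistic rows.

    Variance components default to the null-model ML fit on the phenotyped
    probands. Monomorphic SNPs are skipped.
    """
    spec = spec or DesignSpec()
    usable = [f for f in families
              if f.design_class not in (DesignClass.PROBAND_ONLY,
                                        DesignClass.NOT_IMPUTABLE)]
    only_sibs = all(f.design_class == DesignClass.SIB_PAIRS_NO_PARENTS
                    for f in usable)
    if only_sibs and spec.separate_ntc:
        spec = DesignSpec(spec.model, separate_ntc=False)

    if vc is None:
        ys, fidx = [], []
        for k, fam in enumerate(usable):
            for o in fam.offspring_ids:
                if o in phenotypes:
                    ys.append(phenotypes[o])
                    fidx.append(k)
        vc = fit_null_varcomps(np.array(ys), np.array(fidx))

    # vectorized assembly: per-row column sources gathered once for all SNPs
    G = gset.genotypes().astype(float)
    G[G < 0] = np.nan
    sib_col = spec.model == Model.WITH_SIB_IGE
    use_alpha = not spec.separate_ntc
    y_rows, fam_rows = [], []
    dir_rows = []          # proband genotype rows of G
    sib_rows = []          # (L,) sibling-mean genotype per row
    fa_rows, mo_rows = [], []  # (L,) father / mother columns per row
    for k, fam in enumerate(usable):
        sibs = [s for s in fam.genotyped_offspring if s in gset]
        imp = imputed.get(fam.family_id)
        father_obs = fam.father_id and fam.genotyped.get(fam.father_id, False) \
            and fam.father_id in gset
        mother_obs = fam.mother_id and fam.genotyped.get(fam.mother_id, False) \
            and fam.mother_id in gset
        fa_col = mo_col = None
        if father_obs:
            fa_col = G[gset.index_of(fam.father_id)]
        if mother_obs:
            mo_col = G[gset.index_of(fam.mother_id)]
        if imp is not None:
            if imp.kind == ImputedKind.FATHER:
                fa_col = imp.values
            elif imp.kind == ImputedKind.MOTHER:
                mo_col = imp.values
            else:
                fa_col = imp.values / 2.0
                mo_col = imp.values / 2.0
        if fa_col is None or mo_col is None:
            continue
        for p in sibs:
            if not fam.phenotyped.get(p, False) or p not in phenotypes:
                continue
            others = [s for s in sibs if s != p]
            if sib_col and not others:
                continue
            y_rows.append(phenotypes[p])
            fam_rows.append(k)
            dir_rows.append(gset.index_of(p))
            if sib_col:
                sib_rows.append(np.mean([G[gset.index_of(s)] for s in others],
                                        axis=0))
            fa_rows.append(fa_col)
            mo_rows.append(mo_col)
    if not y_rows:
        raise ValueError("no usable families for the combined regression")
    y_all = np.array(y_rows)
    fam_all = np.array(fam_rows)
    order = np.argsort(fam_all, kind="stable")
    y_all, fam_all = y_all[order], fam_all[order]
    col_dir = G[np.array(dir_rows)][order]
    col_fa = np.vstack(fa_rows)[order]
    col_mo = np.vstack(mo_rows)[order]
    col_sib = np.vstack(sib_rows)[order] if sib_col else None

    labels = ["direct"]
    if sib_col:
        labels.append("eta_s")
    labels += ["alpha"] if use_alpha else ["alpha_p", "alpha_m"]
    labels = tuple(labels)

    rows = []
    for j, variant in enumerate(gset.variants):
        cols = [col_dir[:, j]]
        if sib_col:
            cols.append(col_sib[:, j])
        if use_alpha:
            cols.append(col_fa[:, j] + col_mo[:, j])
        else:
            cols += [col_fa[:, j], col_mo[:, j]]
        X = np.column_stack(cols)
        if np.nanstd(X[:, 0]) == 0:
            continue  # monomorphic
        try:
            est = estimate_snp_effects(y_all, X, fam_all, vc, labels)
        except np.linalg.LinAlgError:
            continue
        beta, var_beta = population_effect(est)
        rows.append(SummaryStatRow(variant, est.labels, est.estimates,
                                   est.covariance, beta_pop=beta,
                                   var_beta_pop=var_beta,
                                   n_eff=est.n_individuals))
    return rows
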