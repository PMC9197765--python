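"""Nuclear-family construction and missing-data-pattern classification.

A nuclear family is represented canonically by four genotype slots
(offspring 1, offspring 2, father, mother). Of the 2^4 - 1 = 15 nonempty
observation patterns, seven admit a *nonlinear* Mendelian imputation of the
missing parental genotype(s) — i.e. the conditional expectation of the
missing quantity given the observed genotypes differs from the best linear
predictor — and therefore add information for estimating direct effects and
non-transmitted coefficients. The classifier here establishes this by exact
enumeration of the finite joint genotype distribution under Hardy–Weinberg
equilibrium and Mendelian transmission, not by a lookup table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genio import MISSING, PedigreeTable, PhasedGenotypeSet

__all__ = [
    "DesignClass",
    "ObservationPattern",
    "FamilyUnit",
    "build_families",
    "enumerate_patterns",
    "classify_nonlinear",
    "family_joint_pmf",
]


class DesignClass(Enum):
    PROBAND_ONLY = "proband_only"
    SIB_PAIRS_NO_PARENTS = "sib_pairs_no_parents"
    ONE_PARENT_ONE_OFFSPRING = "one_parent_one_offspring"
    ONE_PARENT_MULTI_SIB = "one_parent_multi_sib"
    TRIO = "trio"
    BOTH_PARENTS_ONE_OFFSPRING = "trio"  # alias: same design as a trio
    QUAD_BOTH_PARENTS_SIBS = "quad_both_parents_sibs"
    NOT_IMPUTABLE = "not_imputable"


@dataclass(frozen=True)
class ObservationPattern:
    """Canonical two-offspring genotype-observation pattern."""

    offspring1_genotyped: bool
    offspring2_genotyped: bool
    father_genotyped: bool
    mother_genotyped: bool
    nonlinear_imputable: bool = field(default=False, compare=False)

    @property
    def flags(self):
        return (self.offspring1_genotyped, self.offspring2_genotyped,
                self.father_genotyped, self.mother_genotyped)


@dataclass
class FamilyUnit:
    """One nuclear family: parents (possibly ungenotyped) and n_i >= 1 offspring."""

    family_id: str
    father_id: str
    mother_id: str
    offspring_ids: list[str]
    genotyped: dict[str, bool]
    phenotyped: dict[str, bool]
    pattern: ObservationPattern | None = None
    design_class: DesignClass = DesignClass.NOT_IMPUTABLE

    @property
    def n_offspring(self) -> int:
        return len(self.offspring_ids)

    @property
    def genotyped_offspring(self) -> list[str]:
        return [o for o in self.offspring_ids if self.genotyped.get(o, False)]

    @property
    def genotyped_parents(self) -> list[str]:
        return [p for p in (self.father_id, self.mother_id)
                if p and self.genotyped.get(p, False)]


# ---------------------------------------------------------------------------
# Exact joint genotype distribution of a two-offspring nuclear family
# ---------------------------------------------------------------------------

def family_joint_pmf(f: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint pmf of (g1, g2, g_p, g_m, IBD) for a sibling pair under HWE.

    Enumerates the four parental alleles (each Bernoulli(f)) and the four
    independent uniform transmission choices. Returns (configs, probs) where
    configs has columns (g1, g2, g_p, g_m, ibd) with ibd the siblings' IBD
    state in {0, 1, 2}.
    """
    rows, probs = [], []
    for alleles in itertools.product((0, 1), repeat=4):
        p1, p2, m1, m2 = alleles
        pa = np.prod([f if a == 1 else 1 - f for a in alleles])
        gp, gm = p1 + p2, m1 + m2
        for x1, y1, x2, y2 in itertools.product((0, 1), repeat=4):
            g1 = (p1, p2)[x1] + (m1, m2)[y1]
            g2 = (p1, p2)[x2] + (m1, m2)[y2]
            ibd = int(x1 == x2) + int(y1 == y2)
            rows.append((g1, g2, gp, gm, ibd))
            probs.append(pa / 16.0)
    return np.array(rows), np.array(probs)


def classify_nonlinear(pattern: ObservationPattern, freq: float = 0.3,
                       tol: float = 1e-9) -> bool:
    """True iff the conditional expectation of the missing parental
    genotype(s) given the observed genotypes is a nonlinear function of them.

    The target is the sum of the unobserved parental genotypes; patterns with
    both parents observed have nothing to impute and classify False. When
    both offspring are genotyped, the siblings' IBD state is part of the
    observed data (the imputation conditions on it), so it joins the
    conditioning set. The check enumerates the exact finite joint
    distribution at ``freq``.
    """
    if not (0 < freq < 1):
        raise ValueError("freq must be in (0, 1)")
    obs_idx = [i for i, flag in enumerate(pattern.flags) if flag]
    missing_parents = [i for i in (2, 3) if not pattern.flags[i]]
    if not obs_idx or not missing_parents:
        return False
    if pattern.offspring1_genotyped and pattern.offspring2_genotyped:
        obs_idx = obs_idx + [4]  # sibling IBD state
    configs, probs = family_joint_pmf(freq)
    target = configs[:, missing_parents].sum(axis=1).astype(float)
    obs = configs[:, obs_idx].astype(float)

    # conditional expectation per observed combination
    keys = [tuple(row) for row in obs]
    cond: dict[tuple, float] = {}
    for k in set(keys):
        sel = np.array([kk == k for kk in keys])
        w = probs[sel]
        cond[k] = float(np.dot(w, target[sel]) / w.sum())

    # best linear predictor under the same pmf (weighted least squares)
    X = np.column_stack([np.ones(len(obs)), obs])
    W = probs
    coef, *_ = np.linalg.lstsq((X * W[:, None]).T @ X, (X * W[:, None]).T @ target,
                               rcond=None)
    for k, e_cond in cond.items():
        e_lin = coef[0] + float(np.dot(coef[1:], k))
        if abs(e_cond - e_lin) > tol:
            return True
    return False


def enumerate_patterns(freq: float = 0.3) -> list[ObservationPattern]:
    """All 15 nonempty observation patterns, tagged nonlinear_imputable."""
    out = []
    for flags in itertools.product((True, False), repeat=4):
        if not any(flags):
            continue
        p = ObservationPattern(*flags)
        out.append(ObservationPattern(*flags,
                                      nonlinear_imputable=classify_nonlinear(p, freq)))
    return out


# ---------------------------------------------------------------------------
# Family construction
# ---------------------------------------------------------------------------

def _design_class(n_geno_off: int, n_geno_par: int) -> DesignClass:
    if n_geno_off == 0:
        return DesignClass.NOT_IMPUTABLE
    if n_geno_par == 2:
        return DesignClass.TRIO if n_geno_off == 1 else DesignClass.QUAD_BOTH_PARENTS_SIBS
    if n_geno_par == 1:
        return (DesignClass.ONE_PARENT_ONE_OFFSPRING if n_geno_off == 1
                else DesignClass.ONE_PARENT_MULTI_SIB)
    return (DesignClass.PROBAND_ONLY if n_geno_off == 1
            else DesignClass.SIB_PAIRS_NO_PARENTS)


def _observation_pattern(fam: FamilyUnit) -> ObservationPattern:
    geno_off = fam.genotyped_offspring
    flags = (
        len(geno_off) >= 1,
        len(geno_off) >= 2,
        bool(fam.father_id) and fam.genotyped.get(fam.father_id, False),
        bool(fam.mother_id) and fam.genotyped.get(fam.mother_id, False),
    )
    p = ObservationPattern(*flags)
    return ObservationPattern(*flags, nonlinear_imputable=classify_nonlinear(p))


def _find_mz_duplicates(gset: PhasedGenotypeSet, ids: list[str],
                        max_discordance: float = 0.001,
                        min_snps: int = 1000) -> set[str]:
    """Detect monozygotic-twin/duplicate genotype pairs among ``ids``.

    Pairs with genotype discordance below ``max_discordance`` over at least
    ``min_snps`` jointly observed SNPs are flagged; the second member of each
    pair is returned for removal.
    """
    if gset.n_snps < min_snps:
        return set()
    g = gset.genotypes()
    drop: set[str] = set()
    for a, b in itertools.combinations(ids, 2):
        if a in drop or b in drop:
            continue
        ga, gb = g[gset.index_of(a)], g[gset.index_of(b)]
        ok = (ga != MISSING) & (gb != MISSING)
        if ok.sum() < min_snps:
            continue
        if np.mean(ga[ok] != gb[ok]) < max_discordance:
            drop.add(b)
    return drop


def build_families(ped: PedigreeTable, genotyped_ids: set[str],
                   genotypes: PhasedGenotypeSet | None = None) -> list[FamilyUnit]:
    """Group pedigree individuals into nuclear families and classify them.

    Offspring sharing the same (father_id, mother_id) pair form one family.
    Half-sibships (a parent appearing with multiple partners) are excluded
    with a warning, matching the full-nuclear-family scope. When a genotype
    set is supplied, monozygotic-duplicate offspring pairs are detected and
    one member of each pair is dropped.
    """
    t = ped.table
    genotyped = {str(i) for i in genotyped_ids}

    partner_of: dict[str, set[str]] = {}
    for r in t.itertuples():
        if r.father_id and r.mother_id:
            partner_of.setdefault(r.father_id, set()).add(r.mother_id)
            partner_of.setdefault(r.mother_id, set()).add(r.father_id)
    multi = {p for p, partners in partner_of.items() if len(partners) > 1}
    if multi:
        warnings.warn(
            f"excluding half-sib families of {len(multi)} repartnered parent(s): "
            f"{sorted(multi)[:5]}"
        )

    groups: dict[tuple[str, str], list] = {}
    for r in t.itertuples():
        if not (r.father_id or r.mother_id):
            continue
        if r.father_id in multi or r.mother_id in multi:
            continue
        groups.setdefault((r.father_id, r.mother_id), []).append(r)

    families: list[FamilyUnit] = []
    used: set[str] = set()
    pheno_flag = dict(zip(t["individual_id"], t["phenotyped"]))
    for k, ((fid, mid), rows) in enumerate(sorted(groups.items())):
        offspring = sorted(r.individual_id for r in rows)
        fam = FamilyUnit(
            family_id=f"F{k}",
            father_id=fid,
            mother_id=mid,
            offspring_ids=offspring,
            genotyped={i: i in genotyped
                       for i in offspring + [p for p in (fid, mid) if p]},
            phenotyped={i: bool(pheno_flag.get(i, True)) for i in offspring},
        )
        if genotypes is not None:
            geno_off = [o for o in fam.genotyped_offspring if o in genotypes]
            dups = _find_mz_duplicates(genotypes, geno_off)
            if dups:
                warnings.warn(
                    f"family {fam.family_id}: dropping MZ-duplicate member(s) {sorted(dups)}"
                )
                fam.offspring_ids = [o for o in fam.offspring_ids if o not in dups]
        fam.pattern = _observation_pattern(fam)
        fam.design_class = _design_class(len(fam.genotyped_offspring),
                                         len(fam.genotyped_parents))
        families.append(fam)
        used.update(fam.offspring_ids)
        used.update(p for p in (fid, mid) if p)

    # genotyped individuals with no family link become proband-only singletons
    for r in t.itertuples():
        iid = r.individual_id
        if iid in used or iid not in genotyped:
            continue
        fam = FamilyUnit(
            family_id=f"S{iid}", father_id="", mother_id="",
            offspring_ids=[iid], genotyped={iid: True},
            phenotyped={iid: bool(pheno_flag.get(iid, True))},
        )
        fam.pattern = _observation_pattern(fam)
        fam.design_class = DesignClass.PROBAND_ONLY
        families.append(fam)
    return families
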