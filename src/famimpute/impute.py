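"""Mendelian imputation of missing parental genotypes.

A missing parental genotype is replaced by its exact conditional expectation
given the observed family genotypes, the siblings' IBD state, and (when
available) phase. These conditional expectations are *nonlinear* functions of
the observed genotypes, which is what lets them add information for effect
estimation. Unobserved parental alleles are imputed with the allele-1
frequency ``f``.

Closed forms for the two-member classes:

* sibling pair, no parents (imputes the parental sum g_par = g_p + g_m):
  IBD0 -> g1 + g2 (all four parental alleles observed);
  IBD1 -> g1 + g2_notshared + f (three observed);
  IBD2 -> g1 + 2f (two observed);
  IBD1 with both siblings heterozygous and no phase -> 1 + 2f (average over
  the two possible shared alleles).
* one parent + one offspring (imputes the missing parent): the allele the
  missing parent transmitted, a, is determined unless offspring and observed
  parent are both heterozygous; imputed value a + f, or 2f in the unresolved
  unphased case.

Larger sibships and sibships with one genotyped parent are handled by exact
posterior enumeration over the parental alleles and per-sibling transmission
choices, conditioned on the pairwise IBD configuration — the same principle
(conditional expectation under Mendelian transmission and HWE priors),
evaluated numerically.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genio import MISSING, PhasedGenotypeSet
from .ibd import IbdPath
from .pedigree import DesignClass, FamilyUnit

__all__ = [
    "ImputedKind",
    "SibPairSnpView",
    "ImputedParentalGenotypes",
    "impute_parsum_sibs",
    "resolve_shared_allele",
    "impute_parent_from_parent_offspring",
    "impute_parsum_nsibs",
    "impute_parent_from_sibs_and_parent",
    "linear_impute_baseline",
    "imputation_diagnostics",
    "impute_families",
    "mendelian_consistent_pair",
]


class ImputedKind(Enum):
    PAR_SUM = "par_sum"
    FATHER = "father"
    MOTHER = "mother"


@dataclass
class SibPairSnpView:
    """One sibling pair at one SNP: genotypes, optional phase, IBD state."""

    g1: int
    g2: int
    ibd_state: int
    hap1: tuple[int, int] | None = None
    hap2: tuple[int, int] | None = None
    g2_notshared: int | None = None  # defined only in IBD1


@dataclass
class ImputedParentalGenotypes:
    """Imputed parental dosages for one family across SNPs.

    ``values`` lie in [0, 4] for PAR_SUM and [0, 2] otherwise; ``n_observed``
    counts the parental alleles observed per SNP (sib pairs: 4 - IBD state).
    NaN marks SNPs imputed as missing (Mendelian inconsistencies).
    """

    family_id: str
    kind: ImputedKind
    values: np.ndarray
    n_observed: np.ndarray
    phased_used: bool = False
    qc_flags: np.ndarray | None = None


def mendelian_consistent_pair(g1: int, g2: int, ibd: int) -> bool:
    """Whether a sibling genotype pair is possible in the claimed IBD state."""
    if ibd == 2:
        return g1 == g2
    if ibd == 1:
        return not ({g1, g2} == {0, 2})
    return True


# ---------------------------------------------------------------------------
# Sibling pairs
# ---------------------------------------------------------------------------

def _notshared_from_genotypes(g1: int, g2: int) -> int | None:
    """Sibling 2's non-shared allele in IBD1, when genotypes determine it."""
    if g1 == 0:
        return g2          # shared allele is 0
    if g1 == 2:
        return g2 - 1      # shared allele is 1
    # g1 == 1
    if g2 == 0:
        return 0
    if g2 == 2:
        return 1
    return None            # both heterozygous: needs phase


def impute_parsum_sibs(view: SibPairSnpView, f: float) -> float:
    """E[g_par | g1, g2, IBD state (, phase)] for a sibling pair.

    A genotype pair inconsistent with the claimed IBD state falls back to the
    IBD0 imputation g1 + g2 (the caller counts these in QC).
    """
    g1, g2, ibd = view.g1, view.g2, view.ibd_state
    if not mendelian_consistent_pair(g1, g2, ibd):
        return float(g1 + g2)
    if ibd == 0:
        return float(g1 + g2)
    if ibd == 2:
        return g1 + 2.0 * f
    ns = _notshared_from_genotypes(g1, g2)
    if ns is None:
        ns = None if view.g2_notshared is None else int(view.g2_notshared)
    if ns is None:
        return 1.0 + 2.0 * f   # unphased both-heterozygous average
    return g1 + ns + f


def resolve_shared_allele(hapA: np.ndarray, hapB: np.ndarray, target: int,
                          seg_lo: int, seg_hi: int) -> int | None:
    """Resolve the IBD-shared allele at a doubly heterozygous target SNP.

    ``hapA``/``hapB`` are (L, 2) phased haplotype arrays for two individuals
    sharing exactly one allele IBD throughout SNP index range
    [seg_lo, seg_hi). Searches outward from ``target`` for the nearest
    informative SNP — one individual homozygous, the other heterozygous —
    whose phase identifies the shared haplotype. Equidistant informative
    SNPs that disagree, or no informative SNP in the segment, leave the
    allele unresolved (None).
    """
    L = seg_hi - seg_lo
    for dist in range(1, L):
        votes = []
        for k in (target - dist, target + dist):
            if not (seg_lo <= k < seg_hi):
                continue
            s = _shared_allele_from_neighbor(hapA, hapB, target, k)
            if s is not None:
                votes.append(s)
        if votes:
            if len(votes) == 2 and votes[0] != votes[1]:
                return None
            return votes[0]
    return None


def _shared_allele_from_neighbor(hapA, hapB, target: int, k: int) -> int | None:
    a0, a1 = int(hapA[k, 0]), int(hapA[k, 1])
    b0, b1 = int(hapB[k, 0]), int(hapB[k, 1])
    if MISSING in (a0, a1, b0, b1):
        return None
    if a0 == a1 and b0 != b1:
        hom_allele, het = a0, hapB
    elif b0 == b1 and a0 != a1:
        hom_allele, het = b0, hapA
    else:
        return None
    h = 0 if int(het[k, 0]) == hom_allele else 1
    s = int(het[target, h])
    return None if s == MISSING else s


# ---------------------------------------------------------------------------
# Parent-offspring pairs
# ---------------------------------------------------------------------------

def impute_parent_from_parent_offspring(g_o: int, g_obs_parent: int,
                                        transmitted: int | None,
                                        f: float) -> float:
    """E[missing parent's genotype | offspring, observed parent (, phase)].

    ``transmitted`` is the allele the missing parent transmitted to the
    offspring when phase has resolved it; Mendelian-inconsistent pairs are
    imputed as missing (NaN).
    """
    if (g_o == 2 and g_obs_parent == 0) or (g_o == 0 and g_obs_parent == 2):
        return np.nan
    a: int | None
    if g_obs_parent == 0:
        a = g_o
    elif g_obs_parent == 2:
        a = g_o - 1
    elif g_o == 0:
        a = 0
    elif g_o == 2:
        a = 1
    else:
        a = transmitted
    if a is None:
        return 2.0 * f       # doubly heterozygous, unphased
    return a + f


# ---------------------------------------------------------------------------
# Exact posterior enumeration for general sibships
# ---------------------------------------------------------------------------

def _enumerate_nuclear(sib_genotypes, pairwise_ibd, f: float,
                       g_father: int | None = None,
                       g_mother: int | None = None):
    """Posterior over parental allele pairs for a sibship at one SNP.

    Enumerates ordered paternal alleles (p1, p2) and maternal alleles
    (m1, m2) — HWE(f) priors for an ungenotyped parent, orderings of the
    observed genotype otherwise — and each sibling's transmission choice
    (which paternal and which maternal allele), conditioned on the pairwise
    IBD configuration. When the stated configuration admits no assignment,
    the best-supported consistent configurations (maximum number of pairwise
    constraints satisfied) are used instead.

    Returns (E[g_p], E[g_m], n_observed_alleles, ok) where n_observed is the
    posterior-modal count of distinct parental alleles transmitted to the
    sibship, and ok is False when the sib genotypes are jointly impossible.
    """
    n = len(sib_genotypes)

    def parent_states(g_obs):
        if g_obs is None:
            q = 1 - f
            return [((0, 0), q * q), ((0, 1), q * f), ((1, 0), f * q),
                    ((1, 1), f * f)]
        if g_obs == 1:
            return [((0, 1), 0.5), ((1, 0), 0.5)]
        a = g_obs // 2
        return [((a, a), 1.0)]

    assigns = list(itertools.product(range(2), repeat=2 * n))
    pair_list = list(pairwise_ibd.items())

    def n_satisfied(asg):
        sat = 0
        for (j, k), s in pair_list:
            got = int(asg[2 * j] == asg[2 * k]) + int(asg[2 * j + 1] == asg[2 * k + 1])
            if got == s:
                sat += 1
        return sat

    sat_counts = np.array([n_satisfied(a) for a in assigns])
    best = sat_counts.max() if len(pair_list) else 0
    valid = [a for a, c in zip(assigns, sat_counts) if c == best]

    e_gp = e_gm = 0.0
    total = 0.0
    obs_weight: dict[int, float] = {}
    for (pp, wp) in parent_states(g_father):
        for (mm, wm) in parent_states(g_mother):
            for asg in valid:
                ok = True
                for j, g in enumerate(sib_genotypes):
                    if pp[asg[2 * j]] + mm[asg[2 * j + 1]] != g:
                        ok = False
                        break
                if not ok:
                    continue
                w = wp * wm / (4.0 ** n)
                total += w
                e_gp += w * (pp[0] + pp[1])
                e_gm += w * (mm[0] + mm[1])
                n_obs = len({asg[2 * j] for j in range(n)}) \
                    + len({asg[2 * j + 1] for j in range(n)})
                obs_weight[n_obs] = obs_weight.get(n_obs, 0.0) + w
    if total == 0:
        return np.nan, np.nan, 0, False
    n_obs_mode = max(obs_weight, key=obs_weight.get)
    return e_gp / total, e_gm / total, n_obs_mode, True


def impute_parsum_nsibs(sib_genotypes, pairwise_ibd: dict, f: float):
    """Impute the parental-genotype sum from n >= 2 genotyped siblings.

    ``pairwise_ibd`` maps sibling index pairs (j, k) to their IBD state at
    this SNP. Returns (imputed value, n_observed_parental_alleles).
    """
    e_gp, e_gm, n_obs, ok = _enumerate_nuclear(sib_genotypes, pairwise_ibd, f)
    if not ok:
        return np.nan, 0
    return e_gp + e_gm, n_obs


def impute_parent_from_sibs_and_parent(sib_genotypes, pairwise_ibd: dict,
                                       g_obs_parent: int, f: float,
                                       observed_is_mother: bool = True):
    """Impute the missing parent from >= 2 siblings plus one genotyped parent."""
    kw = {"g_mother": g_obs_parent} if observed_is_mother \
        else {"g_father": g_obs_parent}
    e_gp, e_gm, n_obs, ok = _enumerate_nuclear(sib_genotypes, pairwise_ibd, f, **kw)
    if not ok:
        return np.nan, 0
    return (e_gp if observed_is_mother else e_gm), n_obs


# ---------------------------------------------------------------------------
# Linear baseline and diagnostics
# ---------------------------------------------------------------------------

def linear_impute_baseline(observed, f: float, design_class: DesignClass) -> float:
    """Best linear unbiased predictor of the missing parental quantity.

    Sibling pairs: predicts g_par from (g1, g2) with coefficients (2/3, 2/3)
    (population R^2 = 2/3). Parent-offspring: predicts the missing parent
    from (g_offspring, g_observed_parent) with coefficients (2/3, -1/3)
    (R^2 = 1/3). Both follow from the Mendelian covariance structure under
    HWE: var(g) = 2fq, cov(sibs) = fq, cov(parent, offspring) = fq.
    """
    if design_class == DesignClass.SIB_PAIRS_NO_PARENTS:
        g1, g2 = observed
        return 4 * f + (2.0 / 3.0) * ((g1 - 2 * f) + (g2 - 2 * f))
    if design_class == DesignClass.ONE_PARENT_ONE_OFFSPRING:
        g_o, g_par = observed
        return 2 * f + (2.0 / 3.0) * (g_o - 2 * f) - (1.0 / 3.0) * (g_par - 2 * f)
    raise ValueError(f"no linear baseline for {design_class}")


def imputation_diagnostics(imputed, truth):
    """(slope of truth regressed on imputed, squared correlation).

    A slope of 1 certifies unbiased imputation: the covariance between the
    imputed and true values equals the variance of the imputed values for a
    conditional-expectation imputation.
    """
    imputed = np.asarray(imputed, dtype=float)
    truth = np.asarray(truth, dtype=float)
    ok = np.isfinite(imputed) & np.isfinite(truth)
    imputed, truth = imputed[ok], truth[ok]
    ic = imputed - imputed.mean()
    tc = truth - truth.mean()
    v = float(ic @ ic)
    if v == 0:
        raise ValueError("zero variance in imputed values")
    cov = float(ic @ tc)
    slope = cov / v
    r2 = cov ** 2 / (v * float(tc @ tc))
    return slope, r2


# ---------------------------------------------------------------------------
# Family-level driver
# ---------------------------------------------------------------------------

def _ibd1_segments(states: np.ndarray):
    """Index ranges [lo, hi) of maximal IBD1 runs."""
    segs = []
    lo = None
    for i, s in enumerate(states):
        if s == 1 and lo is None:
            lo = i
        elif s != 1 and lo is not None:
            segs.append((lo, i))
            lo = None
    if lo is not None:
        segs.append((lo, len(states)))
    return segs


def _impute_sib_pair(g1, g2, hap1, hap2, states, freqs, phased, qc):
    """Vectorized sibling-pair imputation; the closed forms of
    :func:`impute_parsum_sibs` applied SNP-wise, with phase resolution only
    where it is needed (doubly heterozygous IBD1 SNPs)."""
    g1 = g1.astype(np.int16)
    g2 = g2.astype(np.int16)
    bad = ((states == 2) & (g1 != g2)) | \
          ((states == 1) & (np.minimum(g1, g2) == 0) & (np.maximum(g1, g2) == 2))
    qc["inconsistent"] += int(bad.sum())

    # IBD1 non-shared allele of sibling 2, where genotypes determine it
    ns = np.select(
        [g1 == 0, g1 == 2, g2 == 0, g2 == 2],
        [g2, g2 - 1, 0, 1],
        default=-1,
    ).astype(np.float64)
    both_het = (states == 1) & (g1 == 1) & (g2 == 1) & ~bad
    if phased and hap1 is not None and both_het.any():
        segs = _ibd1_segments(states)
        seg_of = np.full(len(states), -1, dtype=int)
        for si, (lo, hi) in enumerate(segs):
            seg_of[lo:hi] = si
        for j in np.flatnonzero(both_het):
            lo, hi = segs[seg_of[j]]
            r = _notshared_from_phase(hap1, hap2, j, lo, hi)
            if r is not None:
                ns[j] = r

    v_ibd1 = np.where(both_het & (ns < 0), 1.0 + 2 * freqs, g1 + ns + freqs)
    values = np.select(
        [bad, states == 0, states == 2],
        [(g1 + g2).astype(float), (g1 + g2).astype(float), g1 + 2 * freqs],
        default=v_ibd1,
    )
    n_obs = (4 - states).astype(int)
    return values, n_obs


def _notshared_from_phase(hap1, hap2, j, lo, hi):
    s = resolve_shared_allele(hap1, hap2, j, lo, hi)
    return None if s is None else 1 - s


def _transmitted_hap_index(hap_off, g_parent_arr):
    """Which offspring haplotype carries the observed parent's transmissions.

    Majority vote over SNPs where the parent is homozygous and the offspring
    heterozygous; the parent's allele must sit on exactly one offspring
    haplotype there. Returns 0, 1 or None (tie / no informative SNP).
    """
    hom = (g_parent_arr == 0) | (g_parent_arr == 2)
    het = hap_off[:, 0] != hap_off[:, 1]
    obs = (hap_off[:, 0] != MISSING) & (hap_off[:, 1] != MISSING) \
        & (g_parent_arr != MISSING)
    info = np.flatnonzero(hom & het & obs)
    if len(info) == 0:
        return None
    allele = (g_parent_arr[info] // 2).astype(np.int8)
    votes0 = int(np.sum(hap_off[info, 0] == allele))
    votes1 = len(info) - votes0
    if votes0 == votes1:
        return None
    return 0 if votes0 > votes1 else 1


def _impute_po_pair(g_o, hap_o, g_par, freqs, phased, missing_kind, qc):
    L = len(freqs)
    values = np.empty(L)
    h = _transmitted_hap_index(hap_o, g_par) if (phased and hap_o is not None) \
        else None
    for j in range(L):
        transmitted = None
        if h is not None and g_o[j] == 1 and g_par[j] == 1:
            # allele on the *other* haplotype came from the missing parent
            a = int(hap_o[j, 1 - h])
            transmitted = None if a == MISSING else a
        values[j] = impute_parent_from_parent_offspring(
            int(g_o[j]), int(g_par[j]), transmitted, freqs[j])
        if np.isnan(values[j]):
            qc["inconsistent"] += 1
    n_obs = np.full(L, 3, dtype=int)  # both of the observed parent's + one transmitted
    return values, n_obs


def impute_families(gset: PhasedGenotypeSet, families: list[FamilyUnit],
                    ibd_paths: dict[tuple[str, str], IbdPath] | None = None,
                    phased: bool = True) -> dict[str, ImputedParentalGenotypes]:
    """Impute missing parental genotypes for every imputable family.

    ``ibd_paths`` maps genotyped sibling-pair ID tuples (either order) to
    their inferred IBD paths; required for families with >= 2 genotyped
    siblings and no full parent set. Returns a mapping family_id ->
    :class:`ImputedParentalGenotypes`; trio/quad families (nothing missing)
    and non-imputable families are absent from the result.
    """
    ibd_paths = ibd_paths or {}
    freqs = gset.freqs()
    G = gset.genotypes()
    out: dict[str, ImputedParentalGenotypes] = {}
    qc = {"inconsistent": 0}

    def path_for(a, b):
        p = ibd_paths.get((a, b)) or ibd_paths.get((b, a))
        if p is None:
            raise KeyError(f"no IBD path for sibling pair ({a}, {b})")
        return p

    for fam in families:
        cls = fam.design_class
        sibs = [s for s in fam.genotyped_offspring if s in gset]
        if cls == DesignClass.SIB_PAIRS_NO_PARENTS and len(sibs) == 2:
            i1, i2 = (gset.index_of(s) for s in sibs)
            states = path_for(sibs[0], sibs[1]).states
            vals, n_obs = _impute_sib_pair(
                G[i1], G[i2], gset.haplotypes[i1], gset.haplotypes[i2],
                states, freqs, phased, qc)
            out[fam.family_id] = ImputedParentalGenotypes(
                fam.family_id, ImputedKind.PAR_SUM, vals, n_obs, phased)
        elif cls == DesignClass.SIB_PAIRS_NO_PARENTS:
            vals, n_obs = _impute_nsib_family(G, gset, sibs, freqs, path_for)
            out[fam.family_id] = ImputedParentalGenotypes(
                fam.family_id, ImputedKind.PAR_SUM, vals, n_obs, False)
        elif cls == DesignClass.ONE_PARENT_ONE_OFFSPRING:
            obs_parent = fam.genotyped_parents[0]
            missing_kind = (ImputedKind.FATHER
                            if obs_parent == fam.mother_id else ImputedKind.MOTHER)
            io = gset.index_of(sibs[0])
            ip = gset.index_of(obs_parent)
            vals, n_obs = _impute_po_pair(G[io], gset.haplotypes[io], G[ip],
                                          freqs, phased, missing_kind, qc)
            out[fam.family_id] = ImputedParentalGenotypes(
                fam.family_id, missing_kind, vals, n_obs, phased)
        elif cls == DesignClass.ONE_PARENT_MULTI_SIB:
            obs_parent = fam.genotyped_parents[0]
            observed_is_mother = obs_parent == fam.mother_id
            missing_kind = (ImputedKind.FATHER if observed_is_mother
                            else ImputedKind.MOTHER)
            ip = gset.index_of(obs_parent)
            L = gset.n_snps
            vals = np.empty(L)
            n_obs = np.empty(L, dtype=int)
            pair_states = {
                (a, b): path_for(sibs[a], sibs[b]).states
                for a, b in itertools.combinations(range(len(sibs)), 2)
            }
            gs = [G[gset.index_of(s)] for s in sibs]
            for j in range(L):
                pibd = {k: int(v[j]) for k, v in pair_states.items()}
                vals[j], n_obs[j] = impute_parent_from_sibs_and_parent(
                    [int(g[j]) for g in gs], pibd, int(G[ip][j]), freqs[j],
                    observed_is_mother)
            out[fam.family_id] = ImputedParentalGenotypes(
                fam.family_id, missing_kind, vals, n_obs, False)
    if qc["inconsistent"]:
        warnings.warn(
            f"{qc['inconsistent']} SNP(s) inconsistent with the claimed IBD "
            "state or Mendelian transmission; imputed under the fallback rule"
        )
    return out


def write_imputed(imputed: dict[str, ImputedParentalGenotypes],
                  gset: PhasedGenotypeSet, path):
    """Export imputed dosages as a long-format TSV
    (family_id, snp_id, kind, value, n_obs_alleles, phased)."""
    import pandas as pd

    snp_ids = [v.snp_id for v in gset.variants]
    recs = []
    for imp in imputed.values():
        for j, sid in enumerate(snp_ids):
            recs.append((imp.family_id, sid, imp.kind.value,
                         imp.values[j], int(imp.n_observed[j]),
                         int(imp.phased_used)))
    pd.DataFrame(recs, columns=["family_id", "snp_id", "kind", "value",
                                "n_obs_alleles", "phased"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_imputed(path, gset: PhasedGenotypeSet) -> dict[str, ImputedParentalGenotypes]:
    """Load a TSV written by :func:`write_imputed`, aligned to ``gset``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "snp_id": str})
    order = {v.snp_id: j for j, v in enumerate(gset.variants)}
    out = {}
    for fid, sub in df.groupby("family_id", sort=False):
        L = len(order)
        vals = np.full(L, np.nan)
        n_obs = np.zeros(L, dtype=int)
        for rec in sub.itertuples():
            j = order.get(rec.snp_id)
            if j is None:
                continue
            vals[j] = rec.value
            n_obs[j] = rec.n_obs_alleles
        out[str(fid)] = ImputedParentalGenotypes(
            str(fid), ImputedKind(sub["kind"].iloc[0]), vals, n_obs,
            bool(sub["phased"].iloc[0]))
    return out


def _impute_nsib_family(G, gset, sibs, freqs, path_for):
    pair_states = {
        (a, b): path_for(sibs[a], sibs[b]).states
        for a, b in itertools.combinations(range(len(sibs)), 2)
    }
    gs = [G[gset.index_of(s)] for s in sibs]
    L = len(freqs)
    vals = np.empty(L)
    n_obs = np.empty(L, dtype=int)
    for j in range(L):
        pibd = {k: int(v[j]) for k, v in pair_states.items()}
        vals[j], n_obs[j] = impute_parsum_nsibs(
            [int(g[j]) for g in gs], pibd, freqs[j])
    return vals, n_obs
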