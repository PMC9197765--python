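"""Forward-in-time nuclear-family simulator.

Generates phased genotypes, pedigrees, true IBD segments (from recorded
crossovers) and phenotypes under configurable direct effects, parental and
sibling indirect genetic effects, vertical transmission, assortative mating
(AM), discrete-deme population stratification and phenotype-dependent
ascertainment. Every analysis module in this package is validated against
this simulator's ground truth.

Model per generation: couples are formed (randomly, or by noisy phenotype
rank matching calibrated to a target spousal correlation), each couple
produces two offspring by meiosis with Poisson crossovers on the genetic map
(Haldane, no interference), and offspring phenotypes are

    Y = sum_l delta_l g_l                      (direct)
      + sum_l w_l (g_p,l + g_m,l)              (parental IGE)
      + eta_s * sum_l delta_l g_sib,l / ||.||  (sibling IGE, see below)
      + v_vt (Y_p + Y_m)                       (vertical transmission)
      + deme offset + Gaussian noise,

with components scaled to the configured variance shares in the founder
generation. SNPs are founded in linkage equilibrium (frequencies
Uniform(0.05, 0.5), or Balding-Nichols per deme under stratification) on a
uniform map; LD then arises only through mating structure and drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genio import PedigreeTable, PhasedGenotypeSet, PhenotypeVector, VariantInfo
from .ibd import IbdPath, _states_to_segments

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_meiosis",
    "mate_assortatively",
    "generate_phenotypes",
    "run_simulation",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated population.

    Variance shares refer to the founder generation; the residual share is
    1 minus the genetic shares. ``am_target_corr`` is the spousal phenotype
    correlation the matchmaker is calibrated to. ``fst`` is the
    Balding-Nichols divergence of deme allele frequencies.
    """

    n_families: int = 1000
    n_snps: int = 200
    n_chrom: int = 1
    chrom_length_cM: float = 100.0
    freq_range: tuple[float, float] = (0.05, 0.5)
    n_generations: int = 1
    h2_direct: float = 0.5
    share_parental_ige: float = 0.0
    cor_direct_parental: float = 0.5
    eta_s: float = 0.0
    v_vt: float = 0.0
    am_target_corr: float = 0.0
    n_demes: int = 1
    fst: float = 0.0
    deme_offset_sd: float = 0.0
    ascertain: bool = False
    ascertain_center: float = 0.5
    ascertain_slope: float = 0.0
    seed: int = 0

    def __post_init__(self):
        shares = (self.h2_direct + 2 * self.share_parental_ige
                  + self.eta_s ** 2)
        if shares > 1:
            raise ValueError("variance shares exceed 1")
        if self.am_target_corr >= 1:
            raise ValueError("target spousal correlation must be < 1")


@dataclass
class SimOutput:
    """Ground-truth container for one simulated set of nuclear families."""

    config: SimConfig
    gset: PhasedGenotypeSet          # parents + offspring of final families
    pedigree: PedigreeTable
    phenotypes: PhenotypeVector
    families: pd.DataFrame           # family_id, father, mother, offspring1/2
    true_delta: np.ndarray
    true_alpha: np.ndarray           # per-SNP parental IGE (alpha_p = alpha_m)
    true_eta: np.ndarray
    true_ibd: dict[tuple[str, str], IbdPath]
    realized_spousal_corr: float
    realized_r_am: float
    realized_fst: float


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def simulate_meiosis(parent_haps: np.ndarray, pos_cM: np.ndarray,
                     rng: np.random.Generator):
    """One gamete from a phased parent (L, 2): Poisson crossovers on the cM
    map, no interference. Returns (gamete alleles (L,), origin (L,) in
    {0,1}, crossover positions in cM)."""
    gam, orig, xos = _meiosis_batch(parent_haps[None], pos_cM, rng)
    return gam[0], orig[0], xos[0]


def _meiosis_batch(haps: np.ndarray, pos_cM: np.ndarray,
                   rng: np.random.Generator):
    """Vectorized meiosis for a batch of parents (n, L, 2)."""
    n, L, _ = haps.shape
    length = pos_cM[-1] - pos_cM[0]
    counts = rng.poisson(length / 100.0, size=n)
    start = rng.integers(0, 2, size=n)
    origins = np.empty((n, L), dtype=np.int8)
    xo_list = []
    for i in range(n):
        if counts[i] == 0:
            origins[i] = start[i]
            xo_list.append(np.empty(0))
            continue
        xo = np.sort(rng.uniform(pos_cM[0], pos_cM[-1], size=counts[i]))
        origins[i] = (start[i] + np.searchsorted(xo, pos_cM, side="right")) % 2
        xo_list.append(xo)
    gametes = np.take_along_axis(haps, origins[:, :, None], axis=2)[:, :, 0]
    return gametes, origins, xo_list


# ---------------------------------------------------------------------------
# Mating
# ---------------------------------------------------------------------------

def mate_assortatively(phenotypes: np.ndarray, target_corr: float,
                       rng: np.random.Generator, tol: float = 0.02,
                       max_iter: int = 40):
    """Pair individuals by noisy phenotype rank matching.

    Returns (index pairs (n/2, 2), realized spousal correlation). The noise
    scale is calibrated by bisection so the realized cross-spouse phenotype
    correlation lands within ``tol`` of ``target_corr`` (n permitting).
    """
    n = len(phenotypes)
    if n % 2:
        raise ValueError("need an even number of mating individuals")
    if target_corr >= 1:
        raise ValueError("target correlation must be < 1")
    half = rng.permutation(n)
    a, b = half[: n // 2], half[n // 2:]
    if target_corr <= 0:
        pairs = np.column_stack([a, b])
        realized = float(np.corrcoef(phenotypes[a], phenotypes[b])[0, 1])
        return pairs, realized

    sd = float(np.std(phenotypes)) or 1.0

    def pairing(noise_scale):
        za = phenotypes[a] + rng.normal(0, noise_scale * sd, len(a))
        zb = phenotypes[b] + rng.normal(0, noise_scale * sd, len(b))
        pa = a[np.argsort(za)]
        pb = b[np.argsort(zb)]
        r = float(np.corrcoef(phenotypes[pa], phenotypes[pb])[0, 1])
        return np.column_stack([pa, pb]), r

    lo, hi = 0.0, 8.0
    pairs, realized = pairing(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        pairs, realized = pairing(mid)
        if abs(realized - target_corr) <= tol:
            break
        if realized > target_corr:
            lo = mid
        else:
            hi = mid
    return pairs, realized


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def generate_phenotypes(g_child, g_father, g_mother, g_sib, y_parents,
                        deme_offset, delta, alpha, eta, v_vt, noise_sd,
                        rng: np.random.Generator):
    """Assemble offspring phenotypes from the model components.

    ``g_sib`` is the sibling's genotype matrix (sibling IGE acts through the
    same per-SNP weights as the sibling's own direct effect, scaled to the
    eta_s share); ``y_parents`` is (Y_father + Y_mother) for vertical
    transmission.
    """
    y = g_child @ delta
    if alpha is not None:
        y = y + (g_father + g_mother) @ alpha
    if eta is not None and g_sib is not None:
        y = y + g_sib @ eta
    if v_vt:
        y = y + v_vt * y_parents
    y = y + deme_offset
    return y + rng.normal(0.0, noise_sd, size=len(y))


def _scaled_effects(raw: np.ndarray, G: np.ndarray, share: float) -> np.ndarray:
    """Scale raw per-SNP weights so var(G @ effects) = share (founders)."""
    if share == 0:
        return np.zeros_like(raw)
    v = np.var(G @ raw)
    return raw * np.sqrt(share / v) if v > 0 else raw


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _founder_haplotypes(n, freqs, demes, fst, rng):
    L = len(freqs)
    if fst > 0:
        n_demes = demes.max() + 1
        a = freqs * (1 - fst) / fst
        b = (1 - freqs) * (1 - fst) / fst
        deme_freqs = rng.beta(a, b, size=(n_demes, L))
        f_ind = deme_freqs[demes]                       # (n, L)
    else:
        f_ind = np.broadcast_to(freqs, (n, L))
    haps = (rng.random((n, L, 2)) < f_ind[:, :, None]).astype(np.int8)
    return haps


def _variant_table(cfg: SimConfig, freqs: np.ndarray):
    per = np.array_split(np.arange(cfg.n_snps), cfg.n_chrom)
    variants, pos_cM_all = [], np.empty(cfg.n_snps)
    for c, idx in enumerate(per, start=1):
        pos = np.linspace(0.0, cfg.chrom_length_cM, len(idx))
        pos_cM_all[idx] = pos
        for k, j in enumerate(idx):
            variants.append(VariantInfo(
                snp_id=f"snp{j}", chrom=str(c),
                pos_bp=int(round(pos[k] * 1e6)) + 1,
                freq=float(freqs[j]), pos_cM=float(pos[k]), ld_score=1.0))
    return variants, per


def run_simulation(config: SimConfig) -> SimOutput:
    """Run the configured number of generations and emit the final families.

    Fully reproducible from ``config.seed``. The final generation is
    assembled into ``n_families`` nuclear families with exactly two
    offspring each; parents are included in the genotype set (their
    genotyped status is an analysis-time choice made via the pedigree).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    N = 2 * cfg.n_families
    freqs0 = rng.uniform(*cfg.freq_range, size=cfg.n_snps)
    variants, chrom_split = _variant_table(cfg, freqs0)
    demes = (rng.integers(0, cfg.n_demes, size=N) if cfg.n_demes > 1
             else np.zeros(N, dtype=int))
    # deme sizes must be even so within-deme mating keeps the population size
    odd = [d for d in range(cfg.n_demes) if np.sum(demes == d) % 2]
    for a, b in zip(odd[0::2], odd[1::2]):
        demes[np.flatnonzero(demes == a)[0]] = b
    deme_offsets = (rng.normal(0, cfg.deme_offset_sd, size=cfg.n_demes)
                    if cfg.n_demes > 1 else np.zeros(1))

    haps = _founder_haplotypes(N, freqs0, demes, cfg.fst, rng)
    G = haps.sum(axis=2).astype(np.float64)

    # per-SNP effect sizes, frozen across generations
    raw_d = rng.normal(size=cfg.n_snps)
    raw_a = (cfg.cor_direct_parental * raw_d
             + np.sqrt(max(1 - cfg.cor_direct_parental ** 2, 0))
             * rng.normal(size=cfg.n_snps))
    delta = _scaled_effects(raw_d, G, cfg.h2_direct)
    alpha = _scaled_effects(raw_a, G, cfg.share_parental_ige) \
        if cfg.share_parental_ige > 0 else None
    eta = _scaled_effects(raw_d, G, cfg.eta_s ** 2) if cfg.eta_s != 0 else None
    if eta is not None and cfg.eta_s < 0:
        eta = -eta
    noise_var = 1.0 - cfg.h2_direct - 2 * cfg.share_parental_ige \
        - (cfg.eta_s ** 2 if eta is not None else 0.0)
    noise_sd = np.sqrt(max(noise_var, 0.05))

    y = G @ delta + demes_offset(demes, deme_offsets) \
        + rng.normal(0, noise_sd, N)

    pos_cM = np.array([v.pos_cM for v in variants])
    spousal_corr = np.nan
    pat_origin = mat_origin = None
    fathers = mothers = None

    for gen in range(max(cfg.n_generations, 1)):
        pairs_list, realized = _mate_within_demes(y, demes, cfg, rng)
        spousal_corr = realized
        fa = pairs_list[:, 0]
        mo = pairs_list[:, 1]
        # two offspring per couple; meioses per chromosome to respect maps
        child_haps = np.empty((N, cfg.n_snps, 2), dtype=np.int8)
        pat_origin = np.empty((N, cfg.n_snps), dtype=np.int8)
        mat_origin = np.empty((N, cfg.n_snps), dtype=np.int8)
        fa2 = np.repeat(fa, 2)
        mo2 = np.repeat(mo, 2)
        for idx in chrom_split:
            pc = pos_cM[idx]
            gp, op, _ = _meiosis_batch(haps[fa2][:, idx], pc, rng)
            gm, om, _ = _meiosis_batch(haps[mo2][:, idx], pc, rng)
            child_haps[:, idx, 0] = gp
            child_haps[:, idx, 1] = gm
            pat_origin[:, idx] = op
            mat_origin[:, idx] = om
        Gc = child_haps.sum(axis=2).astype(np.float64)
        sib = np.arange(N) ^ 1        # the other child of the same couple
        child_demes = demes[fa2]
        y_child = generate_phenotypes(
            Gc, G[fa2], G[mo2], Gc[sib] if eta is not None else None,
            y[fa2] + y[mo2], demes_offset(child_demes, deme_offsets),
            delta, alpha, eta, cfg.v_vt, noise_sd, rng)
        parent_haps, parent_G, parent_y = haps, G, y
        fathers, mothers = fa2, mo2
        haps, G, y, demes = child_haps, Gc, y_child, child_demes

    # ---- assemble final families -----------------------------------------
    n_fam = cfg.n_families
    fam_rows = []
    keep = np.ones(n_fam, dtype=bool)
    if cfg.ascertain and cfg.ascertain_slope != 0:
        pct = pd.Series(y[0::2]).rank(pct=True).to_numpy()
        p_keep = 1.0 / (1.0 + np.exp(-cfg.ascertain_slope
                                     * (pct - cfg.ascertain_center)))
        keep = rng.random(n_fam) < p_keep

    parent_ids = {}
    ind_ids, ind_haps, pheno = [], [], {}
    ped_rows = []
    true_ibd: dict[tuple[str, str], IbdPath] = {}
    for k in range(n_fam):
        if not keep[k]:
            continue
        c1, c2 = 2 * k, 2 * k + 1
        fid_idx, mid_idx = fathers[c1], mothers[c1]
        fid = parent_ids.setdefault(("F", fid_idx), f"father_{k}")
        mid = parent_ids.setdefault(("M", mid_idx), f"mother_{k}")
        o1, o2 = f"off_{k}_1", f"off_{k}_2"
        for iid, hp in ((fid, parent_haps[fid_idx]), (mid, parent_haps[mid_idx]),
                        (o1, haps[c1]), (o2, haps[c2])):
            ind_ids.append(iid)
            ind_haps.append(hp)
        pheno[fid] = float(parent_y[fid_idx])
        pheno[mid] = float(parent_y[mid_idx])
        pheno[o1] = float(y[c1])
        pheno[o2] = float(y[c2])
        ped_rows += [
            (fid, "", "", 1), (mid, "", "", 2),
            (o1, fid, mid, 0), (o2, fid, mid, 0),
        ]
        fam_rows.append((f"F{k}", fid, mid, o1, o2))
        states_all = ((pat_origin[c1] == pat_origin[c2]).astype(np.int8)
                      + (mat_origin[c1] == mat_origin[c2]).astype(np.int8))
        for c, idx in enumerate(chrom_split, start=1):
            st = states_all[idx]
            pos_bp = np.array([variants[j].pos_bp for j in idx])
            path = IbdPath((o1, o2), str(c), st,
                           _states_to_segments(st, pos_bp),
                           None, pos_bp, pos_cM[idx])
            key = (o1, o2) if cfg.n_chrom == 1 else (o1, o2, str(c))
            true_ibd[key] = path

    # parental-generation frequencies are what the imputation should use
    parent_rows = [i for i, iid in enumerate(ind_ids)
                   if not iid.startswith("off")]
    hap_arr = np.stack(ind_haps)
    f_par = hap_arr[parent_rows].mean(axis=(0, 2))
    for v, fv in zip(variants, f_par):
        v.freq = float(np.clip(fv, 1e-6, 1 - 1e-6))

    gset = PhasedGenotypeSet(ind_ids, variants, hap_arr)
    ped = PedigreeTable(pd.DataFrame(ped_rows, columns=[
        "individual_id", "father_id", "mother_id", "sex"]).drop_duplicates(
        "individual_id").reset_index(drop=True))
    fam_df = pd.DataFrame(fam_rows, columns=["family_id", "father", "mother",
                                             "offspring1", "offspring2"])

    gv_f = parent_G[fathers[0::2]] @ delta
    gv_m = parent_G[mothers[0::2]] @ delta
    r_am = float(np.corrcoef(gv_f, gv_m)[0, 1]) if len(gv_f) > 2 else np.nan

    if cfg.n_demes > 1:
        dm = demes
        fst_num, fst_den = [], []
        for d in range(cfg.n_demes):
            sel = dm == d
            if sel.sum() == 0:
                continue
            fst_num.append(G[sel].mean(axis=0) / 2)
        fd = np.array(fst_num)
        fbar = fd.mean(axis=0)
        with np.errstate(invalid="ignore"):
            fst_real = float(np.nanmean(fd.var(axis=0) / (fbar * (1 - fbar))))
    else:
        fst_real = 0.0

    return SimOutput(
        config=cfg, gset=gset, pedigree=ped,
        phenotypes=PhenotypeVector(pheno, provenance="simulated"),
        families=fam_df,
        true_delta=delta,
        true_alpha=alpha if alpha is not None else np.zeros(cfg.n_snps),
        true_eta=eta if eta is not None else np.zeros(cfg.n_snps),
        true_ibd=true_ibd,
        realized_spousal_corr=spousal_corr,
        realized_r_am=r_am,
        realized_fst=fst_real,
    )


def demes_offset(demes, offsets):
    return offsets[demes] if len(offsets) > 1 else np.zeros(len(demes))


def _mate_within_demes(y, demes, cfg: SimConfig, rng):
    pairs_all = []
    rs = []
    for d in np.unique(demes):
        idx = np.flatnonzero(demes == d)
        if len(idx) % 2:
            idx = idx[:-1]
        pairs, r = mate_assortatively(y[idx], cfg.am_target_corr, rng)
        pairs_all.append(idx[pairs])
        rs.append(r)
    return np.vstack(pairs_all), float(np.mean(rs))
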