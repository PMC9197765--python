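"""Readers and writers for the on-disk formats the toolkit touches.

All downstream modules consume only the in-memory containers defined here:
phased genotypes, pedigrees, phenotypes, genetic maps and summary statistics.
Conventions:

* Biallelic SNPs with alleles coded ``0`` and ``1``; genotypes are counts of
  allele "1", whose population frequency is ``f``.
* bp positions are 1-based (VCF convention); IBD segment files use half-open
  ``[start_bp, end_bp)`` intervals.
* Missingness is explicit (allele value ``-1`` in haplotype arrays), never
  silently encoded as a reference call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "VariantInfo",
    "PhasedGenotypeSet",
    "PedigreeTable",
    "PhenotypeVector",
    "SummaryStatRow",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "GeneticMap",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "read_ld_scores",
    "read_pgi_weights",
    "write_sumstats",
    "read_sumstats",
    "write_ibd_segments",
    "read_ibd_segments",
]


@dataclass
class VariantInfo:
    """Metadata for one biallelic SNP.

    ``freq`` is the frequency of allele "1" (the counted allele) and
    ``ld_score`` the LD score used for the IBD HMM's likelihood weighting
    (``None`` when unavailable).
    """

    snp_id: str
    chrom: str
    pos_bp: int
    allele0: str = "A"
    allele1: str = "G"
    freq: float = np.nan
    pos_cM: float = np.nan
    ld_score: float | None = None


class PhasedGenotypeSet:
    """Phased genotypes for a set of individuals at a set of SNPs.

    haplotypes : int8 array (n_individuals, n_snps, 2); -1 marks a missing
        allele. For phased entries the two positions are the two phased
        haplotypes in file order; for unphased entries the order is arbitrary.
    phased : bool array (n_individuals, n_snps).
    """

    def __init__(self, individual_ids, variants, haplotypes, phased=None):
        self.individual_ids = list(individual_ids)
        self.variants = list(variants)
        self.haplotypes = np.asarray(haplotypes, dtype=np.int8)
        n, m = len(self.individual_ids), len(self.variants)
        if self.haplotypes.shape != (n, m, 2):
            raise ValueError(
                f"haplotype array shape {self.haplotypes.shape} != ({n}, {m}, 2)"
            )
        if phased is None:
            phased = np.ones((n, m), dtype=bool)
        self.phased = np.asarray(phased, dtype=bool)
        self._index = {iid: k for k, iid in enumerate(self.individual_ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def genotypes(self) -> np.ndarray:
        """Genotype matrix (n_individuals, n_snps); -1 where any allele missing.

        Cached; invalidate with ``_geno_cache = None`` after editing
        haplotypes in place.
        """
        cached = getattr(self, "_geno_cache", None)
        if cached is None:
            h = self.haplotypes
            g = h.sum(axis=2).astype(np.int8)
            g[(h == MISSING).any(axis=2)] = MISSING
            self._geno_cache = cached = g
        return cached

    def freqs(self) -> np.ndarray:
        return np.array([v.freq for v in self.variants])

    def positions_cM(self) -> np.ndarray:
        return np.array([v.pos_cM for v in self.variants])

    def subset_individuals(self, ids) -> "PhasedGenotypeSet":
        idx = [self._index[i] for i in ids]
        return PhasedGenotypeSet(
            [self.individual_ids[k] for k in idx],
            self.variants,
            self.haplotypes[idx],
            self.phased[idx],
        )


@dataclass
class PedigreeTable:
    """FAM-like pedigree: one row per individual.

    Columns: individual_id, father_id, mother_id (empty string if unknown),
    sex (0 unknown / 1 male / 2 female), genotyped, phenotyped.
    """

    table: pd.DataFrame

    REQUIRED = ("individual_id", "father_id", "mother_id")

    def __post_init__(self):
        for c in self.REQUIRED:
            if c not in self.table.columns:
                raise ValueError(f"pedigree missing column {c!r}")
        t = self.table
        if "sex" not in t.columns:
            t["sex"] = 0
        if "genotyped" not in t.columns:
            t["genotyped"] = True
        if "phenotyped" not in t.columns:
            t["phenotyped"] = True
        if t["individual_id"].duplicated().any():
            raise ValueError("duplicate individual_id in pedigree")
        self._check_acyclic()

    def _check_acyclic(self):
        parents = {
            r.individual_id: {p for p in (r.father_id, r.mother_id) if p}
            for r in self.table.itertuples()
        }
        seen_ok: set[str] = set()
        for start in parents:
            path: set[str] = set()
            stack = [start]
            while stack:
                node = stack.pop()
                if node in seen_ok or node not in parents:
                    continue
                if node in path:
                    raise ValueError(f"pedigree cycle involving {node!r}")
                path.add(node)
                stack.extend(parents[node])
            seen_ok |= path

    def founder_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[(t.father_id == "") & (t.mother_id == ""), "individual_id"])

    def __len__(self):
        return len(self.table)


@dataclass
class PhenotypeVector:
    """Per-individual phenotype values (finite reals) with free-text provenance."""

    values: dict[str, float]
    provenance: str = ""

    def __post_init__(self):
        bad = [i for i, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite phenotype for {bad[:5]}")

    def __getitem__(self, individual_id: str) -> float:
        return self.values[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.values

    def __len__(self):
        return len(self.values)


PARAM_ORDER = ("direct", "eta_s", "alpha_p", "alpha_m", "alpha")


@dataclass
class SummaryStatRow:
    """Per-SNP effect estimates with full sampling covariance.

    ``labels`` is a subset of ("direct", "eta_s", "alpha_p", "alpha_m",
    "alpha"); ``beta_pop`` is the derived population effect
    beta = delta + (alpha_p + alpha_m)/2 (or delta + alpha when the combined
    NTC was fitted).
    """

    variant: VariantInfo
    labels: tuple[str, ...]
    estimates: np.ndarray
    covariance: np.ndarray
    beta_pop: float = np.nan
    var_beta_pop: float = np.nan
    n_eff: float = np.nan

    def __post_init__(self):
        self.estimates = np.atleast_1d(np.asarray(self.estimates, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        k = len(self.labels)
        if self.estimates.shape != (k,) or self.covariance.shape != (k, k):
            raise ValueError("estimate/covariance shape mismatch with labels")

    def get(self, label: str) -> float:
        return float(self.estimates[self.labels.index(label)])

    def se(self, label: str) -> float:
        i = self.labels.index(label)
        return float(np.sqrt(self.covariance[i, i]))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path, maf_min: float = 0.0, pedigree: PedigreeTable | None = None):
    """Read a VCF with phased GT entries into a :class:`PhasedGenotypeSet`.

    Variants with MAF < ``maf_min`` are dropped, as are multi-allelic sites
    and all-missing sites (with warnings). Allele frequency is computed from
    pedigree founders when a pedigree is supplied (avoiding double-counting
    of transmitted alleles), otherwise from all individuals.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    hap_cols: list[np.ndarray] = []
    phased_cols: list[np.ndarray] = []
    variants: list[VariantInfo] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic variant {rec.ID or rec.POS} at "
                f"{rec.CHROM}:{rec.POS}"
            )
            continue
        gts = rec.genotypes  # list of [a0, a1, phased]
        arr = np.full((len(samples), 2), MISSING, dtype=np.int8)
        phs = np.zeros(len(samples), dtype=bool)
        for i, gt in enumerate(gts):
            if len(gt) < 3:
                raise ValueError(
                    f"malformed GT for sample {samples[i]} at record "
                    f"{rec.CHROM}:{rec.POS}"
                )
            a0, a1 = gt[0], gt[1]
            arr[i, 0] = a0 if a0 >= 0 else MISSING
            arr[i, 1] = a1 if a1 >= 0 else MISSING
            phs[i] = bool(gt[2])
        if (arr == MISSING).all():
            warnings.warn(f"all-missing variant at {rec.CHROM}:{rec.POS}; dropped")
            continue
        variants.append(
            VariantInfo(
                snp_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=str(rec.CHROM),
                pos_bp=int(rec.POS),
                allele0=rec.REF,
                allele1=rec.ALT[0],
            )
        )
        hap_cols.append(arr)
        phased_cols.append(phs)
    if not variants:
        raise ValueError(f"no usable variants in {path}")
    haps = np.stack(hap_cols, axis=1)  # (n, m, 2)
    phased = np.stack(phased_cols, axis=1)
    gset = PhasedGenotypeSet(samples, variants, haps, phased)
    _assign_freqs(gset, pedigree)
    if maf_min > 0:
        f = gset.freqs()
        maf = np.minimum(f, 1 - f)
        keep = np.isfinite(f) & (maf >= maf_min)
        gset = PhasedGenotypeSet(
            gset.individual_ids,
            [v for v, k in zip(gset.variants, keep) if k],
            gset.haplotypes[:, keep],
            gset.phased[:, keep],
        )
    return gset


def _assign_freqs(gset: PhasedGenotypeSet, pedigree: PedigreeTable | None):
    if pedigree is not None:
        founders = [i for i in pedigree.founder_ids() if i in gset]
        rows = [gset.index_of(i) for i in founders] if founders else None
    else:
        rows = None
    h = gset.haplotypes if rows is None else gset.haplotypes[rows]
    obs = h != MISSING
    with np.errstate(invalid="ignore"):
        f = np.where(obs, h, 0).sum(axis=(0, 2)) / obs.sum(axis=(0, 2))
    for v, fv in zip(gset.variants, f):
        v.freq = float(fv)


def write_phased_vcf(gset: PhasedGenotypeSet, path):
    """Write a minimal VCF 4.2 with phased GT entries (round-trips with
    :func:`read_phased_vcf`)."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in gset.variants):
            out.write(f"##contig=<ID={chrom}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gset.individual_ids)
            + "\n"
        )
        for j, v in enumerate(gset.variants):
            cols = [v.chrom, str(v.pos_bp), v.snp_id, v.allele0, v.allele1,
                    ".", "PASS", ".", "GT"]
            for i in range(gset.n_individuals):
                a0, a1 = gset.haplotypes[i, j]
                sep = "|" if gset.phased[i, j] else "/"
                s0 = "." if a0 == MISSING else str(int(a0))
                s1 = "." if a1 == MISSING else str(int(a1))
                cols.append(s0 + sep + s1)
            out.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Per-chromosome piecewise-linear map bp -> cM.

    Queries between map points are linearly interpolated; queries beyond the
    ends are clamped to the terminal cM values.
    """

    def __init__(self, points: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.points = points
        for chrom, (bp, cm) in points.items():
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"decreasing cM within chromosome {chrom}")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"non-increasing bp within chromosome {chrom}")

    def interpolate(self, chrom: str, pos_bp) -> np.ndarray:
        bp, cm = self.points[str(chrom)]
        return np.interp(np.asarray(pos_bp, dtype=float), bp, cm)

    def annotate(self, gset: PhasedGenotypeSet):
        for v in gset.variants:
            v.pos_cM = float(self.interpolate(v.chrom, v.pos_bp))


def read_genetic_map(path) -> GeneticMap:
    """Read a whitespace-delimited (chrom, pos_bp, pos_cM) genetic map."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["chrom", "pos_bp", "pos_cM"], dtype={0: str})
    # tolerate a header line
    if not str(df.iloc[0, 1]).lstrip("-").replace(".", "").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    df["pos_bp"] = df["pos_bp"].astype(float).astype(int)
    df["pos_cM"] = df["pos_cM"].astype(float)
    points = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_bp")
        points[str(chrom)] = (
            sub["pos_bp"].to_numpy(dtype=float),
            sub["pos_cM"].to_numpy(dtype=float),
        )
    return GeneticMap(points)


# ---------------------------------------------------------------------------
# Pedigree / phenotypes / LD scores / PGI weights
# ---------------------------------------------------------------------------

def read_pedigree(path) -> PedigreeTable:
    """Read a FAM-like file: FID IID father mother sex phenotype."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                     names=["fid", "individual_id", "father_id", "mother_id",
                            "sex", "phenotype"])
    df["father_id"] = df["father_id"].replace("0", "").fillna("")
    df["mother_id"] = df["mother_id"].replace("0", "").fillna("")
    df["sex"] = pd.to_numeric(df["sex"], errors="coerce").fillna(0).astype(int)
    return PedigreeTable(
        df[["individual_id", "father_id", "mother_id", "sex"]].copy()
    )


def write_pedigree(ped: PedigreeTable, path):
    t = ped.table
    out = pd.DataFrame({
        "fid": t.get("family_id", pd.Series(["0"] * len(t))).fillna("0"),
        "iid": t["individual_id"],
        "father": t["father_id"].replace("", "0"),
        "mother": t["mother_id"].replace("", "0"),
        "sex": t["sex"],
        "pheno": -9,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_phenotypes(path) -> PhenotypeVector:
    """Read a 2+ column TSV (individual_id, value); extra columns ignored."""
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    if df.columns[0].lower() not in ("iid", "individual_id", "id"):
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype={0: str})
    ids = df.iloc[:, 0].astype(str)
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    ok = vals.notna()
    return PhenotypeVector(dict(zip(ids[ok], vals[ok].astype(float))),
                           provenance=f"read from {path}")


def read_ld_scores(path) -> dict[str, float]:
    """Read a tab-delimited (snp_id, ld_score) file."""
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("LD-score file needs at least 2 columns")
    return dict(zip(df.iloc[:, 0].astype(str),
                    pd.to_numeric(df.iloc[:, 1]).astype(float)))


def read_pgi_weights(path) -> pd.DataFrame:
    """Read a PGI weight file with columns (snp_id, effect_allele, weight)."""
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str, 1: str})
    df.columns = ["snp_id", "effect_allele", "weight"] + list(df.columns[3:])
    df["weight"] = pd.to_numeric(df["weight"])
    if df["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in weight file")
    return df[["snp_id", "effect_allele", "weight"]]


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _vech(m: np.ndarray) -> list[float]:
    k = m.shape[0]
    return [float(m[i, j]) for i in range(k) for j in range(i + 1)]


def write_sumstats(rows: list[SummaryStatRow], path):
    """Write summary statistics as a tab-delimited file.

    Per-parameter estimate/SE columns are emitted for every label in
    ``PARAM_ORDER``; parameters a row did not fit are written as NA. The
    lower triangle of the sampling covariance is vectorized into the
    ``cov_vech`` column (semicolon-separated, row-major, labels in row order).
    """
    recs = []
    for r in rows:
        rec = {
            "chrom": r.variant.chrom,
            "snp_id": r.variant.snp_id,
            "pos_bp": r.variant.pos_bp,
            "allele0": r.variant.allele0,
            "allele1": r.variant.allele1,
            "freq": r.variant.freq,
        }
        for p in PARAM_ORDER:
            if p in r.labels:
                rec[f"{p}_est"] = r.get(p)
                rec[f"{p}_se"] = r.se(p)
            else:
                rec[f"{p}_est"] = np.nan
                rec[f"{p}_se"] = np.nan
        rec["labels"] = ",".join(r.labels)
        rec["cov_vech"] = ";".join(f"{v:.6g}" for v in _vech(r.covariance))
        rec["beta_pop"] = r.beta_pop
        rec["se_beta_pop"] = (
            np.sqrt(r.var_beta_pop) if np.isfinite(r.var_beta_pop) else np.nan
        )
        rec["n_eff"] = r.n_eff
        recs.append(rec)
    cols = (["chrom", "snp_id", "pos_bp", "allele0", "allele1", "freq"]
            + [f"{p}_{s}" for p in PARAM_ORDER for s in ("est", "se")]
            + ["labels", "cov_vech", "beta_pop", "se_beta_pop", "n_eff"])
    df = pd.DataFrame(recs, columns=cols)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_sumstats(path) -> list[SummaryStatRow]:
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})
    rows = []
    for rec in df.itertuples():
        labels = tuple(rec.labels.split(","))
        est = np.array([getattr(rec, f"{p}_est") for p in labels])
        k = len(labels)
        cov = np.zeros((k, k))
        vals = [float(x) for x in str(rec.cov_vech).split(";")]
        it = iter(vals)
        for i in range(k):
            for j in range(i + 1):
                cov[i, j] = cov[j, i] = next(it)
        var_beta = (
            float(rec.se_beta_pop) ** 2 if np.isfinite(rec.se_beta_pop) else np.nan
        )
        rows.append(SummaryStatRow(
            VariantInfo(str(rec.snp_id), str(rec.chrom), int(rec.pos_bp),
                        str(rec.allele0), str(rec.allele1), float(rec.freq)),
            labels, est, cov,
            beta_pop=float(rec.beta_pop), var_beta_pop=var_beta,
            n_eff=float(rec.n_eff),
        ))
    return rows


# ---------------------------------------------------------------------------
# IBD segments (BED-like)
# ---------------------------------------------------------------------------

def write_ibd_segments(paths, out_path):
    """Write IBD segments as a BED-like file.

    Columns: sib1, sib2, chrom, start_bp, end_bp, state; intervals are
    half-open [start_bp, end_bp) as stated in the header.
    """
    with open(out_path, "w") as out:
        out.write("# IBD segments; intervals are half-open [start_bp, end_bp)\n")
        out.write("sib1\tsib2\tchrom\tstart_bp\tend_bp\tstate\n")
        for p in paths:
            s1, s2 = p.sib_pair
            for start, end, state in p.segments:
                out.write(f"{s1}\t{s2}\t{p.chrom}\t{start}\t{end}\t{state}\n")


def read_ibd_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"sib1": str, "sib2": str, "chrom": str})
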