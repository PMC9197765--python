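"""Genome-wide correlations between effect classes, corrected for sampling
error.

Per-SNP effect estimates are noisy; the naive Pearson correlation between,
say, direct-effect and population-effect estimates is attenuated by the
sampling variance and distorted by the sampling covariance (the two
estimates usually come from the same individuals). The moment-based
estimator subtracts the known per-SNP sampling moments:

    cov_hat   = cov(a_hat, b_hat) - mean(sampling cov(a_hat, b_hat))
    var_hat_a = var(a_hat) - mean(sampling var a_hat)       (likewise b)
    r_hat     = cov_hat / sqrt(var_hat_a * var_hat_b)

Standard errors come from a delete-one block jackknife over contiguous
genomic blocks (local LD makes neighboring SNPs dependent, so SNP-level
resampling would understate the error). For estimates from two disjoint
samples the sampling covariance is identically zero
(:func:`cross_sample_correlation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrelationEstimate",
    "moment_correlation",
    "cross_sample_correlation",
    "assign_blocks",
    "effect_correlation_from_sumstats",
]


@dataclass
class CorrelationEstimate:
    r_hat: float
    se: float
    n_snps: int
    n_blocks: int
    label_a: str = "a"
    label_b: str = "b"
    cross_sample: bool = False

    def __post_init__(self):
        if abs(self.r_hat) > 1:
            warnings.warn(
                f"corrected correlation {self.r_hat:.3f} outside [-1, 1]; "
                "reported as-is (noisy input)")


def assign_blocks(n_snps: int, n_blocks: int = 100,
                  chrom: np.ndarray | None = None) -> np.ndarray:
    """Contiguous equal-SNP block labels, never splitting a chromosome
    boundary across a block when ``chrom`` is given."""
    if chrom is None:
        return np.minimum((np.arange(n_snps) * n_blocks) // n_snps,
                          n_blocks - 1)
    blocks = np.empty(n_snps, dtype=int)
    offset = 0
    chrom = np.asarray(chrom)
    uniq = list(dict.fromkeys(chrom.tolist()))
    per = max(n_blocks // max(len(uniq), 1), 1)
    for c in uniq:
        sel = np.flatnonzero(chrom == c)
        blocks[sel] = offset + np.minimum(
            (np.arange(len(sel)) * per) // len(sel), per - 1)
        offset += per
    return blocks


def _corrected_moments(a, b, var_a, var_b, cov_ab):
    n = len(a)
    ca = a - a.mean()
    cb = b - b.mean()
    cov = float(ca @ cb) / n - cov_ab.mean()
    va = float(ca @ ca) / n - var_a.mean()
    vb = float(cb @ cb) / n - var_b.mean()
    return cov, va, vb


def moment_correlation(effects_a, effects_b, var_a, var_b, cov_ab=None,
                       blocks=None, n_blocks: int = 100,
                       labels=("a", "b")) -> CorrelationEstimate:
    """Noise-corrected correlation between two aligned effect vectors.

    ``var_a``/``var_b`` are per-SNP sampling variances and ``cov_ab`` the
    per-SNP sampling covariance between the two estimates (zero allowed,
    e.g. disjoint samples). ``blocks`` assigns SNPs to jackknife blocks
    (default: ``n_blocks`` contiguous equal-SNP blocks).
    """
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    var_a = np.broadcast_to(np.asarray(var_a, dtype=float), a.shape)
    var_b = np.broadcast_to(np.asarray(var_b, dtype=float), a.shape)
    if cov_ab is None:
        cov_ab = np.zeros_like(a)
    cov_ab = np.broadcast_to(np.asarray(cov_ab, dtype=float), a.shape)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(var_a) \
        & np.isfinite(var_b) & np.isfinite(cov_ab)
    a, b, var_a, var_b, cov_ab = (x[ok] for x in (a, b, var_a, var_b, cov_ab))
    n = len(a)
    if n == 0:
        raise ValueError("no SNPs after alignment/filtering")
    if blocks is None:
        blocks = assign_blocks(n, n_blocks)
    else:
        blocks = np.asarray(blocks)[ok]

    cov, va, vb = _corrected_moments(a, b, var_a, var_b, cov_ab)
    if va <= 0 or vb <= 0:
        raise ValueError(
            f"corrected variance non-positive (var_a={va:.3g}, var_b={vb:.3g}); "
            "input too noisy for moment correction")
    r_hat = cov / np.sqrt(va * vb)

    uniq = np.unique(blocks)
    loo = []
    for blk in uniq:
        keep = blocks != blk
        c, x, yv = _corrected_moments(a[keep], b[keep], var_a[keep],
                                      var_b[keep], cov_ab[keep])
        if x <= 0 or yv <= 0:
            continue
        loo.append(c / np.sqrt(x * yv))
    loo = np.array(loo)
    g = len(loo)
    se = float(np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2))) \
        if g >= 2 else np.nan
    return CorrelationEstimate(float(r_hat), se, n, g, *labels)


def cross_sample_correlation(effects_a, effects_b, var_a, var_b,
                             blocks=None, n_blocks: int = 100,
                             labels=("a", "b")) -> CorrelationEstimate:
    """Moment correlation for estimates from two disjoint samples: the
    sampling covariance is fixed at zero."""
    est = moment_correlation(effects_a, effects_b, var_a, var_b,
                             cov_ab=np.zeros(len(np.asarray(effects_a))),
                             blocks=blocks, n_blocks=n_blocks, labels=labels)
    est.cross_sample = True
    return est


_COL = {"direct": "direct", "population": "beta_pop", "alpha": "alpha"}


def effect_correlation_from_sumstats(rows, col_a: str = "direct",
                                     col_b: str = "population",
                                     n_blocks: int = 100) -> CorrelationEstimate:
    """r(effect_a, effect_b) from a list of :class:`SummaryStatRow`.

    ``col_a``/``col_b`` name effect classes: a fitted parameter label
    ("direct", "alpha", ...) or "population" for the derived beta. The
    sampling covariance between the two is taken from each row's stored
    covariance (delta-method for beta)."""

    def extract(r, col):
        if col == "population":
            return r.beta_pop, r.var_beta_pop
        return r.get(col), r.se(col) ** 2

    def sampling_cov(r):
        k = len(r.labels)

        def grad(col):
            c = np.zeros(k)
            if col == "population":
                c[r.labels.index("direct")] = 1.0
                if "alpha" in r.labels:
                    c[r.labels.index("alpha")] = 1.0
                else:
                    c[r.labels.index("alpha_p")] = 0.5
                    c[r.labels.index("alpha_m")] = 0.5
            else:
                c[r.labels.index(col)] = 1.0
            return c

        return float(grad(col_a) @ r.covariance @ grad(col_b))

    a, b, va, vb, cab, chrom = [], [], [], [], [], []
    for r in rows:
        ea, v1 = extract(r, col_a)
        eb, v2 = extract(r, col_b)
        a.append(ea)
        b.append(eb)
        va.append(v1)
        vb.append(v2)
        cab.append(sampling_cov(r))
        chrom.append(r.variant.chrom)
    blocks = assign_blocks(len(a), n_blocks, np.array(chrom))
    return moment_correlation(np.array(a), np.array(b), np.array(va),
                              np.array(vb), np.array(cab), blocks=blocks,
                              labels=(col_a, col_b))
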