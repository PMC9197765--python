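"""Sibling IBD inference along chromosomes with a hidden Markov model.

At each SNP a sibling pair is in IBD state 0, 1 or 2 — the number of alleles
the two siblings inherited from the same parental haplotype. The HMM models
the pair's unphased genotypes conditional on the IBD state, with:

* an emission model derived by exact enumeration over parental transmissions
  under Hardy–Weinberg at the SNP's allele-1 frequency ``f``, plus a
  genotyping-error channel in which each individual's genotype is replaced,
  independently with probability ``gamma``, by a fresh Hardy–Weinberg draw;
* transitions from the genetic map: the IBD state is the sum of a paternal
  and a maternal sharing indicator; each indicator flips between adjacent
  SNPs with probability 2*theta*(1-theta) where theta = (1 - exp(-2d/100))/2
  is the Haldane recombination fraction for map distance d cM (two
  independent meioses per parent). The stationary law is (1/4, 1/2, 1/4);
* per-SNP log-likelihoods down-weighted by the inverse LD score, a
  pseudo-likelihood correction for local LD (the HMM otherwise assumes
  linkage equilibrium between SNPs given the IBD path).

The Viterbi path is authoritative for downstream imputation; forward-backward
posteriors are reported for QC. Inferred segments are smoothed by removing
runs shorter than ``min_segment_cM`` whose two flanking segments agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genio import MISSING, VariantInfo

__all__ = [
    "IbdParams",
    "IbdPath",
    "emission_logprob",
    "transition_matrix",
    "infer_ibd",
    "smooth_segments",
    "ibd_summary",
    "compute_ld_scores",
]

_STATE_PREF = np.array([1, 0, 2])  # tie-break: stationary-probability order


@dataclass
class IbdParams:
    """HMM tuning parameters: genotyping-error rate and minimum segment length."""

    gamma: float = 1e-4
    min_segment_cM: float = 0.01

    def __post_init__(self):
        if not (0 <= self.gamma < 0.5):
            raise ValueError("gamma must be in [0, 0.5)")
        if self.min_segment_cM < 0:
            raise ValueError("min_segment_cM must be >= 0")


@dataclass
class IbdPath:
    """Per-SNP IBD states and segments for one sibling pair on one chromosome."""

    sib_pair: tuple[str, str]
    chrom: str
    states: np.ndarray                       # (L,) in {0,1,2}
    segments: list[tuple[int, int, int]]     # (start_bp, end_bp, state), half-open
    posteriors: np.ndarray | None = None     # (L, 3)
    pos_bp: np.ndarray | None = None
    pos_cM: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------

def _hwe(f):
    f = np.asarray(f, dtype=float)
    q = 1.0 - f
    return np.stack([q * q, 2 * f * q, f * f], axis=-1)  # (..., 3)


def _base_tables(f):
    """Error-free P(g1, g2 | IBD state) as an array (..., 3 states, 3, 3)."""
    f = np.asarray(f, dtype=float)
    hwe = _hwe(f)                                   # (..., 3)
    q = 1.0 - f
    # IBD0: independent HWE draws
    p0 = hwe[..., :, None] * hwe[..., None, :]
    # IBD2: identical genotypes
    p2 = np.zeros(p0.shape)
    for g in range(3):
        p2[..., g, g] = hwe[..., g]
    # IBD1: shared allele s ~ Bern(f); each sib adds one free Bern(f) allele
    p1 = np.zeros(p0.shape)
    for s, ps in ((0, q), (1, f)):
        for b1, pb1 in ((0, q), (1, f)):
            for b2, pb2 in ((0, q), (1, f)):
                p1[..., s + b1, s + b2] += ps * pb1 * pb2
    return np.stack([p0, p1, p2], axis=-3)          # (..., 3, 3, 3)


def _emission_tables(f, gamma: float):
    """P(observed g1, g2 | IBD state) under the HWE-replacement error model."""
    base = _base_tables(f)                          # (..., k, g1, g2)
    if gamma == 0:
        return base
    hwe = _hwe(f)                                   # (..., 3)
    eye = np.eye(3)
    # error channel e[g_true, g_obs] per SNP
    chan = (1 - gamma) * eye + gamma * hwe[..., None, :]
    out = np.einsum("...kab,...ax,...by->...kxy", base, chan, chan)
    return out


def emission_logprob(g1, g2, f: float, gamma: float) -> np.ndarray:
    """Log P(g1, g2 | IBD state) for the three states at one SNP.

    A missing genotype (``MISSING``) is marginalized out.
    """
    tab = _emission_tables(np.array(f), gamma)      # (3, 3, 3)
    if g1 == MISSING and g2 == MISSING:
        p = tab.sum(axis=(1, 2))
    elif g1 == MISSING:
        p = tab[:, :, g2].sum(axis=1)
    elif g2 == MISSING:
        p = tab[:, g1, :].sum(axis=1)
    else:
        p = tab[:, g1, g2]
    with np.errstate(divide="ignore"):
        return np.log(p)


def _emission_logprob_array(g1, g2, freqs, gamma: float) -> np.ndarray:
    """Vectorized per-SNP emission log-likelihoods, shape (L, 3)."""
    tab = _emission_tables(freqs, gamma)            # (L, 3, 3, 3)
    L = len(freqs)
    out = np.empty((L, 3))
    m1 = g1 == MISSING
    m2 = g2 == MISSING
    both = m1 & m2
    only1 = m1 & ~m2
    only2 = m2 & ~m1
    full = ~m1 & ~m2
    idx = np.arange(L)
    if full.any():
        out[full] = tab[idx[full], :, g1[full], g2[full]]
    if only1.any():
        out[only1] = tab[idx[only1], :, :, g2[only1]].sum(axis=2)
    if only2.any():
        out[only2] = tab[idx[only2], :, g1[only2], :].sum(axis=2)
    if both.any():
        out[both] = tab[both].sum(axis=(2, 3))
    with np.errstate(divide="ignore"):
        return np.log(out)


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------

def transition_matrix(d_cM: float) -> np.ndarray:
    """3x3 IBD-state transition matrix over map distance ``d_cM``."""
    if d_cM < 0:
        raise ValueError("distance must be >= 0")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))
    phi = 2.0 * theta * (1.0 - theta)  # flip probability of one sharing indicator
    s, c = phi, 1.0 - phi
    return np.array([
        [c * c, 2 * s * c, s * s],
        [s * c, c * c + s * s, s * c],
        [s * s, 2 * s * c, c * c],
    ])


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _viterbi(log_emit: np.ndarray, log_trans: np.ndarray,
             log_init: np.ndarray) -> np.ndarray:
    L = log_emit.shape[0]
    # work in tie-break preference order so argmax resolves toward IBD1
    perm = _STATE_PREF
    le = log_emit[:, perm]
    lt = log_trans[:, perm][:, :, perm]
    score = log_init[perm] + le[0]
    back = np.zeros((L, 3), dtype=np.int8)
    for i in range(1, L):
        cand = score[:, None] + lt[i - 1]
        back[i] = np.argmax(cand, axis=0)
        score = np.max(cand, axis=0) + le[i]
    path = np.empty(L, dtype=np.int8)
    j = int(np.argmax(score))
    path[-1] = j
    for i in range(L - 1, 0, -1):
        j = back[i, j]
        path[i - 1] = j
    return perm[path]


def _forward_backward(log_emit: np.ndarray, log_trans: np.ndarray,
                      log_init: np.ndarray) -> np.ndarray:
    # scaled linear-space recursions; per-SNP max subtraction guards the exp
    L = log_emit.shape[0]
    emit = np.exp(log_emit - log_emit.max(axis=1, keepdims=True))
    trans = np.exp(log_trans)
    fwd = np.empty((L, 3))
    a = np.exp(log_init) * emit[0]
    fwd[0] = a / a.sum()
    for i in range(1, L):
        a = (fwd[i - 1] @ trans[i - 1]) * emit[i]
        fwd[i] = a / a.sum()
    post = np.empty((L, 3))
    b = np.ones(3)
    post[-1] = fwd[-1]
    for i in range(L - 2, -1, -1):
        b = trans[i] @ (emit[i + 1] * b)
        b /= b.sum()
        p = fwd[i] * b
        post[i] = p / p.sum()
    return post


def _segment_boundaries_cM(states: np.ndarray, pos_cM: np.ndarray):
    """Runs of constant state with midpoint cM boundaries."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(states)]])  # exclusive SNP index
    bounds = np.empty(len(starts) + 1)
    bounds[0] = pos_cM[0]
    bounds[-1] = pos_cM[-1]
    for k, s in enumerate(starts[1:], start=1):
        bounds[k] = 0.5 * (pos_cM[s - 1] + pos_cM[s])
    return starts, ends, bounds


def smooth_segments(path: IbdPath, m: float) -> IbdPath:
    """Remove runs shorter than ``m`` cM whose two flanks share a state.

    Applied iteratively to a fixed point. Chromosome-end runs have only one
    flank and are kept.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    states = path.states.copy()
    if m > 0 and path.pos_cM is not None and len(states) > 2:
        while True:
            starts, ends, bounds = _segment_boundaries_cM(states, path.pos_cM)
            lengths = np.diff(bounds)
            run_states = states[starts]
            changed = False
            for k in range(1, len(starts) - 1):
                if (lengths[k] < m
                        and run_states[k - 1] == run_states[k + 1]
                        and run_states[k] != run_states[k - 1]):
                    states[starts[k]:ends[k]] = run_states[k - 1]
                    changed = True
                    break
            if not changed:
                break
    segments = _states_to_segments(states, path.pos_bp)
    return IbdPath(path.sib_pair, path.chrom, states, segments,
                   path.posteriors, path.pos_bp, path.pos_cM)


def _states_to_segments(states: np.ndarray, pos_bp: np.ndarray | None):
    if pos_bp is None:
        pos_bp = np.arange(1, len(states) + 1)
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(states)]])
    segs = []
    for s, e in zip(starts, ends):
        start_bp = int(pos_bp[s])
        end_bp = int(pos_bp[e]) if e < len(states) else int(pos_bp[-1]) + 1
        segs.append((start_bp, end_bp, int(states[s])))
    return segs


def infer_ibd(g1: np.ndarray, g2: np.ndarray, variants: list[VariantInfo],
              params: IbdParams = IbdParams(),
              sib_pair: tuple[str, str] = ("sib1", "sib2"),
              chrom: str | None = None) -> IbdPath:
    """Decode the IBD path of one sibling pair along one chromosome.

    ``g1``, ``g2`` are unphased genotype arrays aligned with ``variants``
    (sorted by pos_cM). Per-SNP emission log-likelihoods are weighted by the
    inverse LD score before decoding (Viterbi and posteriors consistently),
    then segments are smoothed with :func:`smooth_segments`.
    """
    g1 = np.asarray(g1, dtype=np.int16)
    g2 = np.asarray(g2, dtype=np.int16)
    L = len(variants)
    if L < 10:
        warnings.warn(f"chromosome with only {L} SNPs; IBD path unreliable")
    pos_cM = np.array([v.pos_cM for v in variants], dtype=float)
    if np.any(np.diff(pos_cM) < 0):
        raise ValueError("variants must be sorted by pos_cM")
    pos_bp = np.array([v.pos_bp for v in variants], dtype=np.int64)
    freqs = np.array([v.freq for v in variants], dtype=float)
    lds = np.array([v.ld_score if v.ld_score is not None else np.nan
                    for v in variants], dtype=float)
    if np.isnan(lds).any():
        warnings.warn("missing LD scores; defaulting to 1.0 (no weighting)")
        lds = np.where(np.isnan(lds), 1.0, lds)
    # inverse-LD weights normalized to mean 1: down-weights high-LD SNPs
    # without changing the overall emission/transition balance, so constant
    # LD scores reproduce the unweighted HMM exactly
    w = 1.0 / lds
    w /= w.mean()

    log_emit = _emission_logprob_array(g1, g2, freqs, params.gamma) * w[:, None]
    d = np.diff(pos_cM)
    with np.errstate(divide="ignore"):
        log_trans = np.stack([np.log(transition_matrix(di)) for di in d]) \
            if L > 1 else np.zeros((0, 3, 3))
        log_init = np.log(np.array([0.25, 0.5, 0.25]))

    states = _viterbi(log_emit, log_trans, log_init)
    post = _forward_backward(log_emit, log_trans, log_init)
    chrom = chrom if chrom is not None else variants[0].chrom
    path = IbdPath(sib_pair, chrom, states, _states_to_segments(states, pos_bp),
                   post, pos_bp, pos_cM)
    return smooth_segments(path, params.min_segment_cM)


# ---------------------------------------------------------------------------
# Summaries and helpers
# ---------------------------------------------------------------------------

def ibd_summary(paths: list[IbdPath]) -> np.ndarray:
    """Genome-wide length-weighted (in cM) fractions of IBD0/1/2."""
    if not paths:
        raise ValueError("need at least one IBD path")
    totals = np.zeros(3)
    for p in paths:
        if p.pos_cM is None or len(p.states) < 2:
            continue
        starts, ends, bounds = _segment_boundaries_cM(p.states, p.pos_cM)
        lengths = np.diff(bounds)
        for k, s in enumerate(starts):
            totals[p.states[s]] += lengths[k]
    if totals.sum() == 0:
        raise ValueError("no positive-length segments in the supplied paths")
    return totals / totals.sum()


def compute_ld_scores(haplotypes: np.ndarray, variants: list[VariantInfo],
                      window_cM: float = 1.0) -> np.ndarray:
    """r^2-sum LD scores within a cM window, from a genotype sample.

    Intended for annotating simulated data; real analyses normally supply
    externally computed LD scores.
    """
    g = haplotypes.sum(axis=2).astype(float)        # (n, L)
    pos_cM = np.array([v.pos_cM for v in variants])
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = np.nan
    L = g.shape[1]
    scores = np.ones(L)
    for j in range(L):
        lo = np.searchsorted(pos_cM, pos_cM[j] - window_cM)
        hi = np.searchsorted(pos_cM, pos_cM[j] + window_cM, side="right")
        idx = np.arange(lo, hi)
        idx = idx[idx != j]
        if len(idx) == 0 or np.isnan(sd[j]):
            continue
        r = (g[:, idx] * g[:, [j]]).mean(axis=0) / (sd[idx] * sd[j])
        scores[j] = 1.0 + np.nansum(r ** 2)
    for v, s in zip(variants, scores):
        v.ld_score = float(s)
    return scores
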