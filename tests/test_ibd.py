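import itertools

import numpy as np
import pytest

from famimpute.genio import VariantInfo
from famimpute.ibd import (IbdParams, IbdPath, emission_logprob, ibd_summary,
                           infer_ibd, smooth_segments, transition_matrix)


def _enumeration_emission(g1, g2, f):
    """Independent oracle: P(g1, g2 | IBD) by enumerating parental genotypes
    and transmissions (error-free)."""
    probs = np.zeros(3)
    denom = np.zeros(3)
    for al in itertools.product((0, 1), repeat=4):
        w = np.prod([f if a else 1 - f for a in al])
        p1, p2, m1, m2 = al
        for x1, y1, x2, y2 in itertools.product((0, 1), repeat=4):
            k = int(x1 == x2) + int(y1 == y2)
            denom[k] += w / 16
            if ((p1, p2)[x1] + (m1, m2)[y1] == g1
                    and (p1, p2)[x2] + (m1, m2)[y2] == g2):
                probs[k] += w / 16
    return probs / denom


@pytest.mark.parametrize("g1,g2,f", [(0, 0, 0.5), (1, 2, 0.3), (1, 1, 0.1),
                                     (0, 2, 0.4)])
def test_emission_matches_enumeration_oracle(g1, g2, f):
    got = np.exp(emission_logprob(g1, g2, f, gamma=0.0))
    want = _enumeration_emission(g1, g2, f)
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_emission_opposite_homozygotes_impossible_in_ibd2():
    lp = emission_logprob(0, 2, 0.3, gamma=0.0)
    assert lp[2] == -np.inf
    assert np.exp(emission_logprob(0, 0, 0.5, 0.0))[2] == pytest.approx(0.25)


def test_emission_error_model_gives_full_support():
    lp = emission_logprob(0, 2, 0.3, gamma=1e-3)
    assert np.all(np.isfinite(lp))


def test_emission_missing_genotype_marginalized():
    from famimpute.genio import MISSING
    lp = emission_logprob(MISSING, 1, 0.3, 0.0)
    want = sum(_enumeration_emission(g, 1, 0.3) for g in (0, 1, 2))
    np.testing.assert_allclose(np.exp(lp), want, atol=1e-12)


def test_transition_identity_stationary_symmetry():
    np.testing.assert_allclose(transition_matrix(0.0), np.eye(3), atol=1e-12)
    far = transition_matrix(1e5)
    for row in far:
        np.testing.assert_allclose(row, [0.25, 0.5, 0.25], atol=1e-6)
    for d in (0.01, 0.5, 5.0):
        T = transition_matrix(d)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert T[0, 2] == pytest.approx(T[2, 0])


def _variants(pos_cM, f=0.4):
    return [VariantInfo(f"v{j}", "1", int(p * 1e6) + 1, freq=f, pos_cM=p,
                        ld_score=1.0)
            for j, p in enumerate(pos_cM)]


def test_identical_haplotypes_decode_ibd2():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, 200)
    path = infer_ibd(g, g, _variants(np.linspace(0, 50, 200)))
    assert (path.states == 2).all()
    np.testing.assert_allclose(path.posteriors.sum(axis=1), 1.0, atol=1e-9)


def test_ld_weighting_constant_equals_unweighted():
    rng = np.random.default_rng(1)
    g1 = rng.integers(0, 3, 300)
    g2 = rng.integers(0, 3, 300)
    v1 = _variants(np.linspace(0, 60, 300))  # ld_score = 1 everywhere
    p1 = infer_ibd(g1, g2, v1)
    for v in v1:
        v.ld_score = 3.7  # constant: normalized weights are all 1 again
    p2 = infer_ibd(g1, g2, v1)
    assert np.array_equal(p1.states, p2.states)
    np.testing.assert_allclose(p1.posteriors, p2.posteriors, atol=1e-9)


def test_viterbi_beats_perturbed_paths(dense_sim):
    rng = np.random.default_rng(3)
    gset = dense_sim.gset
    G = gset.genotypes()
    (o1, o2), truth = next(iter(dense_sim.true_ibd.items()))
    path = infer_ibd(G[gset.index_of(o1)], G[gset.index_of(o2)], gset.variants)

    from famimpute.ibd import _emission_logprob_array, transition_matrix as tm
    freqs = gset.freqs()
    le = _emission_logprob_array(G[gset.index_of(o1)].astype(np.int16),
                                 G[gset.index_of(o2)].astype(np.int16),
                                 freqs, 1e-4)
    pos = gset.positions_cM()

    def loglik(states):
        ll = np.log([0.25, 0.5, 0.25])[states[0]] + le[0, states[0]]
        for i in range(1, len(states)):
            T = tm(pos[i] - pos[i - 1])
            ll += np.log(T[states[i - 1], states[i]]) + le[i, states[i]]
        return ll

    base = loglik(path.states)
    for _ in range(5):
        pert = path.states.copy()
        i = rng.integers(0, len(pert))
        pert[i] = (pert[i] + rng.integers(1, 3)) % 3
        assert loglik(pert) <= base + 1e-9


def test_ibd_accuracy_above_99_percent(dense_sim):
    """Per-SNP state accuracy on simulator ground truth with genotyping
    error injected at the gamma = 1e-4 level, one SNP per 0.02 cM."""
    rng = np.random.default_rng(9)
    gset = dense_sim.gset
    G = gset.genotypes()
    accs = []
    for (o1, o2), truth in list(dense_sim.true_ibd.items())[:10]:
        g1 = G[gset.index_of(o1)].astype(int).copy()
        g2 = G[gset.index_of(o2)].astype(int).copy()
        for g in (g1, g2):
            err = rng.random(len(g)) < 1e-4
            g[err] = rng.integers(0, 3, err.sum())
        path = infer_ibd(g1, g2, gset.variants, IbdParams())
        accs.append(np.mean(path.states == truth.states))
    assert np.mean(accs) > 0.99


def test_gamma_zero_never_assigns_impossible_states(dense_sim):
    gset = dense_sim.gset
    G = gset.genotypes()
    (o1, o2), _ = next(iter(dense_sim.true_ibd.items()))
    g1, g2 = G[gset.index_of(o1)], G[gset.index_of(o2)]
    path = infer_ibd(g1, g2, gset.variants, IbdParams(gamma=0.0,
                                                      min_segment_cM=0.0))
    opp_hom = (np.minimum(g1, g2) == 0) & (np.maximum(g1, g2) == 2)
    assert not np.any(path.states[opp_hom] == 2)
    assert not np.any(path.states[opp_hom] == 1)


def _path(states, pos_cM):
    pos_bp = (np.asarray(pos_cM) * 1e6).astype(int) + 1
    from famimpute.ibd import _states_to_segments
    st = np.asarray(states, dtype=np.int8)
    return IbdPath(("a", "b"), "1", st, _states_to_segments(st, pos_bp),
                   None, pos_bp, np.asarray(pos_cM, dtype=float))


def test_smoothing_removes_short_segment_with_agreeing_flanks():
    p = _path([1, 1, 2, 1, 1], [0.0, 0.1, 0.2, 0.3, 0.4])
    sm = smooth_segments(p, m=0.5)
    assert list(sm.states) == [1, 1, 1, 1, 1]


def test_smoothing_keeps_short_segment_with_disagreeing_flanks():
    p = _path([0, 0, 2, 1, 1], [0.0, 0.1, 0.2, 0.3, 0.4])
    sm = smooth_segments(p, m=0.5)
    assert list(sm.states) == [0, 0, 2, 1, 1]


def test_smoothing_m_zero_is_identity():
    p = _path([1, 2, 1, 0, 0], [0.0, 0.1, 0.2, 0.3, 0.4])
    assert np.array_equal(smooth_segments(p, 0.0).states, p.states)


def test_ibd_fractions_near_mendelian_expectation():
    from famimpute.simulate import SimConfig, run_simulation
    sim = run_simulation(SimConfig(n_families=300, n_snps=400,
                                   chrom_length_cM=100.0, seed=55))
    frac = ibd_summary(list(sim.true_ibd.values()))
    # 3 MC SEs: each pair contributes ~1 effective draw per ~25 cM
    np.testing.assert_allclose(frac, [0.25, 0.5, 0.25], atol=0.04)


def test_ibd_summary_single_pair_all_ibd2():
    p = _path([2, 2, 2], [0.0, 1.0, 2.0])
    np.testing.assert_allclose(ibd_summary([p]), [0, 0, 1])
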