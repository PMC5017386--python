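"""Chain HMM construction and Viterbi decoding, with an exhaustive oracle."""

import itertools

import numpy as np
import pytest

from scrubseq.core import GestureLabel, ROUTINE_ORDER
from scrubseq.hmm import ChainHMM, build_who_chain, smooth_predictions, viterbi_decode

G = GestureLabel


def brute_force_decode(obs_ordinals, hmm: ChainHMM, tol=1e-9):
    """Score every possible state path explicitly (feasible for T <= 5).

    Returns every path whose score is within ``tol`` of the optimum: distinct
    paths can be *exactly* tied (same multiset of log terms), in which case
    float summation order decides the argmax arbitrarily.
    """
    logA, logB, logpi = hmm.log_matrices()
    T = len(obs_ordinals)
    scored = []
    for path in itertools.product(range(9), repeat=T):
        s = logpi[path[0]] + logB[path[0], obs_ordinals[0]]
        for t in range(1, T):
            s += logA[path[t - 1], path[t]] + logB[path[t], obs_ordinals[t]]
        scored.append((s, list(path)))
    best = max(s for s, _ in scored)
    return [p for s, p in scored if s >= best - tol]


class TestBuildWhoChain:
    def test_default_matrices(self):
        hmm = build_who_chain()
        np.testing.assert_allclose(hmm.A[0], [0.995, 0.005] + [0.0] * 7)
        np.testing.assert_allclose(hmm.A[8], [0.0] * 8 + [1.0])  # absorbing
        np.testing.assert_allclose(hmm.A.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(hmm.B.sum(axis=1), 1.0, atol=1e-12)
        assert hmm.pi[0] == 1.0 and hmm.pi[1:].sum() == 0.0

    def test_near_perfect_emission_is_identity(self):
        hmm = build_who_chain(emission_correct=1 - 1e-9)
        np.testing.assert_allclose(hmm.B, np.eye(9), atol=1e-8)

    def test_uniform_start(self):
        hmm = build_who_chain(start_at_first=False)
        np.testing.assert_allclose(hmm.pi, 1.0 / 9)

    @pytest.mark.parametrize("kw", [{"self_prob": 0.0}, {"self_prob": 1.0},
                                    {"emission_correct": 0.1}, {"emission_correct": 1.0}])
    def test_parameter_range_rejected(self, kw):
        with pytest.raises(ValueError):
            build_who_chain(**kw)

    def test_non_chain_transition_rejected(self):
        hmm = build_who_chain()
        A = hmm.A.copy()
        A[3, 1] = A[3, 3] - 0.01 + 0.01  # will not be zero below
        A[3, 1] = 0.01
        A[3, 3] -= 0.01
        with pytest.raises(ValueError, match="left-to-right"):
            ChainHMM(A=A, B=hmm.B, pi=hmm.pi)


class TestViterbi:
    def test_constant_observations_decode_to_themselves(self):
        hmm = build_who_chain()
        obs = [G.G1] * 40
        assert viterbi_decode(obs, hmm) == obs

    def test_isolated_spike_is_smoothed_away(self):
        hmm = build_who_chain()
        obs = [G.G1] * 50 + [G.G3] + [G.G1] * 50 + [G.G2L] * 50
        decoded = viterbi_decode(obs, hmm)
        assert G.G3 not in decoded
        assert decoded[:101] == [G.G1] * 101

    def test_matches_exhaustive_enumeration(self):
        """Viterbi == brute force on 200 seeded random sequences, T <= 5."""
        hmm = build_who_chain(start_at_first=False)  # uniform start: all states live
        rng = np.random.default_rng(99)
        for _ in range(200):
            T = int(rng.integers(1, 6))
            obs = rng.integers(0, 9, size=T)
            optimal = brute_force_decode(obs, hmm)
            got = [g.ordinal for g in viterbi_decode(obs, hmm)]
            assert got in optimal
            if len(optimal) == 1:  # unique optimum: exact agreement required
                assert got == optimal[0]

    def test_matches_enumeration_with_pinned_start(self):
        hmm = build_who_chain(start_at_first=True)
        rng = np.random.default_rng(7)
        for _ in range(50):
            T = int(rng.integers(1, 6))
            obs = rng.integers(0, 9, size=T)
            assert [g.ordinal for g in viterbi_decode(obs, hmm)] in brute_force_decode(obs, hmm)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            viterbi_decode([], build_who_chain())


class TestSmoothing:
    def test_monotone_with_at_most_eight_switches(self):
        hmm = build_who_chain()
        rng = np.random.default_rng(3)
        for _ in range(20):
            obs = rng.integers(0, 9, size=300)
            out = np.array([g.ordinal for g in smooth_predictions(obs, hmm)])
            assert np.all(np.diff(out) >= 0)
            assert int(np.sum(np.diff(out) != 0)) <= 8

    def test_clean_monotone_input_is_fixed_point(self):
        hmm = build_who_chain()
        obs = [g for g in ROUTINE_ORDER for _ in range(100)]
        assert smooth_predictions(obs, hmm) == obs

    def test_single_frame_uniform_start(self):
        hmm = build_who_chain(start_at_first=False)
        assert smooth_predictions([G.G4], hmm) == [G.G4]

    @pytest.mark.parametrize("noise", [0.05, 0.15, 0.30])
    def test_smoothing_never_hurts_on_noisy_routines(self, noise):
        """Injecting frame-label noise into a clean routine: decoding always
        recovers at least the noisy accuracy (the claimed benefit of the
        sequence prior, strongest when classification is poor)."""
        hmm = build_who_chain()
        truth = np.repeat(np.arange(9), 150)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            obs = truth.copy()
            flip = rng.random(truth.size) < noise
            obs[flip] = (obs[flip] + rng.integers(1, 9, size=int(flip.sum()))) % 9
            acc_pre = np.mean(obs == truth)
            decoded = np.array([g.ordinal for g in smooth_predictions(obs, hmm)])
            acc_post = np.mean(decoded == truth)
            assert acc_post >= acc_pre

    def test_no_nan_or_inf_in_decoding(self):
        # all-wrong observations still decode to a finite-scoring path
        hmm = build_who_chain()
        obs = [G.G6R] * 100
        out = smooth_predictions(obs, hmm)
        assert len(out) == 100
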