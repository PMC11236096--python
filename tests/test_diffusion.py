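"""Unit and property tests for the diffusion operators and the denoiser."""

import numpy as np
import pytest

from rendor.diffusion import (
    DenoiseConfig,
    clip_negative_rows,
    forward_diffusion,
    from_transition,
    inverse_diffusion,
    nr_diffuse,
    preprocess,
    rendor_denoise,
    stationary,
    to_transition,
)
from rendor.netsim import NoisySimSpec, make_noisy_network
from rendor.metrics import confusion_at_k, matrix_to_ranking

from conftest import random_connected_weighted, random_stochastic


# ---------------------------------------------------------------- g: W -> P

class TestToTransition:
    def test_equal_split_on_cycle(self):
        W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        P = to_transition(W)
        assert np.allclose(P, (np.ones((3, 3)) - np.eye(3)) / 2)

    def test_single_neighbor(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(to_transition(W), [[0, 1], [1, 0]])

    def test_weighted_path(self):
        W = np.array([[0, 1, 0], [1, 0, 3], [0, 3, 0]], dtype=float)
        P = to_transition(W)
        assert np.allclose(P[1], [0.25, 0.0, 0.75])

    def test_zero_degree_node_named_in_error(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            to_transition(W)


# ------------------------------------------------------- forward diffusion

class TestForwardDiffusion:
    def test_two_node_worked_example(self):
        # hand algebra: (m-1) P (mI-P)^{-1} = 1/(m+1) [[1, m], [m, 1]]
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(forward_diffusion(P, 4), [[0.2, 0.8], [0.8, 0.2]], atol=1e-12)

    def test_identity_fixed_point(self):
        assert np.allclose(forward_diffusion(np.eye(4), 7.0), np.eye(4), atol=1e-12)

    def test_large_m_limit_is_input(self, rng):
        P = random_stochastic(rng, 10)
        assert np.max(np.abs(forward_diffusion(P, 1e6) - P)) < 1e-5

    def test_matches_truncated_series(self, rng):
        # sum_{k=1..60} P^k/m^k normalised by sum 1/m^k
        for n in (5, 20, 50):
            P = random_stochastic(rng, n)
            for m in (2.0, 4.0):
                acc = np.zeros_like(P)
                Pk = np.eye(n)
                norm = 0.0
                for k in range(1, 61):
                    Pk = Pk @ P
                    acc += Pk / m**k
                    norm += 1.0 / m**k
                assert np.max(np.abs(forward_diffusion(P, m) - acc / norm)) < 1e-10

    def test_deviation_from_input_shrinks_with_m(self, rng):
        P = random_stochastic(rng, 15)
        devs = [np.max(np.abs(forward_diffusion(P, m) - P))
                for m in (10.0, 1e2, 1e3, 1e4)]
        assert all(a > b for a, b in zip(devs, devs[1:]))

    @pytest.mark.parametrize("m", [1.0, 0.5, -2.0])
    def test_invalid_m_rejected(self, m):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="m must be > 1"):
            forward_diffusion(P, m)


# ------------------------------------------------------- inverse diffusion

class TestInverseDiffusion:
    def test_round_trip_of_worked_example(self):
        P = np.array([[0.2, 0.8], [0.8, 0.2]])
        assert np.allclose(inverse_diffusion(P, 4), [[0, 1], [1, 0]], atol=1e-12)

    def test_identity_fixed_point(self):
        assert np.allclose(inverse_diffusion(np.eye(3), 5.0), np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("m", [2.0, 4.0, 10.0])
    def test_exact_inverse_pair(self, rng, m):
        P = random_stochastic(rng, 50)
        assert np.max(np.abs(inverse_diffusion(forward_diffusion(P, m), m) - P)) < 1e-8
        assert np.max(np.abs(forward_diffusion(inverse_diffusion(P, m), m) - P)) < 1e-8

    @pytest.mark.parametrize("m", [2.0, 4.0, 10.0])
    def test_rows_still_sum_to_one(self, rng, m):
        P = random_stochastic(rng, 40)
        out = inverse_diffusion(P, m)
        assert np.max(np.abs(out.sum(axis=1) - 1.0)) < 1e-10

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            inverse_diffusion(np.eye(2), 1.0)


# --------------------------------------------------- stationary and h: P->W

class TestStationary:
    def test_doubly_stochastic_gives_uniform(self):
        P = to_transition(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        assert np.allclose(stationary(P), [1 / 3] * 3, atol=1e-10)

    def test_proportional_to_degree_on_path(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert np.allclose(stationary(to_transition(W)), [0.25, 0.5, 0.25], atol=1e-10)

    def test_matches_power_iteration_oracle(self, rng):
        P = random_stochastic(rng, 20)
        pi = np.full(20, 1 / 20)
        for _ in range(10_000):
            pi = pi @ P
        got = stationary(P)
        assert np.max(np.abs(got - pi)) < 1e-8
        assert np.max(np.abs(got @ P - got)) < 1e-8

    def test_reducible_chain_rejected(self):
        P = np.zeros((4, 4))
        P[0, 1] = P[1, 0] = P[2, 3] = P[3, 2] = 1.0
        with pytest.raises(ValueError, match="reducible"):
            stationary(P)


class TestFromTransition:
    def test_gh_duality_recovers_graph(self, rng):
        W = random_connected_weighted(rng, 30)
        rec = from_transition(to_transition(W), alpha=W.sum())
        assert np.max(np.abs(rec - W)) < 1e-8

    def test_uniform_walk_on_complete_triangle(self):
        P = (np.ones((3, 3)) - np.eye(3)) / 2
        out = from_transition(P, alpha=6.0)
        assert np.allclose(out, np.ones((3, 3)) - np.eye(3), atol=1e-10)

    def test_reversible_chain_needs_no_symmetrization(self, rng):
        W = random_connected_weighted(rng, 8)
        P = to_transition(W)
        pi = stationary(P)
        M = pi[:, None] * P
        assert np.allclose(M, M.T, atol=1e-12)


# --------------------------------------------------- pre/post processing

class TestPreprocess:
    def test_auto_on_unweighted_graph(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        Wt = preprocess(W)
        assert Wt[0, 1] == 2.0  # existing edge
        assert Wt[0, 2] == 1.0  # non-edge
        assert Wt[0, 0] == 2.0  # diagonal
        assert Wt[1, 1] == 2.0

    def test_auto_on_weighted_graph_uses_min_nonzero(self):
        W = np.array([[0, 0.05, 0], [0.05, 0, 0.8], [0, 0.8, 0]])
        assert np.allclose(preprocess(W), W + 0.05 * np.ones((3, 3)) + 0.05 * np.eye(3))

    def test_zero_offsets_are_identity(self, rng):
        W = random_connected_weighted(rng, 6)
        assert np.array_equal(preprocess(W, 0.0, 0.0), W)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((2, 2)), -0.1, 0.0)


class TestClipNegativeRows:
    def test_row_shift_formula(self):
        P = np.array([[0.5, -0.2, 0.7], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        out = clip_negative_rows(P)
        assert np.allclose(out[0], [0.7, 0.0, 0.9])
        assert np.allclose(out[1], P[1])  # no negative entry: unchanged
        assert np.allclose(out[2], P[2])  # all-zero row: unchanged

    def test_nonnegative_matrix_unchanged(self, rng):
        P = random_stochastic(rng, 7)
        assert np.array_equal(clip_negative_rows(P), P)

    def test_tiny_float_negatives_not_shifted(self):
        P = np.array([[0.5, -1e-14], [0.2, 0.8]])
        assert np.array_equal(clip_negative_rows(P), P)


# --------------------------------------------------------- composite ops

class TestRendorDenoise:
    def test_path_redundant_chord_is_deflated(self):
        # a chord whose endpoints are already joined by a short path is
        # transitively explainable and must fall to the bottom of the
        # edge ranking, while path-critical edges are preserved
        n = 20
        W = np.zeros((n, n))
        for i in range(n):
            W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
        W[0, 2] = W[2, 0] = 1.0  # chord across the 0-1-2 path
        out = rendor_denoise(W, m=4)
        cycle_weights = [out[i, (i + 1) % n] for i in range(n)]
        assert out[0, 2] < min(cycle_weights)

    def test_bridge_between_clusters_is_preserved(self):
        # the converse: an edge with no alternative path (a bridge) has
        # no indirect contribution to strip and keeps a top rank
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        W[1, 2] = W[2, 1] = 0.3
        out = rendor_denoise(W, m=4)
        # bridge still outranks every pair absent from the input
        assert out[1, 2] > out[0, 2]
        assert out[1, 2] > out[0, 3]

    def test_output_symmetric_zero_diagonal(self, rng):
        W = random_connected_weighted(rng, 12)
        out = rendor_denoise(W)
        assert np.array_equal(out, out.T)
        assert np.all(np.diag(out) == 0.0)
        assert np.all(out >= 0)

    def test_deterministic_bit_identical(self, rng):
        W = random_connected_weighted(rng, 10)
        assert np.array_equal(rendor_denoise(W), rendor_denoise(W))

    def test_matches_input_total_weight_by_default(self, rng):
        W = random_connected_weighted(rng, 10)
        out = rendor_denoise(W, eps1=0.0, eps2=0.0)
        assert np.isclose(out.sum(), W.sum(), rtol=1e-10)

    def test_recovers_true_cycle_edges_from_noise(self):
        # scaled version of the noisy-cycle experiment: averaged over
        # seeds, reverse diffusion retains more true edges in its top-20
        # than the tied noisy input does
        tp_in, tp_out = [], []
        for seed in range(10):
            spec = NoisySimSpec(topology="circular", n=20,
                                noise_proportion=15 / 35, seed=seed)
            net = make_noisy_network(spec)
            truth = net.signal_pairs()
            den = rendor_denoise(net.weights, m=4)
            tp_in.append(confusion_at_k(matrix_to_ranking(net.weights), truth, 20)["tp"])
            tp_out.append(confusion_at_k(matrix_to_ranking(den), truth, 20)["tp"])
        assert np.mean(tp_out) > np.mean(tp_in)

    def test_literal_pipeline_flag_available(self, rng):
        W = random_connected_weighted(rng, 8)
        out = rendor_denoise(W, renormalize_rows=False)
        assert np.array_equal(out, out.T)

    def test_config_validates_m(self):
        with pytest.raises(ValueError):
            DenoiseConfig(m=1.0)


class TestNrDiffuse:
    def test_inverts_forward_diffusion_exactly_without_offsets(self, rng):
        W = random_connected_weighted(rng, 20)
        diffused = nr_diffuse(W, m=4)
        back = rendor_denoise(diffused, m=4, eps1=0.0, eps2=0.0, alpha=W.sum())
        assert np.max(np.abs(back - W)) < 1e-8

    def test_every_pair_gains_weight_on_connected_graph(self):
        W = np.zeros((5, 5))
        for i in range(4):  # path graph
            W[i, i + 1] = W[i + 1, i] = 1.0
        out = nr_diffuse(W, m=4)
        off = out[~np.eye(5, dtype=bool)]
        assert np.all(off > 0)

    def test_two_node_transition_mass(self):
        # before h the off-diagonal transition mass at m=4 is 0.8
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        P_out = forward_diffusion(to_transition(W), 4)
        assert np.allclose(P_out, [[0.2, 0.8], [0.8, 0.2]], atol=1e-12)


class TestProperties:
    """Randomised invariants of the operator algebra."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(n=st.integers(2, 12), seed=st.integers(0, 10_000),
           m=st.floats(1.2, 50.0))
    def test_inverse_pair_and_row_sums(self, n, seed, m):
        P = random_stochastic(np.random.default_rng(seed), n)
        F = forward_diffusion(P, m)
        assert np.max(np.abs(F.sum(axis=1) - 1.0)) < 1e-10
        assert np.all(F > -1e-12)  # forward diffusion keeps nonnegativity
        B = inverse_diffusion(P, m)
        assert np.max(np.abs(B.sum(axis=1) - 1.0)) < 1e-10
        assert np.max(np.abs(inverse_diffusion(F, m) - P)) < 1e-8

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(n=st.integers(2, 10), seed=st.integers(0, 10_000))
    def test_clip_negative_rows_postconditions(self, n, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(-1, 1, (n, n))
        out = clip_negative_rows(P)
        assert np.all(out >= -1e-12)
        # rows already nonnegative are untouched
        for i in range(n):
            if P[i].min() >= 0:
                assert np.array_equal(out[i], P[i])


def test_spectral_radius_of_scaled_walk_below_one(rng):
    P = random_stochastic(rng, 30)
    rho = np.max(np.abs(np.linalg.eigvals(P / 4.0)))
    assert rho < 1.0
    assert abs(rho - 0.25) < 1e-10
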