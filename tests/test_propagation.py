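import numpy as np
import pytest

from heteroprop import toy_network
from heteroprop.model_io import (
    ConfigurationError,
    ConvergenceError,
    DiffusionConfig,
    ValidationError,
)
from heteroprop.propagation import (
    TransitionMatrix,
    enriched_initial,
    normalize,
    propagate_integrated,
    propagate_single,
)

from conftest import permute_network


def hand_normalize(W):
    """Independent degree normalization: W / sqrt(outer(row sums, col sums))."""
    W = np.asarray(W, float)
    dr, dc = W.sum(1), W.sum(0)
    denom = np.sqrt(np.outer(dr, dc))
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, W / denom, 0.0)
    return S


def coupled_oracle(net, query, config):
    """Dense fixed-point solve of the full coupled linear system.

    Built independently from the raw weight matrices: x = b + A x with
    alpha_i S_i diagonal blocks, alpha_i S_ij hetero blocks, and
    b_i = (1 - alpha_i)(1 - k_i alpha_i) p_i^0.
    """
    kinds = ["drug", "gene", "phenotype"]
    k = {"drug": 1, "gene": 2, "phenotype": 1}
    S = {kind: hand_normalize(net.homo(kind).weights) for kind in kinds}
    S_dg = hand_normalize(net.drug_gene.links)
    S_pg = hand_normalize(net.phenotype_gene.links)
    blocks = {
        "drug": [("gene", S_dg)],
        "phenotype": [("gene", S_pg)],
        "gene": [("phenotype", S_pg.T), ("drug", S_dg.T)],
    }
    sizes = [net.homo(kind).n_nodes for kind in kinds]
    off = dict(zip(kinds, np.cumsum([0] + sizes[:-1])))
    n = sum(sizes)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for kind, size in zip(kinds, sizes):
        a = config.alpha[kind]
        i0 = off[kind]
        A[i0:i0 + size, i0:i0 + size] = a * S[kind]
        for other, blk in blocks[kind]:
            j0 = off[other]
            A[i0:i0 + size, j0:j0 + blk.shape[1]] = a * blk
        p0 = np.zeros(size)
        if kind == "phenotype":
            p0[net.phenotype.node_ids.index(query)] = 1.0
        b[i0:i0 + size] = (1 - a) * (1 - k[kind] * a) * p0
    x = np.linalg.solve(np.eye(n) - A, b)
    return {kind: x[off[kind]:off[kind] + size] for kind, size in zip(kinds, sizes)}


class TestNormalize:
    def test_equal_sums_cancel(self):
        S = normalize(np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(S.values, [[0, 1], [1, 0]])

    def test_asymmetric_hand_example(self):
        # Dr = (2, 1), Dc = (1, 2)
        S = normalize(np.array([[1.0, 1.0], [0.0, 1.0]]))
        expected = [[1 / np.sqrt(2), 0.5], [0, 1 / np.sqrt(2)]]
        np.testing.assert_allclose(S.values, expected)

    def test_zero_matrix_maps_to_zero(self):
        S = normalize(np.zeros((3, 3)))
        assert (S.values == 0).all()

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            normalize(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_symmetric_input_has_spectral_radius_at_most_one(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            W = np.abs(rng.standard_normal((12, 12)))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            S = normalize(W).values
            assert np.abs(np.linalg.eigvals(S)).max() <= 1 + 1e-10


def random_transition(rng, n):
    W = np.abs(rng.standard_normal((n, n)))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    return normalize(W)


class TestPropagateSingle:
    def test_alpha_zero_traps_walker_at_initial_nodes(self):
        S = random_transition(np.random.default_rng(0), 6)
        p0 = np.zeros(6)
        p0[2] = 1.0
        p, its = propagate_single(S, p0, alpha=0.0)
        np.testing.assert_array_equal(p, p0)
        assert its == 1

    def test_two_node_exchange(self):
        # closed form (1 - a)(I - a S)^-1 p0 with S = [[0,1],[1,0]], a = 0.5
        S = TransitionMatrix(["a", "b"], ["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        p, _ = propagate_single(S, np.array([1.0, 0.0]), alpha=0.5)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-8)

    def test_identity_transition_is_a_fixed_point(self):
        S = TransitionMatrix(["a", "b"], ["a", "b"], np.eye(2))
        p0 = np.array([0.3, 0.7])
        p, _ = propagate_single(S, p0, alpha=0.6)
        np.testing.assert_allclose(p, p0, atol=1e-8)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_matches_closed_form_on_random_networks(self, alpha):
        rng = np.random.default_rng(42)
        for _ in range(10):
            S = random_transition(rng, 50)
            p0 = rng.random(50)
            p0 /= p0.sum()
            p, _ = propagate_single(S, p0, alpha, tol=1e-10)
            exact = (1 - alpha) * np.linalg.solve(np.eye(50) - alpha * S.values, p0)
            assert np.abs(p - exact).max() < 1e-8

    def test_residuals_contract_geometrically(self):
        rng = np.random.default_rng(1)
        S = random_transition(rng, 30)
        alpha = 0.7
        p = rng.random(30)
        p0 = p.copy()
        residuals = []
        for _ in range(40):
            p_next = (1 - alpha) * p0 + alpha * (S.values @ p)
            residuals.append(np.linalg.norm(p_next - p))
            p = p_next
        assert all(r2 <= r1 + 1e-15 for r1, r2 in zip(residuals, residuals[1:]))

    def test_non_convergence_raises_with_residual(self):
        S = random_transition(np.random.default_rng(2), 20)
        with pytest.raises(ConvergenceError) as err:
            propagate_single(S, np.ones(20) / 20, alpha=0.9, tol=1e-12, max_iter=2)
        assert err.value.residual is not None

    def test_rejects_mismatched_vector(self):
        S = random_transition(np.random.default_rng(3), 4)
        with pytest.raises(ValidationError):
            propagate_single(S, np.ones(5), alpha=0.5)


class TestEnrichedInitial:
    def test_equal_split_with_one_neighbor(self):
        S = TransitionMatrix(["a", "b"], ["x", "y"], np.eye(2))
        out = enriched_initial(np.array([1.0, 0.0]), [(S, np.array([0.0, 1.0]))], 0.5)
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_alpha_zero_keeps_own_vector(self):
        S = TransitionMatrix(["a"], ["x"], np.ones((1, 1)))
        out = enriched_initial(np.array([0.8]), [(S, np.array([1.0]))], 0.0)
        np.testing.assert_allclose(out, [0.8])

    def test_two_neighbors_at_high_alpha(self):
        # k = 2, alpha = 0.7 -> a = -0.4: strict rejects, literal proceeds
        S = TransitionMatrix(["a"], ["x"], np.zeros((1, 1)))
        neighbors = [(S, np.zeros(1)), (S, np.zeros(1))]
        with pytest.raises(ConfigurationError):
            enriched_initial(np.array([1.0]), neighbors, 0.7, mode="strict")
        out = enriched_initial(np.array([1.0]), neighbors, 0.7, mode="literal")
        np.testing.assert_allclose(out, [-0.4])

    def test_strict_coefficients_sum_to_one(self):
        for k in (0, 1, 2, 3):
            for alpha in (0.0, 0.1, 0.3):
                a = 1 - k * alpha
                if a < 0:
                    continue
                assert a + k * alpha == pytest.approx(1.0)
                assert a >= 0


class TestPropagateIntegrated:
    def test_all_alphas_zero_return_query_indicator(self, toy):
        config = DiffusionConfig(
            alpha={"drug": 0.0, "gene": 0.0, "phenotype": 0.0},
            coefficient_mode="strict",
        )
        state = propagate_integrated(toy, ["P1"], config)
        np.testing.assert_array_equal(state.vectors["phenotype"], [1.0, 0.0])
        np.testing.assert_array_equal(state.vectors["drug"], [0.0, 0.0])
        np.testing.assert_array_equal(state.vectors["gene"], [0.0, 0.0])

    def test_matches_coupled_oracle_on_toy(self, toy):
        state = propagate_integrated(toy, ["P1"])
        oracle = coupled_oracle(toy, "P1", toy.config)
        for kind in ("drug", "gene", "phenotype"):
            assert np.abs(state.vectors[kind] - oracle[kind]).max() < 1e-8

    def test_targeted_drug_outranks_untargeted(self, toy):
        state = propagate_integrated(toy, ["P1"])
        d = state.vectors["drug"]
        assert d[0] > d[1]

    def test_twin_drugs_with_identical_connectivity_tie(self):
        net = toy_network("twin")
        state = propagate_integrated(net, ["P1"])
        d = state.vectors["drug"]
        assert d[0] == pytest.approx(d[1], abs=1e-12)

    def test_sweep_solver_agrees_with_direct(self, toy):
        direct = propagate_integrated(toy, ["P1"], solver="direct")
        swept = propagate_integrated(toy, ["P1"], solver="sweep")
        for kind in ("drug", "gene", "phenotype"):
            assert np.abs(direct.vectors[kind] - swept.vectors[kind]).max() < 1e-7

    def test_multiple_queries_split_mass(self, toy):
        state = propagate_integrated(
            toy,
            ["P1", "P2"],
            DiffusionConfig(
                alpha={"drug": 0.0, "gene": 0.0, "phenotype": 0.0},
                coefficient_mode="strict",
            ),
        )
        np.testing.assert_allclose(state.vectors["phenotype"], [0.5, 0.5])

    def test_unknown_query_rejected(self, toy):
        with pytest.raises(ValidationError):
            propagate_integrated(toy, ["P9"])

    def test_strict_mode_rejects_high_gene_alpha(self, toy):
        config = DiffusionConfig(
            alpha={"drug": 0.1, "gene": 0.7, "phenotype": 0.3},
            coefficient_mode="strict",
        )
        with pytest.raises(ConfigurationError, match="gene"):
            propagate_integrated(toy, ["P1"], config)

    def test_relabeling_nodes_permutes_outputs(self, small_fixture):
        net = small_fixture.assemble()
        state = propagate_integrated(net, [small_fixture.query_phenotype])
        permuted, perms = permute_network(net, np.random.default_rng(11))
        state_p = propagate_integrated(permuted, [small_fixture.query_phenotype])
        for kind in ("drug", "gene", "phenotype"):
            np.testing.assert_allclose(
                state_p.vectors[kind], state.vectors[kind][perms[kind]], atol=1e-10
            )
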