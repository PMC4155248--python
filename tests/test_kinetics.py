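import math

import numpy as np
import pytest

from basinflood.fixtures import random_toy_landscape
from basinflood.global_flood import barriers_flood, brute_force_macromodel
from basinflood.kinetics import (
    MacroChain,
    arrhenius_chain,
    compare_models,
    exact_macro_chain,
    first_passage_times,
    fpt_from_start,
    merged_chain,
    spearman_rank_correlation,
)


@pytest.fixture
def l1_chain(L1):
    return exact_macro_chain(brute_force_macromodel(L1))


class TestExactChain:
    def test_l1_worked_probabilities(self, l1_chain):
        q01 = 0.5 * math.exp(-2) / (1 + math.exp(-2))
        q10 = 0.5 * math.exp(-1)
        i0, i2 = l1_chain.index["s0"], l1_chain.index["s2"]
        assert l1_chain.matrix[i0, i2] == pytest.approx(q01, rel=1e-12)
        assert l1_chain.matrix[i2, i0] == pytest.approx(q10, rel=1e-12)

    def test_macro_detailed_balance(self, L2):
        model = brute_force_macromodel(L2)
        chain = exact_macro_chain(model)
        Z = {b.minimum: b.Z for b in model.basins}
        for a in model.minima:
            for b in model.minima:
                if a != b:
                    lhs = Z[a] * chain.matrix[chain.index[a], chain.index[b]]
                    rhs = Z[b] * chain.matrix[chain.index[b], chain.index[a]]
                    assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-300)

    def test_rows_sum_to_one(self, L2):
        chain = exact_macro_chain(brute_force_macromodel(L2))
        assert np.abs(chain.matrix.sum(axis=1) - 1).max() < 1e-12

    def test_single_basin_is_identity(self):
        from basinflood.landscape import RnaLandscape

        chain = exact_macro_chain(brute_force_macromodel(RnaLandscape("AAAA")))
        assert chain.matrix.shape == (1, 1) and chain.matrix[0, 0] == 1.0


class TestArrheniusChain:
    def test_l2_adjacent_and_distant_pairs(self, L2):
        _, tree = barriers_flood(L2)
        ch = arrhenius_chain(tree, beta=1.0, A=0.01)
        # saddle({s2},{s3,s4}) = 2.0, E(s2) = 1.0
        assert ch.matrix[ch.index["s2"], ch.index["s4"]] == pytest.approx(
            0.01 * math.exp(-1.0), rel=1e-12
        )
        # non-adjacent pair gets positive probability from the barrier model
        assert ch.matrix[ch.index["s0"], ch.index["s4"]] == pytest.approx(
            0.01 * math.exp(-3.0), rel=1e-12
        )

    def test_detailed_balance_in_minima_energies(self, L1):
        _, tree = barriers_flood(L1)
        ch = arrhenius_chain(tree, beta=1.0)
        a01 = ch.matrix[ch.index["s0"], ch.index["s2"]]
        a10 = ch.matrix[ch.index["s2"], ch.index["s0"]]
        assert a01 / a10 == pytest.approx(math.exp(-(0.0 - 1.0) * -1.0), rel=1e-12)

    def test_auto_prefactor_keeps_diagonal_positive(self):
        L = random_toy_landscape(120, 4.0, 0.0, 5.0, seed=2)
        _, tree = barriers_flood(L)
        ch = arrhenius_chain(tree, beta=1.0)
        assert np.diag(ch.matrix).min() > 0

    def test_non_positive_prefactor_rejected(self, L2):
        _, tree = barriers_flood(L2)
        with pytest.raises(ValueError, match="positive"):
            arrhenius_chain(tree, beta=1.0, A=0.0)


class TestMergedChain:
    def test_l1_all_pairs_adjacent(self, L1, l1_chain):
        _, tree = barriers_flood(L1)
        arr = arrhenius_chain(tree, beta=1.0)
        mg = merged_chain(l1_chain, arr)
        off = ~np.eye(2, dtype=bool)
        assert np.allclose(mg.matrix[off], arr.matrix[off])

    def test_l2_masks_non_adjacent_pair(self, L2):
        model, tree = barriers_flood(L2)
        ex = exact_macro_chain(model)
        arr = arrhenius_chain(tree, beta=1.0)
        mg = merged_chain(ex, arr)
        i0, i4 = mg.index["s0"], mg.index["s4"]
        assert mg.matrix[i0, i4] == 0.0 and arr.matrix[i0, i4] > 0.0

    def test_no_exact_transitions_gives_identity(self):
        minima = ["a", "b"]
        ident = MacroChain(minima, np.eye(2), "exact")
        arr = MacroChain(minima, np.array([[0.6, 0.4], [0.4, 0.6]]), "barrier",
                         prefactor=1.0)
        mg = merged_chain(ident, arr)
        assert np.array_equal(mg.matrix, np.eye(2))

    def test_index_mismatch_rejected(self, l1_chain):
        other = MacroChain(["x", "y"], np.eye(2), "barrier", prefactor=1.0)
        with pytest.raises(ValueError, match="different basin lists"):
            merged_chain(l1_chain, other)


class TestFirstPassageTimes:
    def test_target_to_itself_zero(self, l1_chain):
        assert first_passage_times(l1_chain, "s2").values["s2"] == 0.0

    def test_geometric_mean(self):
        chain = MacroChain(["b", "t"], np.array([[0.5, 0.5], [0.0, 1.0]]), "exact")
        assert first_passage_times(chain, "t").values["b"] == pytest.approx(2.0)

    def test_l1_two_state_closed_form(self, l1_chain):
        q = 0.5 * math.exp(-2) / (1 + math.exp(-2))
        tau = first_passage_times(l1_chain, "s2").values["s0"]
        assert tau == pytest.approx(1.0 / q, rel=1e-9)
        assert tau == pytest.approx(16.778, abs=1e-3)

    def test_unreachable_start_is_infinite(self):
        chain = MacroChain(["a", "b"], np.eye(2), "exact")
        assert first_passage_times(chain, "b").values["a"] == math.inf

    def test_recursion_residual(self, L2):
        chain = exact_macro_chain(brute_force_macromodel(L2))
        target = "s4"
        fpt = first_passage_times(chain, target)
        tau = fpt.as_array(chain.minima)
        t = chain.index[target]
        resid = tau - (1.0 + chain.matrix @ tau)
        resid = np.delete(resid, t)
        assert np.abs(resid).max() < 1e-8

    def test_fundamental_matrix_route_agrees(self):
        """Single-factorization FPT equals per-target absorbing solves."""
        L = random_toy_landscape(120, 4.0, 0.0, 5.0, seed=5)
        model, tree = barriers_flood(L)
        start = model.minima[0]
        exact = exact_macro_chain(model)
        full = fpt_from_start(exact, start, pi=np.array([b.Z for b in model.basins]))
        arr = arrhenius_chain(tree, beta=1.0)
        E = np.array([tree.energies[m] for m in model.minima])
        full_a = fpt_from_start(arr, start, pi=np.exp(-(E - E.min())))
        for t in model.minima[1:]:
            assert full[t] == pytest.approx(
                first_passage_times(exact, t).values[start], rel=1e-8)
            assert full_a[t] == pytest.approx(
                first_passage_times(arr, t).values[start], rel=1e-8)


class TestSpearman:
    def test_identical_vectors(self):
        assert spearman_rank_correlation([1, 5, 9], [1, 5, 9]) == pytest.approx(1.0)

    def test_reversed_order(self):
        assert spearman_rank_correlation([1, 2, 3], [9, 5, 1]) == pytest.approx(-1.0)

    def test_worked_example(self):
        assert spearman_rank_correlation([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_non_finite_pairs_dropped(self):
        rho = spearman_rank_correlation([1, 2, 3, math.inf], [1, 2, 3, 0])
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("u,v", [([1.0], [2.0]), ([1, 1, 1], [1, 2, 3])])
    def test_degenerate_inputs_rejected(self, u, v):
        with pytest.raises(ValueError):
            spearman_rank_correlation(u, v)


class TestPrefactorInvariance:
    @pytest.mark.parametrize("seed", [6, 8])
    def test_fpt_ranks_invariant_to_prefactor(self, seed):
        import scipy.stats

        L = random_toy_landscape(100, 4.0, 0.0, 5.0, seed=seed)
        model, tree = barriers_flood(L)
        start = model.minima[0]
        targets = model.minima[1:]
        ranks = []
        base = arrhenius_chain(tree, beta=1.0).prefactor
        for A in (base, base / 10):
            ch = arrhenius_chain(tree, beta=1.0, A=A)
            tau = [first_passage_times(ch, t).values[start] for t in targets]
            ranks.append(scipy.stats.rankdata(tau))
        assert np.array_equal(ranks[0], ranks[1])


class TestCompareModels:
    def test_l2_coefficients_match_hand_solved_systems(self, L2):
        cmp = compare_models(L2, start_state="s0")
        # 2 targets only: coefficients are +-1; exact and merged share the
        # adjacency topology of the path, the pure barrier model shortcuts it
        assert cmp.spearman_exact_merged == pytest.approx(1.0)
        assert abs(cmp.spearman_exact_barrier) == pytest.approx(1.0)
        # cross-check exact FPTs against the hand-solvable absorbing systems
        model = brute_force_macromodel(L2)
        chain = exact_macro_chain(model)
        for t in ("s2", "s4"):
            assert cmp.fpt_exact[t] == pytest.approx(
                first_passage_times(chain, t).values["s0"], rel=1e-9)

    def test_model_against_itself_is_one(self, L2):
        cmp = compare_models(L2, start_state="s0")
        vals = [cmp.fpt_exact[t] for t in cmp.targets]
        assert spearman_rank_correlation(vals, vals) == pytest.approx(1.0)

    def test_single_basin_rejected(self):
        from basinflood.landscape import RnaLandscape

        with pytest.raises(ValueError, match="single basin"):
            compare_models(RnaLandscape("AAAA"))
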