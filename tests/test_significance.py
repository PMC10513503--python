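"""SVD subset criteria, exhaustive quadruple search and greedy ranking."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgidipole import (
    Criterion,
    criterion_score,
    exhaustive_quadruple,
    greedy_order,
    subset_singular_values,
    top_fraction_occurrence,
)
from ecgidipole.significance import _eigvals3_sym, all_quadruples

CRITERIA = [Criterion.A, Criterion.B, Criterion.C]


def brute_best_quadruple(block, crit):
    """Naive double-SVD brute force, no Gram fast path."""
    best = None
    for s in itertools.combinations(range(block.shape[0]), 4):
        sv = np.linalg.svd(block[list(s)], compute_uv=False)
        v = criterion_score(sv, crit)
        better = best is None or (v < best[1] if crit is Criterion.A else v > best[1])
        if better:
            best = (s, v)
    return best


class TestSingularValues:
    def test_constructed_diagonal_case(self):
        block = np.zeros((6, 3))
        block[0] = [2, 0, 0]
        block[1] = [0, 1, 0]
        block[2] = [0, 0, 1]
        sv = subset_singular_values(block, range(6))
        np.testing.assert_allclose(sv, [2, 1, 1], atol=1e-12)

    def test_gram_vs_svd_on_random_subsets(self, rng):
        """Fast Gram path and direct SVD agree to 1e-8 relative on 1000 subsets."""
        block = rng.normal(size=(16, 3))
        worst = 0.0
        for _ in range(1000):
            k = int(rng.integers(3, 17))
            subset = rng.choice(16, size=k, replace=False)
            a = subset_singular_values(block, subset, method="gram")
            b = subset_singular_values(block, subset, method="svd")
            worst = max(worst, float(np.max(np.abs(a - b) / b[0])))
        assert worst < 1e-8

    def test_identical_rows_rank_one(self):
        block = np.tile([[1.0, 2.0, 3.0]], (5, 1))
        sv_direct = subset_singular_values(block, [0, 1, 2], method="svd")
        assert sv_direct[1] == pytest.approx(0.0, abs=1e-12)
        assert sv_direct[2] == pytest.approx(0.0, abs=1e-12)
        # Gram path squares then square-roots, so exact zeros come back only
        # to sqrt(eps) relative accuracy
        sv_gram = subset_singular_values(block, [0, 1, 2], method="gram")
        assert sv_gram[1] < 1e-6 * sv_gram[0]
        assert sv_gram[2] < 1e-6 * sv_gram[0]

    def test_small_subset_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            subset_singular_values(rng.normal(size=(6, 3)), [0, 1])

    def test_closed_form_eigvals_vs_lapack(self, rng):
        g = rng.normal(size=(500, 5, 3))
        G = np.einsum("nij,nik->njk", g, g)
        lam = _eigvals3_sym(G)
        ref = np.linalg.eigvalsh(G)[:, ::-1]
        np.testing.assert_allclose(lam, ref, atol=1e-10 * ref.max())


class TestCriterionScore:
    @pytest.mark.parametrize(
        "svals,expected",
        [((1, 1, 1), {"A": 1.0, "B": 1.0, "C": 3.0}), ((3, 2, 1), {"A": 3.0, "B": 6.0, "C": 6.0})],
    )
    def test_arithmetic(self, svals, expected):
        for c in CRITERIA:
            assert criterion_score(svals, c) == pytest.approx(expected[c.value])

    def test_rank_deficient_sentinel(self):
        assert criterion_score((2, 1, 0), Criterion.A) == math.inf
        assert criterion_score((2, 1, 0), Criterion.B) == 0.0
        assert criterion_score((2, 1, 0), Criterion.C) == 3.0

    def test_condition_number_at_least_one(self, rng):
        for _ in range(50):
            sv = np.sort(np.abs(rng.normal(size=3)))[::-1]
            assert criterion_score(sv, Criterion.A) >= 1.0


class TestExhaustiveQuadruple:
    def test_combination_count_m5(self, rng):
        block = rng.normal(size=(5, 3))
        res = exhaustive_quadruple(block, Criterion.C)
        assert res.n_combinations == 5
        assert res.subset == brute_best_quadruple(block, Criterion.C)[0]

    @pytest.mark.parametrize("crit", CRITERIA)
    def test_matches_naive_brute_force_m10(self, crit, rng):
        block = np.random.default_rng(11).normal(size=(10, 3))
        res = exhaustive_quadruple(block, crit)
        want, score = brute_best_quadruple(block, crit)
        assert res.subset == want
        assert res.score == pytest.approx(score, rel=1e-9)

    def test_lexicographic_combos(self):
        q = all_quadruples(6)
        assert q.shape == (15, 4)
        assert q[0].tolist() == [0, 1, 2, 3] and q[-1].tolist() == [2, 3, 4, 5]

    def test_too_few_electrodes(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            exhaustive_quadruple(rng.normal(size=(3, 3)), Criterion.B)


class TestTopFractionOccurrence:
    def test_full_fraction_combinatorial_identity(self, rng):
        """fraction = 1 keeps everything: each electrode appears C(M-1, 3) times."""
        m = 9
        block = rng.normal(size=(m, 3))
        res = exhaustive_quadruple(block, Criterion.B, keep_scores=True)
        counts = top_fraction_occurrence(res, 1.0)
        np.testing.assert_array_equal(counts, np.full(m, math.comb(m - 1, 3)))

    def test_counts_sum_rule(self, rng):
        m, frac = 10, 0.25
        res = exhaustive_quadruple(rng.normal(size=(m, 3)), Criterion.C, keep_scores=True)
        counts = top_fraction_occurrence(res, frac)
        n_keep = math.floor(frac * math.comb(m, 4))
        assert counts.sum() == 4 * n_keep

    def test_selects_best_under_sense(self, rng):
        """The retained sets are exactly the top-scoring ones (checked by sort)."""
        m = 8
        block = rng.normal(size=(m, 3))
        res = exhaustive_quadruple(block, Criterion.A, keep_scores=True)
        counts = top_fraction_occurrence(res, 0.1)
        n_keep = math.floor(0.1 * res.n_combinations)
        best = np.argsort(res.scores, kind="stable")[:n_keep]  # A minimises
        ref = np.bincount(res.combos[best].ravel(), minlength=m)
        np.testing.assert_array_equal(counts, ref)

    def test_empty_selection_rejected(self, rng):
        res = exhaustive_quadruple(rng.normal(size=(6, 3)), Criterion.B, keep_scores=True)
        with pytest.raises(ValueError, match="empty"):
            top_fraction_occurrence(res, 1e-9)


class TestGreedyOrder:
    @pytest.mark.parametrize("crit", CRITERIA)
    def test_each_step_locally_optimal(self, crit):
        """Stepwise brute-force oracle: every greedy pick is exactly the best
        augmentation at that step (equality, not approximation)."""
        block = np.random.default_rng(21).normal(size=(12, 3))
        g = greedy_order(block, crit)
        chosen = list(g.order[:4])
        for step, e in enumerate(g.order[4:], start=1):
            best = None
            for cand in sorted(set(range(12)) - set(chosen)):
                sv = np.linalg.svd(block[chosen + [cand]], compute_uv=False)
                v = criterion_score(sv, crit)
                better = best is None or (v < best[1] - 0 if crit is Criterion.A else v > best[1])
                if better:
                    best = (cand, v)
            assert e == best[0]
            assert g.scores[step] == pytest.approx(best[1], rel=1e-8)
            chosen.append(int(e))

    def test_order_is_permutation(self, rng):
        block = rng.normal(size=(15, 3))
        for crit in CRITERIA:
            g = greedy_order(block, crit)
            assert sorted(g.order.tolist()) == list(range(15))

    @pytest.mark.parametrize("crit", [Criterion.B, Criterion.C])
    def test_monotone_scores(self, crit, rng):
        block = rng.normal(size=(20, 3))
        g = greedy_order(block, crit)
        assert np.all(np.diff(g.scores) >= -1e-9 * np.abs(g.scores[:-1]))

    def test_seed_matches_exhaustive(self, rng):
        block = rng.normal(size=(12, 3))
        for crit in CRITERIA:
            g = greedy_order(block, crit)
            assert g.seed_set == exhaustive_quadruple(block, crit).subset
            assert g.scores[0] == pytest.approx(exhaustive_quadruple(block, crit).score, rel=1e-12)

    @pytest.mark.parametrize("crit", [Criterion.B, Criterion.C])
    def test_zero_row_ranked_last(self, crit, rng):
        """An all-zero electrode row never changes B/C scores, so it ends last."""
        block = np.random.default_rng(33).normal(size=(10, 3))
        block[6] = 0.0
        g = greedy_order(block, crit)
        assert g.order[-1] == 6

    def test_full_set_score_matches_direct(self, rng):
        block = rng.normal(size=(14, 3))
        for crit in CRITERIA:
            g = greedy_order(block, crit)
            direct = criterion_score(np.linalg.svd(block, compute_uv=False), crit)
            assert g.scores[-1] == pytest.approx(direct, rel=1e-9)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_permutation_property_random_blocks(self, seed):
        block = np.random.default_rng(seed).normal(size=(8, 3))
        for crit in CRITERIA:
            g = greedy_order(block, crit)
            assert sorted(g.order.tolist()) == list(range(8))
            assert g.scores.size == 8 - 3
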