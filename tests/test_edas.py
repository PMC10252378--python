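"""The eight-step EDAS chain: worked-example cells and structural properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivestress.edas import (
    DecisionMatrix,
    appraisal,
    average_solution,
    distance_matrices,
    normalize_sums,
    rank,
    run_edas,
    weighted_sums,
)
from drivestress.errors import EmptyInputError
from drivestress.metrics import MetricsRow, decision_matrix_from_metrics
from drivestress.reference import CRITERIA_WEIGHTS, two_class_matrix


def reference_dm(state="relaxed"):
    names, x = two_class_matrix("cnn", state)
    return decision_matrix_from_metrics([(n, MetricsRow(*r)) for n, r in zip(names, x)])


def loop_edas(x, w, beneficial):
    """Independent step-by-step loop oracle (no vectorized shortcuts)."""
    n, m = x.shape
    psi = [sum(x[a][b] for a in range(n)) / n for b in range(m)]
    pi = [[0.0] * m for _ in range(n)]
    ni = [[0.0] * m for _ in range(n)]
    for a in range(n):
        for b in range(m):
            below = max(0.0, psi[b] - x[a][b]) / psi[b]
            above = max(0.0, x[a][b] - psi[b]) / psi[b]
            pi[a][b] = below if beneficial[b] else above
            ni[a][b] = above if beneficial[b] else below
    spi = [sum(w[b] * pi[a][b] for b in range(m)) for a in range(n)]
    sni = [sum(w[b] * ni[a][b] for b in range(m)) for a in range(n)]
    ms, mn = max(spi), max(sni)
    nspi = [s / ms if ms > 0 else 0.0 for s in spi]
    nsni = [1 - (s / mn if mn > 0 else 0.0) for s in sni]
    lam = [(p + q) / 2 for p, q in zip(nspi, nsni)]
    return psi, pi, ni, spi, sni, nspi, nsni, lam


class TestSteps:
    def test_average_solution_of_reference_matrix(self):
        psi = average_solution(reference_dm().x)
        assert np.allclose(psi.round(4), [0.9076, 0.9051, 0.8886, 0.8947, 0.9130])

    def test_average_of_constant_matrix(self):
        assert np.allclose(average_solution(np.full((4, 3), 2.5)), 2.5)

    def test_average_matches_loop_oracle(self, rng):
        x = rng.uniform(0, 1, (4, 3))
        loop = [sum(x[a][b] for a in range(4)) / 4 for b in range(3)]
        assert np.allclose(average_solution(x), loop, atol=1e-12)

    def test_average_of_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            average_solution(np.empty((0, 0)))

    def test_distance_directions_on_reference_cells(self):
        dm = reference_dm()
        psi = average_solution(dm.x)
        pi, ni = distance_matrices(dm.x, psi, dm.beneficial)
        # below-average recall counts as positive (penalized) distance
        assert round(pi[0, 1], 4) == 0.0306  # SRAD recall 0.8774
        # above-average recall counts as negative (rewarded) distance
        assert round(ni[5, 1], 4) == 0.0796  # fused recall 0.9772

    def test_matrix_equal_to_average_gives_zero_distances(self):
        psi = np.array([0.5, 2.0])
        x = np.tile(psi, (3, 1))
        pi, ni = distance_matrices(x, psi, [True, False])
        assert not pi.any() and not ni.any()

    def test_zero_average_rejected(self):
        with pytest.raises(ZeroDivisionError):
            distance_matrices(np.ones((2, 2)), np.array([1.0, 0.0]), [True, True])

    def test_weighted_sums_reference_values(self):
        dm = reference_dm()
        pi, ni = distance_matrices(dm.x, average_solution(dm.x), dm.beneficial)
        spi, sni = weighted_sums(pi, ni, dm.weights)
        assert round(spi[1], 4) == 0.0233  # BH
        assert round(sni[5], 4) == 0.0579  # fused BH+E4-(L+R)

    def test_weighted_sums_of_zero_matrices(self):
        spi, sni = weighted_sums(np.zeros((2, 3)), np.zeros((2, 3)), np.ones(3) / 3)
        assert not spi.any() and not sni.any()

    def test_weight_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weight length"):
            weighted_sums(np.zeros((2, 3)), np.zeros((2, 3)), np.ones(2))

    def test_normalization_conventions(self):
        nspi, nsni = normalize_sums(np.array([0.1, 0.2]), np.array([0.0, 0.0]))
        assert nspi[1] == 1.0  # max-SPI alternative
        assert np.allclose(nsni, 1.0)  # all-zero SNI -> all NSNI = 1
        nspi0, _ = normalize_sums(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        assert not nspi0.any()

    def test_appraisal_endpoints(self):
        assert appraisal(np.zeros(2), np.zeros(2)).tolist() == [0.0, 0.0]
        assert appraisal(np.ones(2), np.ones(2)).tolist() == [1.0, 1.0]

    def test_dense_ranks(self):
        assert rank(np.array([0.3, 0.1, 0.2])).tolist() == [3, 1, 2]
        assert rank(np.array([0.5, 0.5, 0.9]), tol=1e-4).tolist() == [1, 1, 2]


class TestFullChain:
    def test_relaxed_state_chain_reproduces_consistent_cells(self):
        res = run_edas(reference_dm("relaxed"))
        assert np.allclose(res.psi.round(4), [0.9076, 0.9051, 0.8886, 0.8947, 0.9130])
        assert round(res.nsni[0], 4) == pytest.approx(0.7270, abs=2e-4)  # SRAD
        assert res.ranks[5] == 1  # fused BH+E4-(L+R) wins

    def test_stressed_state_chain(self):
        res = run_edas(reference_dm("stressed"))
        assert round(res.sni[5], 4) == 0.0505
        assert res.sni.argmax() == 5
        assert res.ranks[5] == 1

    def test_single_alternative_matrix(self):
        dm = DecisionMatrix(
            x=[[0.9, 0.8]], weights=[0.5, 0.5], beneficial=[True, True], names=("only",)
        )
        res = run_edas(dm)
        assert not res.pi.any() and not res.ni.any()
        assert res.ranks.tolist() == [1]

    def test_random_matrix_matches_loop_oracle(self, rng):
        x = rng.uniform(0.1, 1.0, (5, 4))
        w = rng.dirichlet(np.ones(4))
        beneficial = [True, False, True, True]
        dm = DecisionMatrix(x=x, weights=w, beneficial=beneficial)
        res = run_edas(dm)
        psi, pi, ni, spi, sni, nspi, nsni, lam = loop_edas(x, w, beneficial)
        assert np.allclose(res.psi, psi, atol=1e-10)
        assert np.allclose(res.pi, pi, atol=1e-10)
        assert np.allclose(res.ni, ni, atol=1e-10)
        assert np.allclose(res.spi, spi, atol=1e-10)
        assert np.allclose(res.sni, sni, atol=1e-10)
        assert np.allclose(res.nspi, nspi, atol=1e-10)
        assert np.allclose(res.nsni, nsni, atol=1e-10)
        assert np.allclose(res.lam, lam, atol=1e-10)


matrix_strategy = st.integers(2, 6).flatmap(
    lambda n: st.integers(2, 5).flatmap(
        lambda m: st.lists(
            st.lists(st.floats(0.1, 10.0), min_size=m, max_size=m),
            min_size=n,
            max_size=n,
        )
    )
)


class TestProperties:
    @given(data=matrix_strategy, col_scale=st.floats(0.01, 100.0))
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance_of_criterion_columns(self, data, col_scale):
        x = np.asarray(data)
        m = x.shape[1]
        w = np.full(m, 1.0 / m)
        ben = np.ones(m, dtype=bool)
        scaled = x.copy()
        scaled[:, 0] *= col_scale
        a = run_edas(DecisionMatrix(x=x, weights=w, beneficial=ben))
        b = run_edas(DecisionMatrix(x=scaled, weights=w, beneficial=ben))
        assert np.allclose(a.pi, b.pi, atol=1e-9)
        assert np.allclose(a.ni, b.ni, atol=1e-9)
        assert np.allclose(a.lam, b.lam, atol=1e-9)
        assert np.array_equal(a.ranks, b.ranks)

    @given(data=matrix_strategy)
    @settings(max_examples=60, deadline=None)
    def test_pi_ni_complementarity_and_lambda_bounds(self, data):
        x = np.asarray(data)
        m = x.shape[1]
        res = run_edas(DecisionMatrix(x=x, weights=np.full(m, 1 / m), beneficial=np.ones(m, bool)))
        assert np.allclose(res.pi * res.ni, 0.0)
        assert (res.pi >= 0).all() and (res.ni >= 0).all()
        assert (res.lam >= 0).all() and (res.lam <= 1 + 1e-12).all()

    def test_dominant_alternative_has_zero_spi_and_rank_one(self, rng):
        for _ in range(20):
            x = rng.uniform(0.2, 0.8, (4, 3))
            dominant = x.max(axis=0) + rng.uniform(0.05, 0.2, 3)
            x = np.vstack([x, dominant])
            res = run_edas(
                DecisionMatrix(x=x, weights=np.full(3, 1 / 3), beneficial=np.ones(3, bool))
            )
            assert res.spi[-1] == 0.0
            assert res.ranks[-1] == 1

    def test_duplicating_the_average_row_preserves_order(self, rng):
        """Appending a row equal to the column means leaves psi, hence every
        distance and the relative order of the originals, unchanged."""
        x = rng.uniform(0.2, 1.0, (5, 4))
        w = rng.dirichlet(np.ones(4))
        dm = DecisionMatrix(x=x, weights=w, beneficial=np.ones(4, bool))
        res = run_edas(dm)
        x2 = np.vstack([x, x.mean(axis=0)])
        res2 = run_edas(DecisionMatrix(x=x2, weights=w, beneficial=np.ones(4, bool)))
        order = np.argsort(res.lam)
        order2 = np.argsort(res2.lam[:5])
        assert np.array_equal(order, order2)

    def test_duplicate_alternative_rank_reversal_counterexample(self):
        """Duplicating an arbitrary alternative shifts the column means and
        CAN reverse the order of the others — a documented rank-reversal
        weakness of average-based MCDM.  This regression test pins one
        concrete counterexample so the behaviour is never silently 'fixed'
        into an invariant that the procedure does not actually have."""
        rng = np.random.default_rng(0)
        found = False
        for _ in range(300):
            n, m = int(rng.integers(3, 7)), int(rng.integers(2, 6))
            x = rng.uniform(0.5, 1.0, (n, m))
            w = rng.dirichlet(np.ones(m))
            ben = np.ones(m, bool)
            lam0 = run_edas(DecisionMatrix(x=x, weights=w, beneficial=ben)).lam
            dup = int(rng.integers(n))
            lam1 = run_edas(
                DecisionMatrix(x=np.vstack([x, x[dup]]), weights=w, beneficial=ben)
            ).lam[:n]
            for a in range(n):
                for b in range(n):
                    if lam0[a] < lam0[b] - 1e-9 and lam1[a] > lam1[b] + 1e-9:
                        found = True
        assert found

    def test_weights_not_summing_to_one_warn(self):
        with pytest.warns(UserWarning, match="sum to"):
            DecisionMatrix(
                x=[[1.0, 2.0]], weights=[0.5, 0.6], beneficial=[True, True]
            )

    def test_reference_weights_kept_as_printed_with_optin_renormalization(self):
        dm = reference_dm()
        assert np.allclose(dm.weights, CRITERIA_WEIGHTS)
        assert dm.weights.sum() != 1.0
        renorm = dm.renormalized()
        assert renorm.weights.sum() == pytest.approx(1.0)
        # ranking is insensitive to the overall weight scale
        assert np.array_equal(run_edas(dm).ranks, run_edas(renorm).ranks)
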