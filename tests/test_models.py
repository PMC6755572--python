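"""Estimator correctness: reductions, limits, and oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gknnqsar import (
    ModelParams,
    gknn_estimate,
    knn_arithmetic,
    knn_exponential,
    knn_geometric,
    predict,
)

from conftest import make_dataset


def naive_gknn(A, S, x, y):
    """Direct transcription of the power-mean estimator, no log-domain
    tricks: (sum A^x S^y / sum S^y) ** (1/x)."""
    num = sum(a**x * s**y for a, s in zip(A, S))
    den = sum(s**y for s in S)
    return (num / den) ** (1.0 / x)


def mpmath_gknn(A, S, x, y, dps=60):
    """Arbitrary-precision evaluation of the same formula."""
    import mpmath as mp

    with mp.workdps(dps):
        num = mp.fsum(mp.mpf(a) ** x * mp.mpf(s) ** y for a, s in zip(A, S))
        den = mp.fsum(mp.mpf(s) ** y for s in S)
        return float((num / den) ** (mp.mpf(1) / x))


def random_instance(rng, n_min=3, n_max=20, positive=True):
    n = int(rng.integers(n_min, n_max + 1))
    low = 0.05 if positive else 0.0
    A = rng.uniform(low, 1.0, size=n)
    S = rng.uniform(0.05, 1.0, size=n)
    return A, S


class TestGknnEstimate:
    def test_single_neighbor_identity(self):
        assert gknn_estimate([0.42], [0.3], x=2.7, y=4.0) == pytest.approx(0.42)

    def test_reduces_to_arithmetic_mean(self):
        assert gknn_estimate([0.2, 0.4, 0.9], [0.5, 0.9, 0.1], x=1, y=0) == pytest.approx(0.5)

    def test_similarity_weighted_mean(self):
        assert gknn_estimate([1.0, 0.0], [0.8, 0.2], x=1, y=1) == pytest.approx(0.8)

    def test_large_x_approaches_max(self):
        est = gknn_estimate([0.2, 0.9], [0.5, 0.5], x=50, y=0)
        assert abs(est - 0.9) < 0.05

    def test_x_zero_is_weighted_geometric_mean(self):
        A, S = [0.25, 1.0], [0.5, 0.5]
        assert gknn_estimate(A, S, x=0, y=0) == pytest.approx(0.5)
        assert gknn_estimate([0.0, 0.9], [0.5, 0.5], x=0, y=1) == 0.0

    def test_zero_activity_neighbors_handled(self):
        # 0^x = 0: zero activities drop from the numerator but their
        # similarity weight stays in the denominator
        est = gknn_estimate([0.0, 0.8], [0.5, 0.5], x=2, y=0)
        assert est == pytest.approx((0.8**2 / 2) ** 0.5)

    def test_all_zero_similarity_falls_back_with_warning(self):
        with pytest.warns(RuntimeWarning, match="unweighted"):
            est = gknn_estimate([0.2, 0.6], [0.0, 0.0], x=1, y=2)
        assert est == pytest.approx(0.4)

    def test_naive_oracle_equivalence_moderate_exponents(self, rng):
        """Log-domain path equals the direct formula to 1e-10 for x, y <= 10."""
        grid = [0.1, 0.5, 1.0, 2.0, 5.0, 10.0]
        for _ in range(20):
            A, S = random_instance(rng)
            for x in grid:
                for y in grid:
                    assert gknn_estimate(A, S, x, y) == pytest.approx(
                        naive_gknn(A, S, x, y), abs=1e-10
                    )

    def test_high_precision_oracle_at_extreme_exponents(self, rng):
        """At x = y = 50 the naive float formula under/overflows; the
        log-domain path must match a 60-digit arbitrary-precision oracle."""
        for _ in range(25):
            A, S = random_instance(rng)
            assert gknn_estimate(A, S, 50.0, 50.0) == pytest.approx(
                mpmath_gknn(A, S, 50.0, 50.0), abs=1e-8
            )

    def test_large_y_selects_most_similar_neighbor(self, rng):
        for _ in range(20):
            A, S = random_instance(rng)
            S[int(rng.integers(len(S)))] = 1.0  # unique maximum
            S[S < 1.0] *= 0.8
            est = gknn_estimate(A, S, x=1, y=50)
            assert abs(est - A[np.argmax(S)]) < 0.05

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        st.data(),
        st.sampled_from([0.0, 0.3, 1.0, 3.0, 20.0]),
        st.sampled_from([0.0, 1.0, 7.0]),
    )
    def test_bounded_by_neighbor_activities(self, acts, data, x, y):
        sims = data.draw(
            st.lists(
                st.floats(0.01, 1.0), min_size=len(acts), max_size=len(acts)
            )
        )
        est = gknn_estimate(acts, sims, x, y)
        assert min(acts) - 1e-9 <= est <= max(acts) + 1e-9

    def test_permutation_invariant(self, rng):
        A, S = random_instance(rng)
        perm = rng.permutation(len(A))
        assert gknn_estimate(A, S, 2.5, 3.0) == pytest.approx(
            gknn_estimate(A[perm], S[perm], 2.5, 3.0), abs=1e-12
        )

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            gknn_estimate([0.5], [0.5], x=-1, y=0)
        with pytest.raises(ValueError):
            gknn_estimate([1.5], [0.5], x=1, y=0)
        with pytest.raises(ValueError):
            gknn_estimate([], [], x=1, y=0)


class TestClassicalVariants:
    @pytest.mark.parametrize("acts,expected", [([0.2, 0.4, 0.9], 0.5), ([0.7], 0.7)])
    def test_arithmetic(self, acts, expected):
        assert knn_arithmetic(acts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "acts,expected", [([0.25, 1.0], 0.5), ([0.0, 0.9, 0.9], 0.0), ([0.6], 0.6)]
    )
    def test_geometric(self, acts, expected):
        assert knn_geometric(acts) == pytest.approx(expected)

    def test_exponential_direct_substitution(self):
        # S = [1, 0.5] -> d = [0, 1]; x=1, A=[1, 0] -> e/(e+1)
        est = knn_exponential([1.0, 0.0], [1.0, 0.5], x=1.0)
        assert est == pytest.approx(math.e / (math.e + 1))

    def test_exponential_x_zero_is_arithmetic(self, rng):
        for _ in range(10):
            A, S = random_instance(rng)
            assert knn_exponential(A, S, 0.0) == pytest.approx(knn_arithmetic(A), abs=1e-12)

    def test_exponential_single_neighbor(self):
        assert knn_exponential([0.33], [0.4], x=2.0) == pytest.approx(0.33)

    def test_exponential_all_zero_similarity_fallback(self):
        with pytest.warns(RuntimeWarning):
            est = knn_exponential([0.7, 0.2], [0.0, 0.0], x=1.0)
        assert est == 0.7

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            knn_arithmetic([])
        with pytest.raises(ValueError):
            knn_geometric([])


class TestReductionSweeps:
    """Randomized verification that the general estimator collapses onto
    the classical variants at the documented parameter values."""

    def test_gknn_x1_y0_equals_arithmetic(self, rng):
        for _ in range(100):
            A, S = random_instance(rng, positive=False)
            assert gknn_estimate(A, S, 1.0, 0.0) == pytest.approx(
                knn_arithmetic(A), abs=1e-12
            )

    def test_gknn_x0_y0_equals_geometric(self, rng):
        for _ in range(100):
            A, S = random_instance(rng)
            assert gknn_estimate(A, S, 0.0, 0.0) == pytest.approx(
                knn_geometric(A), abs=1e-10
            )

    def test_k1_returns_neighbor_activity(self, rng):
        for _ in range(100):
            a = float(rng.uniform(0, 1))
            s = float(rng.uniform(0.01, 1))
            x = float(rng.uniform(0.1, 50))
            y = float(rng.uniform(0, 50))
            assert gknn_estimate([a], [s], x, y) == pytest.approx(a, abs=1e-12)


class TestPredict:
    def test_identical_training_chemical(self):
        training = make_dataset([0.9, 0.2], ids=["T0", "T1"])
        query = make_dataset([0.0], ids=["Q"])
        from gknnqsar import SimilarityMatrix

        sim = SimilarityMatrix(
            values=np.array([[1.0, 0.4]]), row_ids=["Q"], col_ids=["T0", "T1"]
        )
        params = ModelParams(family="gknn", k=1, x=1, y=1)
        (pred,) = predict(query, training, params, sim=sim)
        assert pred.estimate == pytest.approx(0.9)
        assert pred.confidence == 1.0

    def test_constant_training_activities(self):
        training = make_dataset([0.3, 0.3, 0.3], ids=["T0", "T1", "T2"])
        query = make_dataset([0.0], ids=["Q"])
        from gknnqsar import SimilarityMatrix

        sim = SimilarityMatrix(
            values=np.array([[0.9, 0.5, 0.2]]), row_ids=["Q"], col_ids=training.ids
        )
        for family in ("gknn", "knn_arithmetic", "knn_exponential"):
            params = ModelParams(family=family, k=3, x=2.0, y=3.0)
            (pred,) = predict(query, training, params, sim=sim)
            assert pred.estimate == pytest.approx(0.3)

    def test_self_excluded_by_id(self, abstract_smooth):
        ds, sm = abstract_smooth
        params = ModelParams(family="gknn", k=3, x=1, y=1)
        preds = predict(ds, ds, params, sim=sm)
        for p, rec in zip(preds, ds):
            assert rec.chem_id not in [n[0] for n in p.neighbors]

    def test_matches_bruteforce_formula(self, smiles_set):
        """Full pipeline equals a literal few-line evaluation of the
        power-mean formula on explicitly sorted neighbors."""
        ds, sm = smiles_set
        x, y, k = 1.5, 2.0, 4
        params = ModelParams(family="gknn", k=k, x=x, y=y)
        preds = predict(ds, ds, params, sim=sm)
        acts = ds.activities()
        for qi, p in enumerate(preds):
            sims = [(sm.values[qi, j], -j) for j in range(len(ds)) if j != qi]
            top = sorted(sims, reverse=True)[:k]
            A = [acts[-j] for _, j in top]
            S = [s for s, _ in top]
            expected = sum(a**x * s**y for a, s in zip(A, S)) / sum(s**y for s in S)
            expected = expected ** (1 / x)
            assert p.estimate == pytest.approx(expected, abs=1e-10)

    def test_deterministic_reruns(self, abstract_smooth):
        ds, sm = abstract_smooth
        params = ModelParams(family="knn_exponential", k=5, x=1.5)
        p1 = predict(ds, ds, params, sim=sm)
        p2 = predict(ds, ds, params, sim=sm)
        assert [(p.chem_id, p.estimate, p.confidence) for p in p1] == [
            (p.chem_id, p.estimate, p.confidence) for p in p2
        ]

    def test_empty_training_rejected(self):
        from gknnqsar import Dataset

        with pytest.raises(ValueError):
            predict(make_dataset([0.5]), Dataset([]), ModelParams())
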