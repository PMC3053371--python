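"""The combined fold-recognition statistic: empirical-CDF tail conventions,
exact hypergeometric upper tail against enumeration and scipy, combination
rules, and the accept/reject decision on constructed rankings."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

from remotethread.formats import SequenceRecord
from remotethread.scoring import (
    ACCEPT_THRESHOLD,
    EmpiricalCDF,
    HypergeomParams,
    ScoringError,
    build_cdf,
    combine,
    combine_fisher,
    hypergeom_upper,
    score_threading,
)
from remotethread.threader import ThreadingHit, ThreadingResult


@pytest.fixture(scope="module")
def normal_cdf():
    return build_cdf(np.random.default_rng(0).standard_normal(100_000))


class TestEmpiricalCDF:
    def test_too_small_background_rejected(self):
        with pytest.raises(ScoringError):
            build_cdf(np.zeros(100))

    def test_median_tail_probability(self, normal_cdf):
        assert normal_cdf.upper_tail(0.0) == pytest.approx(0.5, abs=0.01)

    def test_below_minimum_tail_near_one(self, normal_cdf):
        assert normal_cdf.upper_tail(-10.0) == pytest.approx(1.0, abs=1e-4)

    def test_above_maximum_pseudocounted(self, normal_cdf):
        p = normal_cdf.upper_tail(50.0)
        assert p == 1.0 / (normal_cdf.sample_size + 1)
        assert p > 0

    def test_monotone_nonincreasing_tail(self, normal_cdf):
        zs = np.linspace(-4, 4, 50)
        ps = [normal_cdf.upper_tail(z) for z in zs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def _enumerate_upper(N, n, m, k):
    """Exhaustive oracle: draw every n-subset of N items, the first m of
    which are 'expected'; count draws containing >= k expected items."""
    hits = 0
    total = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in subset if x < m) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_k_zero_is_one(self):
        assert hypergeom_upper(HypergeomParams(N=100, n=10, m=5, k=0)) == 1.0

    def test_worked_example_8_over_120(self):
        p = hypergeom_upper(HypergeomParams(N=10, n=3, m=2, k=2))
        assert p == pytest.approx(8 / 120, abs=1e-12)

    def test_matches_enumeration_on_sampled_small_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(1, 13))
            n = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, m) + 1))
            p = hypergeom_upper(HypergeomParams(N=N, n=n, m=m, k=k))
            assert p == pytest.approx(_enumerate_upper(N, n, m, k), abs=1e-12)

    def test_matches_scipy_at_scale(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            N = int(rng.integers(10, 20000))
            n = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, m) + 1))
            ours = hypergeom_upper(HypergeomParams(N=N, n=n, m=m, k=k))
            ref = float(scipy_hypergeom.sf(k - 1, N, m, n))
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_invalid_params_rejected(self):
        with pytest.raises(ScoringError):
            HypergeomParams(N=10, n=3, m=2, k=3)
        with pytest.raises(ScoringError):
            HypergeomParams(N=10, n=11, m=2, k=1)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(2, 60), st.integers(1, 60), st.integers(1, 60), st.integers(1, 60))
    def test_monotone_in_k_and_m(self, N, n, m, k):
        n, m = min(n, N), min(m, N)
        k = min(k, n, m)
        p_k = hypergeom_upper(HypergeomParams(N=N, n=n, m=m, k=k))
        if k >= 1:
            p_km1 = hypergeom_upper(HypergeomParams(N=N, n=n, m=m, k=k - 1))
            assert p_k <= p_km1 + 1e-12
        if m + 1 <= N:
            p_m1 = hypergeom_upper(HypergeomParams(N=N, n=n, m=m + 1, k=k))
            assert p_m1 >= p_k - 1e-12


class TestCombine:
    def test_identity_at_one(self):
        assert combine(1.0, 1.0) == 1.0

    def test_product_rule_arithmetic(self):
        assert combine(0.01, 0.05) == pytest.approx(5e-4)

    def test_fisher_alternative(self):
        p = combine(0.01, 0.05, method="fisher")
        stat = -2 * (math.log(0.01) + math.log(0.05))
        from scipy.stats import chi2
        assert p == pytest.approx(float(chi2.sf(stat, 4)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoringError):
            combine(0.0, 0.5)
        with pytest.raises(ScoringError):
            combine(0.5, 1.5)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.floats(1e-10, 1.0), st.floats(1e-10, 1.0), st.floats(0.01, 1.0),
           st.sampled_from(["product", "fisher"]))
    def test_monotone_in_both_arguments(self, p1, p2, shrink, method):
        base = combine(p1, p2, method=method)
        assert combine(p1 * shrink, p2, method=method) <= base + 1e-12
        assert combine(p1, p2 * shrink, method=method) <= base + 1e-12


def _ranking(zs_by_id):
    order = sorted(zs_by_id, key=lambda s: (-zs_by_id[s], s))
    hits = tuple(
        ThreadingHit(structure_id=s, zscore=zs_by_id[s], rank=i)
        for i, s in enumerate(order, 1)
    )
    return ThreadingResult(query_id="q", hits=hits, backend="constructed")


class TestScoreThreading:
    def _library_z(self, rng, n):
        return {f"s{i:04d}": float(z) for i, z in enumerate(rng.standard_normal(n))}

    def test_planted_top_structure_accepted(self, normal_cdf):
        rng = np.random.default_rng(2)
        zs = self._library_z(rng, 1000)
        zs["planted"] = 12.0
        fs = score_threading(_ranking(zs), {"planted"}, normal_cdf, window=5)
        assert fs.accepted and fs.p_combined < ACCEPT_THRESHOLD
        assert fs.params.k == 1 and fs.best_expected_z == 12.0

    def test_k_zero_rejected_with_unit_pvalues(self, normal_cdf):
        rng = np.random.default_rng(3)
        zs = self._library_z(rng, 500)
        zs["expected"] = -20.0  # bottom of the ranking
        fs = score_threading(_ranking(zs), {"expected"}, normal_cdf, window=3)
        assert not fs.accepted
        assert fs.p_cdf == fs.p_hyper == fs.p_combined == 1.0
        assert fs.best_expected_z is None

    def test_frequent_fold_at_chance_level_not_accepted(self, normal_cdf):
        """A fold family making up 30% of the library and appearing in the
        top window at its chance proportion is not over-represented."""
        rng = np.random.default_rng(4)
        N, window = 1000, 10
        zs = self._library_z(rng, N)
        ranking = _ranking(zs)
        by_rank = [h.structure_id for h in ranking.hits]
        # exactly 3 of the top 10 expected (the chance proportion for m = 300),
        # sitting at chance positions within the window rather than at its top
        expected = set(by_rank[7:10]) | set(by_rank[window:][:297])
        fs = score_threading(ranking, expected, normal_cdf, window=window)
        assert fs.params == HypergeomParams(N=N, n=window, m=300, k=3)
        assert fs.p_hyper > 0.05
        assert not fs.accepted

    def test_empty_expected_set_rejected(self, normal_cdf):
        rng = np.random.default_rng(5)
        with pytest.raises(ScoringError):
            score_threading(_ranking(self._library_z(rng, 10)), set(), normal_cdf, 2)

    def test_unknown_expected_structure_rejected(self, normal_cdf):
        rng = np.random.default_rng(6)
        with pytest.raises(ScoringError, match="not in library"):
            score_threading(_ranking(self._library_z(rng, 10)), {"nope"}, normal_cdf, 2)

    def test_combined_never_exceeds_either_part_under_product(self, normal_cdf):
        rng = np.random.default_rng(7)
        zs = self._library_z(rng, 300)
        zs["planted"] = 4.0
        fs = score_threading(_ranking(zs), {"planted"}, normal_cdf, window=5)
        if fs.params.k >= 1:
            assert fs.p_combined <= min(fs.p_cdf, fs.p_hyper) + 1e-15
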