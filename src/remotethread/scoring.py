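"""The combined fold-recognition statistic.

Two independent pieces of evidence decide whether the fold expected for a
weak domain hit was truly recognized:

* ``p_cdf`` — the upper-tail probability of the best expected structure's
  threading Z-score under an empirical background distribution of Z-scores
  (pooled from threading runs of random proteins).  This asks "is the score
  itself exceptional?".

* ``p_hyper`` — the upper-tail cumulative hypergeometric probability of
  seeing ``k`` of the ``m`` structures mapped to the expected domain within
  the top ``n`` of all ``N`` ranked structures.  This asks "are the expected
  structures over-represented near the top of the ranking?", and
  discriminates folds that score well merely because they are frequent in
  the library from folds that are genuinely over-represented.

The two combine (by default, their product) into a single p-value; a domain
is accepted when the combined value is at or below 0.001 and at least one
expected structure sits inside the top window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .threader import ThreadingResult

#: Combined-probability acceptance threshold.
ACCEPT_THRESHOLD = 1e-3

#: Minimum background sample size for a usable empirical CDF.
MIN_BACKGROUND = 10_000


class ScoringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# empirical background CDF


class EmpiricalCDF:
    """Right-continuous empirical CDF over a background Z-score sample.

    The upper tail uses an add-one pseudocount,
    ``p(z) = (#background >= z + 1) / (n + 1)``, so a Z-score above every
    background value still gets a strictly positive p-value.
    """

    def __init__(self, background: Sequence[float], source: str = "background"):
        values = np.sort(np.asarray(background, dtype=float))
        if values.size < MIN_BACKGROUND:
            raise ScoringError(
                f"background sample too small ({values.size} < {MIN_BACKGROUND})"
            )
        if not np.isfinite(values).all():
            raise ScoringError("background sample contains non-finite values")
        self._values = values
        self.sample_size = int(values.size)
        self.source = source

    def cdf(self, z: float) -> float:
        """P(background <= z)."""
        idx = np.searchsorted(self._values, z, side="right")
        return float(idx) / self.sample_size

    def upper_tail(self, z: float) -> float:
        """Pseudocounted P(background >= z); always in (0, 1]."""
        idx = np.searchsorted(self._values, z, side="left")
        count_ge = self.sample_size - int(idx)
        return (count_ge + 1) / (self.sample_size + 1)


def build_cdf(background: Sequence[float], source: str = "background") -> EmpiricalCDF:
    return EmpiricalCDF(background, source=source)


# ---------------------------------------------------------------------------
# hypergeometric over-representation


@dataclass(frozen=True)
class HypergeomParams:
    """Sampling-without-replacement parameters of the top-window draw.

    N: all structures threaded; n: size of the top window; m: structures
    mapped to the expected domain; k: expected structures observed inside
    the window.
    """

    N: int
    n: int
    m: int
    k: int

    def __post_init__(self):
        ok = (
            0 <= self.k <= min(self.n, self.m)
            and 0 < self.m <= self.N
            and 0 < self.n <= self.N
        )
        if not ok:
            raise ScoringError(
                f"invalid hypergeometric parameters N={self.N} n={self.n} "
                f"m={self.m} k={self.k}"
            )


def _log_comb(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper(params: HypergeomParams) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N, m, n).

    Computed as a log-gamma-based sum over the upper tail, not a normal or
    binomial approximation.
    """
    N, n, m, k = params.N, params.n, params.m, params.k
    if k == 0:
        return 1.0
    denom = _log_comb(N, n)
    hi = min(n, m)
    terms = []
    for i in range(k, hi + 1):
        if n - i > N - m:  # impossible configuration
            continue
        terms.append(_log_comb(m, i) + _log_comb(N - m, n - i) - denom)
    if not terms:
        return 0.0
    mx = max(terms)
    total = mx + math.log(sum(math.exp(t - mx) for t in terms))
    return float(min(1.0, math.exp(total)))


# ---------------------------------------------------------------------------
# combination


def combine_product(p_cdf: float, p_hyper: float) -> float:
    """Default combination rule: the plain product of the two p-values."""
    return p_cdf * p_hyper


def combine_fisher(p_cdf: float, p_hyper: float) -> float:
    """Fisher's method: chi-square tail of -2(ln p1 + ln p2) on 4 df."""
    stat = -2.0 * (math.log(p_cdf) + math.log(p_hyper))
    return float(chi2.sf(stat, df=4))


COMBINERS: dict[str, Callable[[float, float], float]] = {
    "product": combine_product,
    "fisher": combine_fisher,
}


def combine(p_cdf: float, p_hyper: float, method: str = "product") -> float:
    if not (0.0 < p_cdf <= 1.0 and 0.0 < p_hyper <= 1.0):
        raise ScoringError("p-values must lie in (0, 1]")
    try:
        return COMBINERS[method](p_cdf, p_hyper)
    except KeyError:
        raise ScoringError(f"unknown combination method {method!r}") from None


# ---------------------------------------------------------------------------
# the fold score


@dataclass(frozen=True)
class FoldScore:
    """Accept/reject decision for one threaded domain region."""

    p_cdf: float
    p_hyper: float
    p_combined: float
    accepted: bool
    params: HypergeomParams
    best_expected_z: Optional[float]


def score_threading(
    result: ThreadingResult,
    expected_structures: set[str],
    cdf: EmpiricalCDF,
    window: int,
    threshold: float = ACCEPT_THRESHOLD,
    method: str = "product",
) -> FoldScore:
    """Score a threading ranking against the structures expected for a domain.

    ``k`` counts expected structures inside the top window; ``p_cdf`` is the
    background tail probability of the best-ranked expected structure inside
    the window.  With ``k = 0`` both p-values default to 1 and the domain is
    rejected outright: an expected structure below the window contributes to
    neither statistic.
    """
    if not expected_structures:
        raise ScoringError("expected structure set is empty")
    library_ids = {h.structure_id for h in result.hits}
    unknown = expected_structures - library_ids
    if unknown:
        raise ScoringError(f"expected structures not in library: {sorted(unknown)[:5]}")
    if window > len(result.hits):
        raise ScoringError("window larger than library")
    top = result.hits[:window]
    in_window = [h for h in top if h.structure_id in expected_structures]
    N = len(result.hits)
    n = window
    m = len(expected_structures)
    k = len(in_window)
    params = HypergeomParams(N=N, n=n, m=m, k=k)
    if k == 0:
        return FoldScore(
            p_cdf=1.0,
            p_hyper=1.0,
            p_combined=1.0,
            accepted=False,
            params=params,
            best_expected_z=None,
        )
    best_z = max(h.zscore for h in in_window)
    p_cdf = cdf.upper_tail(best_z)
    p_hyper = hypergeom_upper(params)
    p_combined = combine(p_cdf, p_hyper, method=method)
    return FoldScore(
        p_cdf=p_cdf,
        p_hyper=p_hyper,
        p_combined=p_combined,
        accepted=bool(p_combined <= threshold),
        params=params,
        best_expected_z=best_z,
    )


# ---------------------------------------------------------------------------
# null calibration


def simulate_null_acceptance(
    cdf: EmpiricalCDF,
    background_sampler: Callable[[np.random.Generator, int], np.ndarray],
    library_size: int,
    window: int,
    m: int,
    n_trials: int,
    seed: int,
    threshold: float = ACCEPT_THRESHOLD,
    method: str = "product",
) -> float:
    """Fraction of null scorings accepted at the combined threshold.

    Null model: each of the ``m`` expected structures receives an independent
    Z-score drawn from the background model, i.e. the expected set is placed
    uniformly at random within a library-sized ranking.  The rank of an
    expected Z among the other ``library_size - m`` background draws is
    sampled directly from its tail probability (binomial), avoiding the
    construction of full rankings, and the accept decision reuses the exact
    statistics of :func:`score_threading`.
    """
    rng = np.random.default_rng(seed)
    accepted = 0
    others = library_size - m
    for _ in range(n_trials):
        zs = np.asarray(background_sampler(rng, m), dtype=float)
        # rank of each expected z among the `others` background structures
        tails = np.array([1.0 - cdf.cdf(z) for z in zs])
        ranks = 1 + rng.binomial(others, tails)
        # account for expected structures outranking one another
        order = np.argsort(-zs)
        for extra, idx in enumerate(order):
            ranks[idx] += sum(1 for j in order[:extra] if ranks[j] <= ranks[idx])
        in_window = ranks <= window
        k = int(in_window.sum())
        params = HypergeomParams(N=library_size, n=window, m=m, k=k)
        if k == 0:
            continue
        best_z = float(zs[in_window].max())
        p = combine(cdf.upper_tail(best_z), hypergeom_upper(params), method=method)
        if p <= threshold:
            accepted += 1
    return accepted / n_trials
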