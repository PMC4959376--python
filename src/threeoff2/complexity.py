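"""MDL/BIC and factorized NML model-complexity terms.

The complexity k_{x;y|{u}} is the log-ratio of maximum-likelihood
normalization constants between a model with the edge xy and the simpler model
in which x and y are separated by {u}.  Two scores are provided:

* ``mdl``: the BIC/MDL penalty (1/2)(r_x-1)(r_y-1) prod_i r_{u_i} ln N, the
  large-N Laplace limit of NML;
* ``nml``: the factorized, xy-symmetrized normalized-maximum-likelihood
  penalty built from the universal multinomial normalization constant C^r_n.

C^r_n is computed in log-space: the exact binomial sum for r=2 up to a
switch-over sample size (default 1000), the Szpankowski asymptotic expansion
above it, and the linear-time recursion

    C^r_n = C^{r-1}_n + n/(r-2) C^{r-2}_n      (r >= 3)

for more levels.  All values are natural-log scaled (nats).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .dataset import CategoricalDataset

__all__ = [
    "ComplexityValue",
    "LogMultinomialCache",
    "log_multinomial_constant",
    "mdl_pair_complexity",
    "nml_pair_complexity",
    "pair_complexity",
    "three_point_complexity",
]


@dataclass(frozen=True)
class ComplexityValue:
    value: float
    score_kind: str  # "mdl" | "nml"

    def __float__(self) -> float:
        return self.value


def _log_c2_exact(n: int) -> float:
    """log C^2_n by the exact binomial sum, evaluated with log-sum-exp."""
    if n == 0:
        return 0.0
    h = np.arange(n + 1)
    log_binom = gammaln(n + 1) - gammaln(h + 1) - gammaln(n - h + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(h > 0, h * (np.log(h) - np.log(n)), 0.0)
        t2 = np.where(n - h > 0, (n - h) * (np.log(n - h) - np.log(n)), 0.0)
    return float(logsumexp(log_binom + t1 + t2))


def _log_c2_szpankowski(n: int) -> float:
    """Asymptotic expansion of log C^2_n, accurate to O(n^-3/2); used for large n."""
    return float(
        0.5 * np.log(n * np.pi / 2.0)
        + np.sqrt(8.0 / (9.0 * n * np.pi))
        + (3.0 * np.pi - 16.0) / (36.0 * n * np.pi)
    )


class LogMultinomialCache:
    """Memoized log C^r_n values.

    ``switchover`` is the sample size above which the exact r=2 sum is
    replaced by the Szpankowski approximation (the sum is O(n) per value and
    the expansion is accurate well below 0.1 % there).
    """

    def __init__(self, switchover: int = 1000):
        self.switchover = int(switchover)
        self._memo: dict[tuple[int, int], float] = {}

    def log_c(self, n: int, r: int) -> float:
        n, r = int(n), int(r)
        if n < 0 or r < 1:
            raise ValueError("need n >= 0 and r >= 1")
        if n == 0 or r == 1:
            return 0.0
        key = (n, r)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        if r == 2:
            value = _log_c2_exact(n) if n <= self.switchover else _log_c2_szpankowski(n)
        else:
            # recursion in log-space from C^1_n and C^2_n upward
            prev2, prev1 = 0.0, self.log_c(n, 2)
            for rr in range(3, r + 1):
                cur = np.logaddexp(prev1, np.log(n / (rr - 2.0)) + prev2)
                self._memo.setdefault((n, rr), float(cur))
                prev2, prev1 = prev1, cur
            value = prev1
        value = float(value)
        self._memo[key] = value
        return value


_DEFAULT_CACHE = LogMultinomialCache()


def log_multinomial_constant(n: int, r: int, cache: LogMultinomialCache | None = None) -> float:
    """log of the universal multinomial normalization constant C^r_n (nats)."""
    return (cache or _DEFAULT_CACHE).log_c(n, r)


def mdl_pair_complexity(r_x: int, r_y: int, r_u=(), N: int = None) -> ComplexityValue:
    """MDL/BIC pair complexity (1/2)(r_x-1)(r_y-1) prod_i r_{u_i} ln N."""
    if N is None or N < 2:
        raise ValueError("MDL complexity needs N >= 2")
    value = 0.5 * (r_x - 1) * (r_y - 1) * float(np.prod(list(r_u))) * np.log(N)
    return ComplexityValue(float(value), "mdl")


def nml_pair_complexity(
    data: CategoricalDataset, x: int, y: int, u=(), cache: LogMultinomialCache | None = None
) -> ComplexityValue:
    """Factorized, xy-symmetrized NML pair complexity.

    Sums, over the observed joint states j' of the conditioning set {u}:

        (1/2) [ sum_{k_x} log C^{r_y}_{N_{k_x j'}} - log C^{r_y}_{N_{j'}}
              + sum_{k_y} log C^{r_x}_{N_{k_y j'}} - log C^{r_x}_{N_{j'}} ]

    Unobserved states contribute log C^r_0 = 0 exactly, so iterating over the
    observed states only is lossless.
    """
    u = list(u)
    if x == y or x in u or y in u:
        raise ValueError("x, y and the conditioning set must be disjoint")
    cache = cache or _DEFAULT_CACHE
    r_x, r_y = int(data.levels[x]), int(data.levels[y])

    u_codes, n_u_states = data.joint_codes(u)
    nj = np.bincount(u_codes)  # N_{j'}
    x_codes = data.values[:, x] * nj.size + u_codes  # joint (x, u) state
    n_xj = np.bincount(x_codes, minlength=r_x * nj.size)
    y_codes = data.values[:, y] * nj.size + u_codes
    n_yj = np.bincount(y_codes, minlength=r_y * nj.size)

    total = 0.0
    for n in n_xj[n_xj > 0]:
        total += cache.log_c(int(n), r_y)
    for n in n_yj[n_yj > 0]:
        total += cache.log_c(int(n), r_x)
    for n in nj[nj > 0]:
        total -= cache.log_c(int(n), r_y) + cache.log_c(int(n), r_x)
    return ComplexityValue(0.5 * total, "nml")


def pair_complexity(
    data: CategoricalDataset,
    x: int,
    y: int,
    u=(),
    score_kind: str = "nml",
    cache: LogMultinomialCache | None = None,
) -> ComplexityValue:
    """Dispatch on score kind; {u} enters MDL only through its level counts."""
    if score_kind == "mdl":
        r_u = [int(data.levels[v]) for v in u]
        return mdl_pair_complexity(int(data.levels[x]), int(data.levels[y]), r_u, data.n_samples)
    if score_kind == "nml":
        return nml_pair_complexity(data, x, y, u, cache)
    raise ValueError(f"unknown score kind {score_kind!r}")


def three_point_complexity(
    data: CategoricalDataset,
    x: int,
    y: int,
    z: int,
    u=(),
    score_kind: str = "nml",
    cache: LogMultinomialCache | None = None,
) -> ComplexityValue:
    """k_{x;y;z|{u}} = k_{x;y|{u},z} - k_{x;y|{u}}; positive when all r >= 2."""
    u = list(u)
    big = pair_complexity(data, x, y, u + [z], score_kind, cache)
    small = pair_complexity(data, x, y, u, score_kind, cache)
    return ComplexityValue(big.value - small.value, score_kind)
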