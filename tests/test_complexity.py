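import math
from itertools import combinations_with_replacement

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from threeoff2.complexity import (
    LogMultinomialCache,
    log_multinomial_constant,
    mdl_pair_complexity,
    nml_pair_complexity,
    three_point_complexity,
)

from conftest import make_dataset, random_dataset


def brute_force_log_c(n: int, r: int) -> float:
    """Independent oracle: explicit sum over all partitions l1+...+lr = n."""
    if n == 0 or r == 1:
        return 0.0

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    terms = []
    for comp in compositions(n, r):
        log_multi = gammaln(n + 1) - sum(gammaln(l + 1) for l in comp)
        log_prob = sum(l * math.log(l / n) for l in comp if l > 0)
        terms.append(log_multi + log_prob)
    return float(logsumexp(terms))


class TestLogMultinomialConstant:
    def test_boundary_constants(self):
        assert log_multinomial_constant(0, 5) == 0.0
        assert log_multinomial_constant(7, 1) == 0.0

    def test_tiny_binary_case(self):
        assert log_multinomial_constant(1, 2) == pytest.approx(math.log(2), abs=1e-12)

    def test_small_ternary_case(self):
        assert log_multinomial_constant(2, 3) == pytest.approx(math.log(4.5), abs=1e-12)

    @pytest.mark.parametrize("r", [2, 3, 4, 5])
    def test_matches_brute_force_partition_sum(self, r):
        for n in range(1, 13):
            assert log_multinomial_constant(n, r) == pytest.approx(
                brute_force_log_c(n, r), abs=1e-9
            )

    @pytest.mark.parametrize("n", [5, 37, 200, 1000])
    def test_recursion_consistency(self, n):
        # C^r_n = C^{r-1}_n + n/(r-2) C^{r-2}_n for r >= 3
        for r in range(3, 7):
            lhs = log_multinomial_constant(n, r)
            rhs = np.logaddexp(
                log_multinomial_constant(n, r - 1),
                math.log(n / (r - 2)) + log_multinomial_constant(n, r - 2),
            )
            assert lhs == pytest.approx(float(rhs), rel=1e-12)

    def test_szpankowski_accuracy_above_switchover(self):
        exact_cache = LogMultinomialCache(switchover=10**9)
        approx_cache = LogMultinomialCache(switchover=0)
        for n in (1000, 1500, 2500, 5000):
            exact = math.exp(exact_cache.log_c(n, 2))
            approx = math.exp(approx_cache.log_c(n, 2))
            assert abs(exact - approx) / exact < 1e-3

    def test_monotone_in_n_and_r(self):
        cache = LogMultinomialCache()
        vals_n = [cache.log_c(n, 3) for n in range(0, 50, 5)]
        assert all(a <= b for a, b in zip(vals_n, vals_n[1:]))
        vals_r = [cache.log_c(20, r) for r in range(1, 7)]
        assert all(a <= b for a, b in zip(vals_r, vals_r[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            log_multinomial_constant(-1, 2)
        with pytest.raises(ValueError):
            log_multinomial_constant(3, 0)


class TestMdlComplexity:
    def test_binary_pair(self):
        v = mdl_pair_complexity(2, 2, (), 100)
        assert v.value == pytest.approx(0.5 * math.log(100), abs=1e-12)

    def test_conditioning_multiplies_by_levels(self):
        v = mdl_pair_complexity(2, 2, (3,), 100)
        assert v.value == pytest.approx(1.5 * math.log(100), abs=1e-12)

    def test_constant_variable_is_free(self):
        assert mdl_pair_complexity(1, 4, (2, 2), 50).value == 0.0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            mdl_pair_complexity(2, 2, (), 1)


class TestNmlComplexity:
    def test_xy_symmetry(self, rng):
        data = random_dataset(rng, 50, 4)
        a = nml_pair_complexity(data, 0, 1, [2, 3]).value
        b = nml_pair_complexity(data, 1, 0, [2, 3]).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_hand_computed_unconditional_case(self):
        # 10 samples: x has counts (6, 4), y has counts (7, 3)
        data = make_dataset({"x": [0] * 6 + [1] * 4, "y": [0] * 7 + [1] * 3})
        c = brute_force_log_c
        expected = 0.5 * (
            (c(6, 2) + c(4, 2) - c(10, 2)) + (c(7, 2) + c(3, 2) - c(10, 2))
        )
        assert nml_pair_complexity(data, 0, 1).value == pytest.approx(expected, abs=1e-9)

    def test_hand_computed_conditional_case(self, rng):
        # split by a binary u: each stratum contributes its own normalization
        data = random_dataset(rng, 24, 3)
        u = 2
        got = nml_pair_complexity(data, 0, 1, [u]).value
        expected = 0.0
        c = brute_force_log_c
        for state in range(int(data.levels[u])):
            mask = data.values[:, u] == state
            nj = int(mask.sum())
            if nj == 0:
                continue
            rx, ry = int(data.levels[0]), int(data.levels[1])
            nx = np.bincount(data.values[mask, 0], minlength=rx)
            ny = np.bincount(data.values[mask, 1], minlength=ry)
            expected += 0.5 * (
                sum(c(int(k), ry) for k in nx)
                - c(nj, ry)
                + sum(c(int(k), rx) for k in ny)
                - c(nj, rx)
            )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_sublinear_growth_and_mdl_limit(self, rng):
        base = random_dataset(rng, 40, 2)
        ratios = []
        for dup in (1, 25, 100):
            data = make_dataset(
                {
                    n: np.tile(base.values[:, j], dup)
                    for j, n in enumerate(base.variable_names)
                }
            )
            k_nml = nml_pair_complexity(data, 0, 1).value
            k_mdl = mdl_pair_complexity(
                int(data.levels[0]), int(data.levels[1]), (), data.n_samples
            ).value
            ratios.append(k_nml / k_mdl)
        # complexity grows sublinearly in N: the NML/MDL ratio approaches O(1)
        assert abs(ratios[-1] - 1.0) < abs(ratios[0] - 1.0)
        assert 0.3 < ratios[-1] < 1.5


class TestThreePointComplexity:
    def test_mdl_binary_triple(self):
        data = make_dataset({"x": [0, 1] * 50, "y": [0, 1] * 50, "z": [0, 1] * 50})
        v = three_point_complexity(data, 0, 1, 2, score_kind="mdl")
        assert v.value == pytest.approx(0.5 * math.log(100), abs=1e-12)

    def test_constant_z_contributes_nothing_mdl(self):
        data = make_dataset({"x": [0, 1] * 10, "y": [0, 1] * 10, "z": [0] * 20})
        assert three_point_complexity(data, 0, 1, 2, score_kind="mdl").value == 0.0

    def test_nml_positive_on_random_data(self, rng):
        for _ in range(10):
            data = random_dataset(rng, 50, 3)
            v = three_point_complexity(data, 0, 1, 2, score_kind="nml").value
            assert v > 0.0
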