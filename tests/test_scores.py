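import math

import numpy as np
import pytest
from scipy.special import expit

from threeoff2.complexity import pair_complexity, three_point_complexity
from threeoff2.infotheory import (
    conditional_mutual_information,
    three_point_information,
)
from threeoff2.scores import (
    best_contributor,
    contribution_score,
    prob_base,
    prob_non_v,
    resolve_rank_mode,
    shifted_information,
)
from threeoff2.simulate import fixtures, sample

from conftest import make_dataset, random_dataset


def test_auto_rank_resolution():
    assert resolve_rank_mode("auto", "nml") == "shifted"
    assert resolve_rank_mode("auto", "mdl") == "raw"
    with pytest.raises(ValueError):
        resolve_rank_mode("bogus", "nml")


class TestShiftedInformation:
    def test_independent_pair_is_negative(self, rng):
        x = rng.integers(0, 2, 500)
        y = rng.integers(0, 2, 500)
        data = make_dataset({"x": x, "y": y})
        for score in ("nml", "mdl"):
            i2s, _ = shifted_information(data, 0, 1, score_kind=score)
            assert i2s < 0  # complexity dominates a null dependence

    def test_identical_pair_mdl_closed_form(self):
        col = [0, 1] * 500
        data = make_dataset({"x": col, "y": col})
        i2s, _ = shifted_information(data, 0, 1, score_kind="mdl")
        assert i2s == pytest.approx(math.log(2) - math.log(1000) / 2000, abs=1e-12)

    def test_constant_variable_shift_free_mdl(self):
        data = make_dataset({"x": [0, 1] * 20, "y": [0] * 40})
        i2s, _ = shifted_information(data, 0, 1, score_kind="mdl")
        assert i2s == conditional_mutual_information(data, 0, 1).value

    def test_three_point_shift_adds_complexity(self, rng):
        data = random_dataset(rng, 80, 3)
        _, i3s = shifted_information(data, 0, 1, 2, score_kind="nml")
        i3 = three_point_information(data, 0, 1, 2).value
        k3 = three_point_complexity(data, 0, 1, 2, score_kind="nml").value
        assert i3s == pytest.approx(i3 + k3 / data.n_samples, abs=1e-12)


class TestProbNonV:
    def test_logistic_of_shifted_info(self, rng):
        data = random_dataset(rng, 60, 3)
        _, i3s = shifted_information(data, 0, 1, 2, score_kind="nml")
        assert prob_non_v(data, 0, 1, 2) == pytest.approx(
            float(expit(data.n_samples * i3s)), abs=1e-12
        )

    def test_raw_mode_matches_likelihood_ratio(self, rng):
        # with u = {} and raw information, P_nv = L_nv / (L_nv + L_v)
        # where L_v / L_nv = exp(-N I(x;y;z))
        data = random_dataset(rng, 40, 3)
        i3 = three_point_information(data, 0, 1, 2).value
        ratio = math.exp(-data.n_samples * i3)
        expected = 1.0 / (1.0 + ratio)
        assert prob_non_v(data, 0, 1, 2, rank_mode="raw") == pytest.approx(
            expected, abs=1e-12
        )

    def test_xor_triple_is_v_structure_certain(self, xor_dataset):
        big = make_dataset(
            {
                n: np.tile(xor_dataset.values[:, j], 625)
                for j, n in enumerate(xor_dataset.variable_names)
            }
        )
        assert prob_non_v(big, 0, 1, 2) < 1e-6

    def test_monotone_in_shifted_info(self, rng):
        # across random triples, p_nv orders exactly as I3_shifted
        rows = []
        for _ in range(15):
            data = random_dataset(rng, 50, 3)
            _, i3s = shifted_information(data, 0, 1, 2, score_kind="nml")
            rows.append((data.n_samples * i3s, prob_non_v(data, 0, 1, 2)))
        rows.sort()
        probs = [p for _, p in rows]
        assert probs == sorted(probs)


class TestProbBase:
    def test_normalization(self, rng):
        for _ in range(10):
            data = random_dataset(rng, 50, 4)
            u = [3]
            total = (
                prob_base(data, 0, 1, 2, u)
                + prob_base(data, 0, 2, 1, u)
                + prob_base(data, 1, 2, 0, u)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_weakest_pair_wins(self):
        data = sample(fixtures()["chain"], 5000, seed=2)
        x, z, y = (data.index_of(n) for n in ("x", "z", "y"))
        # I(x;y) is the smallest pairwise information on a chain
        assert prob_base(data, x, y, z) > max(
            prob_base(data, x, z, y), prob_base(data, z, y, x)
        )

    def test_dominant_base_limit(self):
        # collider: I(x;y) ~ 0 while both parents carry signal into z,
        # so the xy base probability approaches 1 at large N
        data = sample(fixtures()["v_structure"], 5000, seed=4)
        x, y, z = (data.index_of(n) for n in ("x", "y", "z"))
        assert prob_base(data, x, y, z) > 0.99


class TestContributionScore:
    def test_lower_bound_is_exact_min(self, rng):
        for _ in range(10):
            data = random_dataset(rng, 50, 4)
            ts = contribution_score(data, 0, 1, 2, [3])
            assert ts.s_lb == min(ts.p_nv, ts.p_base)
            assert 0.0 <= ts.s_lb <= 1.0

    def test_xor_contributor_rejected(self, xor_dataset):
        big = make_dataset(
            {
                n: np.tile(xor_dataset.values[:, j], 625)
                for j, n in enumerate(xor_dataset.variable_names)
            }
        )
        ts = contribution_score(big, 0, 1, 2)
        assert ts.s_lb < 0.5  # z is a collider, not an indirect path


class TestBestContributor:
    def test_empty_candidates(self, rng):
        data = random_dataset(rng, 30, 2)
        assert best_contributor(data, 0, 1, candidates=()) == (None, 0.0)

    def test_chain_middle_selected(self):
        data = sample(fixtures()["chain"], 5000, seed=1)
        x, z, y = (data.index_of(n) for n in ("x", "z", "y"))
        zstar, rank = best_contributor(data, x, y, candidates=[z])
        assert zstar == z
        assert rank > 0.5

    def test_noise_node_loses_to_chain_middle(self):
        data = sample(fixtures()["chain"], 5000, seed=1)
        rng = np.random.default_rng(99)
        cols = {n: data.values[:, j] for j, n in enumerate(data.variable_names)}
        cols["noise"] = rng.integers(0, 2, data.n_samples)
        data2 = make_dataset(cols)
        x, z, y, w = (data2.index_of(n) for n in ("x", "z", "y", "noise"))
        zstar, _ = best_contributor(data2, x, y, candidates=[z, w])
        assert zstar == z

    def test_collider_candidate_ineligible(self, xor_dataset):
        big = make_dataset(
            {
                n: np.tile(xor_dataset.values[:, j], 625)
                for j, n in enumerate(xor_dataset.variable_names)
            }
        )
        zstar, rank = best_contributor(big, 0, 1, candidates=[2])
        assert zstar is None and rank == 0.0
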