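"""Trajectory metrics and the statistical comparisons built on them."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filoguide import (alignment_angle, angular_histogram, compare_groups,
                       tortuosity)


class TestTortuosity:
    def test_straight_path_is_exactly_one(self):
        assert tortuosity([(0, 0), (1, 0), (2, 0)]) == 1.0

    def test_hand_trigonometry_oracle(self):
        # (0,0) -> (1,0) -> (2,1): path 1 + sqrt(2), chord sqrt(5)
        assert tortuosity([(0, 0), (1, 0), (2, 1)]) == pytest.approx(
            (1 + math.sqrt(2)) / math.sqrt(5))

    def test_semicircle_limit(self):
        t = np.linspace(0, math.pi, 2001)
        path = np.column_stack([np.cos(math.pi - t), np.sin(t)])
        assert tortuosity(path) == pytest.approx(math.pi / 2, abs=1e-5)

    @given(angle=st.floats(0, 2 * math.pi), scale=st.floats(0.01, 100),
           tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    @settings(derandomize=True)
    def test_invariant_to_rigid_motion_and_scaling(self, angle, scale, tx, ty):
        base = np.array([(0, 0), (1, 0.2), (2.5, -0.3), (4, 1)], dtype=float)
        R = np.array([[math.cos(angle), -math.sin(angle)],
                      [math.sin(angle), math.cos(angle)]])
        moved = scale * base @ R.T + [tx, ty]
        assert tortuosity(moved) == pytest.approx(tortuosity(base),
                                                  rel=1e-9)

    def test_degenerate_inputs_signalled(self):
        with pytest.raises(ValueError):
            tortuosity([(0, 0)])
        with pytest.raises(ValueError):
            tortuosity([(0, 0), (1, 0), (0, 0)])   # coincident endpoints


class TestAlignmentAngle:
    @pytest.mark.parametrize("chord_angle,expected",
                             [(0, 0), (90, 90), (135, 45), (170, 10),
                              (-30, 30)])
    def test_axis_folding(self, chord_angle, expected):
        a = math.radians(chord_angle)
        path = [(0, 0), (math.cos(a), math.sin(a))]
        assert alignment_angle(path, (1, 0)) == pytest.approx(expected,
                                                              abs=1e-9)

    @given(tx=st.floats(-100, 100), ty=st.floats(-100, 100),
           flip=st.booleans())
    @settings(derandomize=True)
    def test_translation_and_axis_flip_invariance(self, tx, ty, flip):
        path = np.array([(0, 0), (3, 1), (5, 4)], dtype=float)
        axis = np.array([-1.0, 0.0]) if flip else np.array([1.0, 0.0])
        assert alignment_angle(path + [tx, ty], axis) == pytest.approx(
            alignment_angle(path, (1, 0)), abs=1e-9)

    def test_zero_chord_signalled(self):
        with pytest.raises(ValueError):
            alignment_angle([(1, 1), (1, 1)], (1, 0))


class TestAngularHistogram:
    def test_single_bin_mass(self):
        h = angular_histogram([5.0] * 20, 10.0)
        assert h[0] == 100.0 and h[1:].sum() == 0.0

    def test_uniform_grid_counting_oracle(self):
        h = angular_histogram(np.arange(90, dtype=float), 10.0)
        np.testing.assert_allclose(h, 100.0 / 9.0)

    def test_boundary_goes_to_upper_bin(self):
        h = angular_histogram([10.0], 10.0)
        assert h[1] == 100.0

    def test_final_bin_closed_at_ninety(self):
        h = angular_histogram([90.0], 10.0)
        assert h[-1] == 100.0

    @given(st.lists(st.floats(0, 90), min_size=1, max_size=60))
    @settings(derandomize=True)
    def test_sums_to_hundred_and_permutation_invariant(self, angles):
        h = angular_histogram(angles, 15.0)
        assert h.sum() == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(
            h, angular_histogram(list(reversed(angles)), 15.0))

    def test_bad_inputs_signalled(self):
        with pytest.raises(ValueError):
            angular_histogram([], 10.0)
        with pytest.raises(ValueError):
            angular_histogram([5.0], 7.0)


def _welch_oracle(a, b):
    """Welch statistic and two-sided p from the textbook formulae."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy.stats import t as tdist
    return t, 2 * tdist.sf(abs(t), df)


def _rank_sum_exact_p(a, b):
    """Two-sided rank-sum p by exhaustive enumeration of labelings."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n = len(a)
    w_obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestCompareGroups:
    def test_identical_permuted_samples(self):
        a = [3.0, 1.0, 4.0, 1.5, 9.0]
        res = compare_groups(a, list(reversed(a)), test="welch_t")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.shapiro_a is not None

    def test_welch_matches_textbook_oracle(self):
        a = [27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1]
        b = [27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0]
        t_o, p_o = _welch_oracle(a, b)
        res = compare_groups(a, b, test="welch_t")
        assert res.statistic == pytest.approx(t_o, abs=1e-6)
        assert res.p_value == pytest.approx(p_o, abs=1e-6)

    @pytest.mark.parametrize("n,m", [(4, 4), (5, 6), (8, 7)])
    def test_wilcoxon_matches_exact_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(1.0, 1.0, m)
        res = compare_groups(a, b, test="wilcoxon_rank_sum")
        assert res.p_value == pytest.approx(_rank_sum_exact_p(a, b),
                                            abs=1e-9)

    def test_separated_samples_reach_minimal_p(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0]
        res = compare_groups(a, b, test="wilcoxon_rank_sum")
        assert res.p_value == pytest.approx(2.0 / math.comb(8, 4), abs=1e-12)

    def test_degenerate_and_small_samples_signalled(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], test="welch_t")
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
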