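"""P*, censoring, depth integration, mixed-layer depth, and the association screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from n2fix.hydro import (AnalyteLimits, association_screen, censor_analyte,
                         depth_integrate, mann_whitney, mixed_layer_depth,
                         p_star, redfield_c_equivalent, spearman_association)


class TestPStar:
    @pytest.mark.parametrize("po4, no3no2, expected", [
        (0.88, 9.82, 0.27),   # printed survey row, Stn 1 DCM
        (0.64, 9.05, 0.07),   # printed survey row, Stn 2 DCM
        (0.0, 0.0, 0.0),
    ])
    def test_values(self, po4, no3no2, expected):
        assert round(p_star(po4, no3no2), 2) == pytest.approx(expected)

    def test_may_be_negative_and_propagates_nan(self):
        assert p_star(0.05, 2.0) < 0
        assert math.isnan(p_star(float("nan"), 1.0))

    @given(st.floats(0, 3), st.floats(0, 40), st.floats(0, 3), st.floats(0, 40))
    @settings(derandomize=True)
    def test_linearity(self, p1, n1, p2, n2):
        assert p_star(p1 + p2, n1 + n2) == pytest.approx(
            p_star(p1, n1) + p_star(p2, n2), abs=1e-9)


def test_censor_analyte_flags_never_silently_zero():
    lim = AnalyteLimits("no3no2", lod=0.01, loq=0.04)
    assert censor_analyte(0.005, lim) == (0.0, "BDL")
    assert censor_analyte(0.02, lim) == (0.02, "DNQ")
    assert censor_analyte(0.5, lim) == (0.5, "quantified")
    v, s = censor_analyte(float("nan"), lim)
    assert math.isnan(v) and s == "missing"


class TestDepthIntegrate:
    def test_constant_profile_rectangle(self):
        # 5 nmol l^-1 d^-1 over 0-100 m -> 500 umol m^-2 d^-1
        assert depth_integrate([2, 50, 100], [5.0, 5.0, 5.0]) == \
            pytest.approx(500.0)

    def test_linear_profile_trapezoid(self):
        assert depth_integrate([0, 100], [10.0, 0.0]) == pytest.approx(500.0)

    def test_sort_invariance(self):
        a = depth_integrate([10, 2, 50], [3.0, 6.0, 1.0])
        b = depth_integrate([2, 10, 50], [6.0, 3.0, 1.0])
        assert a == pytest.approx(b)

    def test_additive_over_contiguous_intervals(self):
        d = [0, 10, 30, 60]
        v = [4.0, 3.0, 2.0, 1.0]
        whole = depth_integrate(d, v)
        upper = depth_integrate(d, v, z_max=30)
        lower = depth_integrate([30, 60], [2.0, 1.0], extend_surface=False)
        assert whole == pytest.approx(upper + lower)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(derandomize=True)
    def test_homogeneous_degree_one(self, scale):
        d = [2, 20, 80]
        v = np.array([5.0, 2.0, 0.5])
        assert depth_integrate(d, scale * v) == \
            pytest.approx(scale * depth_integrate(d, v))

    def test_single_depth_rejected(self):
        with pytest.raises(ValueError):
            depth_integrate([10], [5.0])

    def test_truncation_and_extension(self):
        d, v = [0, 100], [10.0, 0.0]
        assert depth_integrate(d, v, z_max=50) == pytest.approx(375.0)
        assert depth_integrate([0, 50], [2.0, 2.0], z_max=100) == \
            pytest.approx(200.0)  # constant-extrapolated below deepest


class TestMixedLayerDepth:
    def test_uniform_profile_flagged(self):
        mld, flag = mixed_layer_depth([2, 10, 50], [25.0, 25.0, 25.0])
        assert mld == 50.0 and flag == "unstratified"

    def test_two_layer_jump(self):
        # density jump of 0.5 between 20 and 21 m; threshold 0.125 inside it
        mld, flag = mixed_layer_depth([2, 10, 20, 21, 50],
                                      [25.0, 25.0, 25.0, 25.5, 25.6])
        assert flag == "ok"
        assert 20.0 < mld < 21.0
        # crossing at 20 + (0.125/0.5) * 1 m
        assert mld == pytest.approx(20.25)

    def test_threshold_larger_than_range(self):
        mld, flag = mixed_layer_depth([2, 30], [25.0, 25.05], threshold=0.125)
        assert mld == 30.0 and flag == "unstratified"

    def test_temperature_criterion_absolute_deviation(self):
        mld, flag = mixed_layer_depth([2, 10, 40], [18.0, 17.9, 14.0],
                                      threshold=0.2, criterion="temperature")
        assert flag == "ok" and 10 < mld < 40


def test_redfield_c_equivalent():
    assert redfield_c_equivalent(0.0) == 0.0
    assert redfield_c_equivalent(16.0) == pytest.approx(106.0)
    assert redfield_c_equivalent(195.0) == pytest.approx(1291.9, abs=0.1)


def _exact_spearman_p(x, y):
    """Brute-force permutation null for |rho|, average ranks for ties."""
    def rho(a, b):
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        return np.corrcoef(ra, rb)[0, 1]
    obs = abs(rho(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(rho(x, perm)) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestSpearman:
    def test_perfect_monotone(self):
        r, _ = spearman_association([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)
        r, _ = spearman_association([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_derived_example_with_enumeration_oracle(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        r, p = spearman_association(x, y)
        assert r == pytest.approx(0.6)
        assert p == pytest.approx(_exact_spearman_p(x, y))

    @pytest.mark.parametrize("y", [
        [3, 1, 2, 5, 4],
        [2, 2, 1, 4, 3],          # ties
        [5, 4, 3, 2, 1],
        [1, 3, 2, 6, 5, 4],
    ])
    def test_exact_p_matches_enumeration(self, y):
        x = list(range(1, len(y) + 1))
        _, p = spearman_association(x, y)
        assert p == pytest.approx(_exact_spearman_p(x, y))

    def test_constant_variable_reported_missing(self):
        r, p = spearman_association([1, 2, 3], [5, 5, 5])
        assert math.isnan(r) and math.isnan(p)

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r, p = spearman_association(x, y)
        rs, ps = stats.spearmanr(x, y)
        assert r == pytest.approx(rs) and p == pytest.approx(ps)


def _u_statistic(a, b):
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


def _exact_mwu_p(a, b):
    """Enumeration oracle: two-sided p = 2*min one-sided tail, capped at 1."""
    pooled = list(a) + list(b)
    n_a = len(a)
    obs = _u_statistic(a, b)
    ge = le = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = _u_statistic(ga, gb)
        total += 1
        ge += u >= obs - 1e-12
        le += u <= obs + 1e-12
    return min(1.0, 2.0 * min(ge, le) / total)


class TestMannWhitney:
    @pytest.mark.parametrize("a, b", [
        ([1.0, 3.0, 5.0], [2.0, 4.0, 6.0, 8.0]),
        ([1.0, 2.0], [3.0, 4.0, 5.0]),
        ([10.0, 1.0, 7.0], [2.0, 9.0, 4.0]),
    ])
    def test_exact_small_sample_matches_enumeration(self, a, b):
        u, p = mann_whitney(a, b)
        assert u == pytest.approx(_u_statistic(a, b))
        assert p == pytest.approx(_exact_mwu_p(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def test_association_screen_table():
    df = pd.DataFrame({
        "temp": [18.0, 17.5, 16.0, 15.0, 14.0],
        "no3": [0.1, 0.3, 1.0, 4.0, 9.0],
        "season": ["may", "may", "oct", "oct", "oct"],
        "rate": [2.0, 3.0, 5.0, 6.0, 7.0],
    })
    out = association_screen(df, pairs=[("temp", "no3")],
                             group_tests=[("rate", "season")])
    spear = out[out.test == "spearman"].iloc[0]
    assert spear.statistic == pytest.approx(-1.0)
    mwu = out[out.test == "mannwhitney"].iloc[0]
    assert mwu.n == 5 and not math.isnan(mwu.p_value)
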