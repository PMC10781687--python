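import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landprior import FeatureTable, TargetRuleParams, build_target_vector, species_target_area
from landprior.targets import species_target_fraction, target_rule_branch


def interp_oracle(area):
    """Independent evaluation of the rule: linear interpolation between
    (log 1000, 1.0) and (log 250000, 0.1) via np.interp, then cap."""
    f = np.interp(np.log(area), [np.log(1000.0), np.log(250000.0)],
                  [1.0, 0.1])
    return min(f * area, 1_000_000.0)


@pytest.mark.parametrize("area,expected", [
    (900.0, 900.0),            # full protection below the lower knot
    (300_000.0, 30_000.0),     # 10% floor above the upper knot
    (20_000_000.0, 1_000_000.0),  # cap binds
])
def test_rule_at_printed_thresholds(area, expected):
    assert species_target_area(area) == pytest.approx(expected, rel=1e-12)


def test_interpolated_value_matches_independent_oracle():
    assert species_target_area(10_000.0) == pytest.approx(
        interp_oracle(10_000.0), rel=1e-12)
    # frozen value from the oracle
    assert species_target_area(10_000.0) == pytest.approx(6246.78, abs=0.01)


def test_continuity_at_both_knots():
    eps = 1e-9
    assert species_target_fraction(1000.0) == 1.0
    assert abs(species_target_fraction(1000.0 - eps)
               - species_target_fraction(1000.0 + eps)) < 1e-9
    assert species_target_fraction(250_000.0) == 0.1
    assert abs(species_target_fraction(250_000.0 - eps)
               - species_target_fraction(250_000.0 + eps)) < 1e-9


def test_fraction_monotone_and_target_area_dip_is_bounded():
    """f(A) is non-increasing everywhere.  The absolute target A*f(A) is
    non-decreasing except in a window below the upper knot: the derivative
    f - 0.9/ln(250) turns negative once f < 0.163 (A above ~170,000 km2),
    so the target dips from ~27,690 km2 there to 25,000 km2 at the knot.
    The dip is intrinsic to the published fraction rule; we pin its
    analytic location and depth rather than deny it."""
    areas = np.logspace(1, 8, 1000)
    f = np.array([species_target_fraction(a) for a in areas])
    assert np.all(np.diff(f) <= 1e-15)
    pre_cap = f * areas
    # analytic entry of the dip: f(A) = 0.9 / ln(250)
    f_crit = 0.9 / np.log(250.0)
    dip_lo = 1000.0 * np.exp((1 - f_crit) / 0.9 * np.log(250.0))
    # outside the dip window the target area is non-decreasing
    outside = (areas[1:] <= dip_lo) | (areas[:-1] >= 250_000.0)
    assert np.all(np.diff(pre_cap)[outside] >= -1e-9)
    # inside it, the depth matches the analytic ratio 25000 / (f_crit*A_lo)
    window = (areas >= dip_lo) & (areas <= 250_000.0)
    ratio = pre_cap[window].min() / pre_cap[window].max()
    assert ratio == pytest.approx(25_000.0 / (f_crit * dip_lo), rel=1e-2)


def test_cap_triggers_only_above_ten_million_km2():
    areas = np.logspace(1, 8, 2000)
    for a in areas:
        capped = species_target_area(a)
        uncapped = species_target_fraction(a) * a
        if capped != uncapped:
            assert a > 10_000_000.0
    # and the cap does engage somewhere
    assert species_target_area(2e7) == 1_000_000.0


@given(st.floats(min_value=0.0, max_value=1e9, allow_nan=False))
@settings(max_examples=200, deadline=None)
def test_rule_bounds_property(area):
    t = species_target_area(area)
    assert 0.0 <= t <= min(area, 1_000_000.0) + 1e-9
    f = species_target_fraction(area)
    assert 0.1 <= f <= 1.0


def test_rule_matches_oracle_everywhere():
    for a in np.logspace(0, 8, 500):
        assert species_target_area(a) == pytest.approx(interp_oracle(a),
                                                       rel=1e-9)


def test_negative_area_rejected():
    with pytest.raises(ValueError):
        species_target_area(-1.0)


def test_branch_labels():
    assert target_rule_branch(500) == "full"
    assert target_rule_branch(10_000) == "interp"
    assert target_rule_branch(300_000) == "floor"
    assert target_rule_branch(2e7) == "capped"


# -- target vectors ---------------------------------------------------------

def make_features():
    ft = FeatureTable()
    ft.add_feature("a", "ncp", np.array([0, 1]), np.array([60.0, 40.0]))
    ft.add_feature("b", "ncp", np.array([0, 1]), np.array([20.0, 30.0]))
    ft.add_feature("bird_s2", "species", np.array([0]), np.array([500.0]))
    ft.add_feature("bird_s3", "species", np.array([0, 1]),
                   np.array([1e6, 1e6]))
    return ft


def test_ncp_targets_proportional():
    ft = make_features()
    areas = {"bird_s2": 500.0, "bird_s3": 2_000_000.0}
    t = build_target_vector(ft, areas, 0.9, include_species=False)
    assert t["a"] == pytest.approx(90.0)
    assert t["b"] == pytest.approx(45.0)
    assert t["bird_s2"] == 0.0 and t["bird_s3"] == 0.0

    zero = build_target_vector(ft, areas, 0.0, include_species=False)
    assert zero["a"] == 0.0 and zero["b"] == 0.0


def test_seasonal_records_targeted_independently():
    ft = make_features()
    areas = {"bird_s2": 500.0, "bird_s3": 2_000_000.0}
    t = build_target_vector(ft, areas, 0.5, include_species=True)
    assert t["bird_s2"] == pytest.approx(500.0)       # full protection
    assert t["bird_s3"] == pytest.approx(200_000.0)   # 10% of 2M km2


def test_level_outside_unit_interval_rejected():
    ft = make_features()
    with pytest.raises(ValueError):
        build_target_vector(ft, {}, 1.5, include_species=False)
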