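"""OLS dose-response fits: examples, an independent oracle, and OLS invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aai_score import (
    DegenerateDesignError,
    InputValidationError,
    InsufficientDataError,
    ResponseRecord,
    SlopeFit,
    UndefinedInverseError,
    fit_all,
    fit_slope,
    fit_slope_xy,
    inverse_slope,
)
from oracles import ols_by_oracle

# 9-point noisy toy set at doses {5, 25, 100}, 3 mice each; expected values
# frozen from the brute-force oracle (shrinking-grid least squares; p by
# numerical integration of the t density)
TOY_DOSES = [5.0, 5.0, 5.0, 25.0, 25.0, 25.0, 100.0, 100.0, 100.0]
TOY_VALUES = [1.21, 0.88, 1.35, 1.42, 1.96, 1.18, 2.84, 3.52, 2.33]
TOY_SLOPE = 0.01840310087
TOY_SE = 0.00330189105
TOY_T = 5.57350336
TOY_P = 8.38927799e-4


def _records(doses, values, group="g", analyte="IL-4"):
    return [
        ResponseRecord(mouse_id=f"m{i}", group=group, dose=d, analyte=analyte, value=v)
        for i, (d, v) in enumerate(zip(doses, values))
    ]


def test_flat_response_has_unit_p_value():
    fit = fit_slope(_records([5, 25, 100], [1.0, 1.0, 1.0]))
    assert fit.slope == 0.0
    assert fit.t_stat == 0.0
    assert fit.p_value == pytest.approx(1.0)


def test_exact_line_is_a_perfect_fit():
    fit = fit_slope_xy([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.perfect_fit
    assert fit.p_value == 0.0


def test_toy_fixture_matches_frozen_oracle_values():
    fit = fit_slope(_records(TOY_DOSES, TOY_VALUES))
    assert fit.n == 9 and fit.df == 7
    assert fit.slope == pytest.approx(TOY_SLOPE, rel=1e-8)
    assert fit.slope_se == pytest.approx(TOY_SE, rel=1e-8)
    assert fit.t_stat == pytest.approx(TOY_T, rel=1e-7)
    assert fit.p_value == pytest.approx(TOY_P, rel=1e-7)


def test_toy_fixture_against_live_oracle():
    fit = fit_slope(_records(TOY_DOSES, TOY_VALUES))
    b, se, t, p = ols_by_oracle(TOY_DOSES, TOY_VALUES)
    assert fit.slope == pytest.approx(b, rel=1e-6)
    assert fit.p_value == pytest.approx(p, abs=1e-8)


def test_against_statsmodels_cross_check():
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    for _ in range(5):
        x = np.repeat([5.0, 25.0, 100.0], 4)
        y = 1 + 0.01 * x + rng.normal(0, 0.4, x.size)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        fit = fit_slope_xy(x, y)
        assert fit.slope == pytest.approx(res.params[1], rel=1e-10)
        assert fit.slope_se == pytest.approx(res.bse[1], rel=1e-10)
        assert fit.p_value == pytest.approx(res.pvalues[1], rel=1e-9)


def test_dose_zero_points_are_excluded_by_default():
    recs = _records([0, 0, 5, 25, 100], [1.0, 1.0, 1.3, 2.1, 4.2])
    assert fit_slope(recs).n == 3
    assert fit_slope(recs, include_dose_zero=True).n == 5


def test_one_sided_p_is_half_the_two_sided_for_positive_slopes():
    recs = _records(TOY_DOSES, TOY_VALUES)
    assert fit_slope(recs, one_sided=True).p_value == pytest.approx(TOY_P / 2, rel=1e-7)


@pytest.mark.parametrize(
    "slope, expected",
    [(0.5, 2.0), (-0.25, -4.0), (TOY_SLOPE, 1.0 / TOY_SLOPE)],
)
def test_inverse_slope(slope, expected):
    fit = SlopeFit("g", "a", 9, slope, 1.0, 0.1, slope / 0.1, 7, 0.5)
    assert inverse_slope(fit) == pytest.approx(expected, rel=1e-9)


def test_inverse_of_zero_slope_raises():
    fit = SlopeFit("g", "a", 9, 0.0, 1.0, 0.1, 0.0, 7, 1.0)
    with pytest.raises(UndefinedInverseError):
        inverse_slope(fit)


def test_insufficient_and_degenerate_designs():
    with pytest.raises(InsufficientDataError):
        fit_slope(_records([5, 25], [1.0, 2.0]))
    with pytest.raises(DegenerateDesignError):
        fit_slope(_records([25, 25, 25], [1.0, 2.0, 3.0]))
    with pytest.raises(InsufficientDataError):
        # dose-0 filtering leaves only 2 points
        fit_slope(_records([0, 0, 5, 25], [1.0, 1.0, 1.3, 2.1]))


def test_fit_slope_refuses_mixed_cells():
    recs = _records([5, 25, 100], [1, 2, 3], group="A") + _records(
        [5, 25, 100], [1, 2, 3], group="B"
    )
    with pytest.raises(InputValidationError):
        fit_slope(recs)


def test_fit_all_cardinality_and_order():
    recs = []
    for g in ("B", "A"):
        for a in ("IL-4", "CCL7"):
            recs += _records([5, 25, 100], [1.1, 1.9, 3.7], group=g, analyte=a)
    fits = fit_all(recs)
    assert [(f.group, f.analyte) for f in fits] == [
        ("A", "CCL7"), ("A", "IL-4"), ("B", "CCL7"), ("B", "IL-4"),
    ]


def test_fit_all_single_cell_matches_fit_slope():
    recs = _records(TOY_DOSES, TOY_VALUES)
    (only,) = fit_all(recs)
    assert only == fit_slope(recs)


def test_fit_all_reports_missing_cells():
    recs = _records([5, 25, 100], [1, 2, 3], group="A", analyte="IL-4")
    with pytest.raises(Exception, match="B/IL-13"):
        fit_all(recs, groups=["A", "B"], analytes=["IL-4", "IL-13"])


# --- OLS invariants -----------------------------------------------------

values_strategy = st.lists(
    st.floats(min_value=0.05, max_value=50, allow_nan=False), min_size=6, max_size=12
)


@settings(max_examples=100, deadline=None)
@given(values=values_strategy, data=st.data())
def test_normal_equations_hold(values, data):
    n = len(values)
    doses = data.draw(
        st.lists(st.sampled_from([5.0, 25.0, 100.0]), min_size=n, max_size=n).filter(
            lambda d: len(set(d)) >= 2
        )
    )
    fit = fit_slope_xy(doses, values)
    x = np.asarray(doses)
    resid = np.asarray(values) - (fit.intercept + fit.slope * x)
    scale = max(1.0, float(np.abs(values).max()) * float(np.abs(x).max()))
    assert abs(resid.sum()) < 1e-8 * scale
    assert abs(float(resid @ x)) < 1e-8 * scale * x.size


@settings(max_examples=50, deadline=None)
@given(c=st.floats(min_value=0.01, max_value=100, allow_nan=False))
def test_dose_scaling_equivariance(c):
    fit = fit_slope_xy(TOY_DOSES, TOY_VALUES)
    scaled = fit_slope_xy([d * c for d in TOY_DOSES], TOY_VALUES)
    assert scaled.slope == pytest.approx(fit.slope / c, rel=1e-9)
    assert scaled.t_stat == pytest.approx(fit.t_stat, rel=1e-9)
    assert scaled.p_value == pytest.approx(fit.p_value, rel=1e-9)


@settings(max_examples=50, deadline=None)
@given(const=st.floats(min_value=5, max_value=100, allow_nan=False))
def test_two_sided_p_invariant_under_reflection(const):
    fit = fit_slope_xy(TOY_DOSES, TOY_VALUES)
    reflected = fit_slope_xy(TOY_DOSES, [const - v for v in TOY_VALUES])
    assert reflected.slope == pytest.approx(-fit.slope, rel=1e-9)
    assert reflected.p_value == pytest.approx(fit.p_value, rel=1e-9)


def test_estimated_slopes_cover_truth(scenario):
    """Planted slopes land within 3 SE of the estimate for ~all cells (30 seeds)."""
    from aai_score import simulate_responses

    covered = total = 0
    for seed in range(30):
        fits = fit_all(simulate_responses(scenario, seed=seed))
        truth = {g.name: g.slopes for g in scenario.groups}
        for f in fits:
            if f.slope_se == 0:
                continue
            total += 1
            covered += abs(f.slope - truth[f.group][f.analyte]) <= 3 * f.slope_se
    assert covered / total >= 0.90
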