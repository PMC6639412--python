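import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import twinconn as tc
from twinconn.gradient import (
    RegressionFit,
    TwoComponentModel,
    akaike_weights,
    area_profile,
    component_intercept_fit,
    early_visual_slope,
    fit_polynomial,
    fit_two_component,
    nested_f_test,
    relative_likelihood,
)
from twinconn.simulate import EARLY_VISUAL_AREAS, PlasticityCurve


def _series(d):
    idx = pd.MultiIndex.from_tuples(d.keys(), names=["area_a", "area_b"])
    return pd.Series(list(d.values()), index=idx)


# ----------------------------------------------------------- area profiles

def test_area_profile_simple_mean():
    s = _series({("A", "B"): 0.2, ("A", "C"): 0.4, ("B", "C"): 0.3})
    prof = area_profile(s).set_index("area")["mean"]
    assert prof["A"] == pytest.approx(0.3)
    assert prof["B"] == pytest.approx(0.25)


def test_area_profile_constant_connections():
    s = _series({("A", "B"): 0.7, ("A", "C"): 0.7, ("B", "C"): 0.7})
    assert (area_profile(s)["mean"] == 0.7).all()


def test_area_profile_matches_enumeration_oracle(rng):
    areas = [f"r{i}" for i in range(10)]
    vals = {}
    for i in range(10):
        for j in range(i + 1, 10):
            vals[(areas[i], areas[j])] = float(rng.uniform())
    prof = area_profile(_series(vals)).set_index("area")
    for a in areas:
        direct = [v for (x, y), v in vals.items() if a in (x, y)]
        assert prof.loc[a, "mean"] == pytest.approx(np.mean(direct), abs=1e-12)
        assert prof.loc[a, "sem"] == pytest.approx(
            np.std(direct, ddof=1) / np.sqrt(len(direct)), abs=1e-12
        )


def test_area_profile_mask_excludes_and_drops(caplog):
    s = _series({("A", "B"): 0.2, ("A", "C"): 0.4, ("B", "C"): 0.6})
    mask = pd.Series([True, False, False], index=s.index)
    with caplog.at_level("WARNING"):
        prof = area_profile(s, mask)
    assert set(prof["area"]) == {"A", "B"}
    assert "C" in caplog.text


# ------------------------------------------------------- polynomial models

def test_exact_linear_data_gives_unit_r2():
    eta = np.arange(8.0)
    fit = fit_polynomial(eta, 0.5 - 0.03 * eta, degree=1)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.params[1] == pytest.approx(-0.03, abs=1e-12)


def test_polynomial_matches_normal_equations_oracle(rng):
    for degree in (1, 2):
        for _ in range(15):
            n = int(rng.integers(6, 25))
            eta = rng.uniform(0, 10, n)
            y = rng.standard_normal(n)
            fit = fit_polynomial(eta, y, degree)
            x = np.column_stack([eta**k for k in range(degree + 1)])
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            np.testing.assert_allclose(fit.params, beta, atol=1e-9)
            rss = float(np.sum((y - x @ beta) ** 2))
            assert fit.rss == pytest.approx(rss, abs=1e-9)
            tss = np.sum((y - y.mean()) ** 2)
            assert fit.r2 == pytest.approx(1 - rss / tss, abs=1e-9)


def test_polynomial_rejects_constant_eta():
    with pytest.raises(ValueError):
        fit_polynomial(np.ones(6), np.arange(6.0), 1)


def test_nested_f_matches_partial_f_oracle(rng):
    eta = np.arange(10.0)
    y = 0.4 - 0.02 * eta + 0.004 * eta**2 + 0.01 * rng.standard_normal(10)
    lin = fit_polynomial(eta, y, 1)
    quad = fit_polynomial(eta, y, 2)
    f, df1, df2, p = nested_f_test(lin, quad)
    f_direct = (lin.rss - quad.rss) / (quad.rss / (10 - 3))
    assert f == pytest.approx(f_direct, abs=1e-10)
    assert (df1, df2) == (1, 7)
    assert p == pytest.approx(stats.f.sf(f_direct, 1, 7), abs=1e-12)


def test_nested_f_perfect_quadratic_is_infinite():
    eta = np.arange(7.0)
    y = 1.0 + 0.5 * eta - 0.1 * eta**2
    f, _, _, p = nested_f_test(fit_polynomial(eta, y, 1), fit_polynomial(eta, y, 2))
    assert np.isinf(f) and p == 0.0


def test_nested_f_rejects_non_nested():
    a = RegressionFit(1, np.zeros(2), 0, 0, 1, 5, 1, rss=1.0, n=8)
    b = RegressionFit(2, np.zeros(3), 0, 0, 2, 4, 1, rss=2.0, n=8)
    with pytest.raises(ValueError):
        nested_f_test(a, b)


def test_nested_f_null_calibration(rng):
    """With no true curvature the partial-F p-value is ~ uniform."""
    eta = np.tile(np.arange(12.0), 4)
    ps = []
    for _ in range(200):
        y = 0.3 - 0.01 * eta + 0.05 * rng.standard_normal(len(eta))
        ps.append(nested_f_test(fit_polynomial(eta, y, 1), fit_polynomial(eta, y, 2))[3])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# -------------------------------------------------------- early-visual test

def _profile_from(levels, values):
    return pd.DataFrame({"area": list(levels.index), "mean": values,
                         "sem": 0.01, "n_connections": 5})


def test_early_visual_slope_df_is_eight(area_levels):
    levels = pd.concat([
        area_levels.rename(lambda a: a),  # left hemisphere
        area_levels.rename(lambda a: a.replace("L_", "R_")),
    ])
    vals = 0.2 + 0.05 * levels.to_numpy()
    prof = _profile_from(levels, vals)
    t, df, p = early_visual_slope(prof, levels, EARLY_VISUAL_AREAS)
    assert df == 8
    assert p < 1e-3  # strictly increasing noiseless values


def test_early_visual_requires_enough_areas(area_levels):
    prof = _profile_from(area_levels, 0.3)
    with pytest.raises(ValueError):
        early_visual_slope(prof, area_levels, ("L_V1", "L_V2v"))


# -------------------------------------------------- two-component model

def test_two_component_noiseless_round_trip():
    eta = np.arange(11.0)
    truth = (0.25, 0.8, 0.001, 0.6)
    y = 0.5 - truth[0] * np.exp(-truth[1] * eta) - truth[2] * np.exp(truth[3] * eta)
    m = fit_two_component(eta, y, h_max=0.5)
    assert m.converged_
    got = (m.a1_, m.b1_, m.a2_, m.b2_)
    np.testing.assert_allclose(got, truth, atol=1e-4)
    assert m.r2_ == pytest.approx(1.0, abs=1e-8)


def test_two_component_requires_enough_levels():
    with pytest.raises(ValueError):
        fit_two_component(np.array([0, 0, 1, 1, 2.0]), np.zeros(5))


def test_two_component_estimator_interface():
    m = TwoComponentModel(h_max=0.4)
    assert m.get_params()["h_max"] == 0.4
    eta = np.arange(8.0)
    y = 0.4 - 0.2 * np.exp(-eta) - 0.005 * np.exp(0.4 * eta)
    m.fit(eta, y)
    np.testing.assert_allclose(m.predict(eta), y, atol=1e-6)


# ------------------------------------------- component comparison & Akaike

def test_component_intercept_exact_target():
    eta = np.arange(11.0)
    curve = PlasticityCurve(a1=0.25, b1=0.8, a2=0.001, b2=0.6)
    full = fit_two_component(eta, curve.h2(eta), h_max=0.5)
    target = 0.6 - full.short_term(eta)
    beta, aic, rss = component_intercept_fit(eta, target, full, "short")
    assert beta == pytest.approx(0.6, abs=1e-6)
    assert rss == pytest.approx(0.0, abs=1e-10)


def test_component_intercept_invalid_which():
    eta = np.arange(11.0)
    full = fit_two_component(eta, PlasticityCurve().h2(eta), h_max=0.5)
    with pytest.raises(ValueError):
        component_intercept_fit(eta, np.zeros(11), full, "medium")


def test_monotone_decreasing_target_prefers_long_component(rng):
    """An anatomy-like monotone profile is matched by the growing component."""
    eta = np.arange(11.0)
    full = fit_two_component(eta, PlasticityCurve().h2(eta), h_max=0.5)
    target = 0.8 - full.long_term(eta) + 0.01 * rng.standard_normal(11)
    _, aic_s, _ = component_intercept_fit(eta, target, full, "short")
    _, aic_l, _ = component_intercept_fit(eta, target, full, "long")
    assert aic_l < aic_s
    w = akaike_weights([aic_s, aic_l])
    assert w[1] > 0.9


def test_akaike_weights_closed_forms():
    np.testing.assert_allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])
    assert relative_likelihood(12.0, 10.0) == pytest.approx(np.exp(-1.0), abs=1e-12)
    w = akaike_weights([0.0, 9.22])
    assert w[1] < 0.01


@given(st.floats(-100, 100))
def test_akaike_weights_shift_invariant(shift):
    base = np.array([3.0, 5.5, 4.1])
    np.testing.assert_allclose(
        akaike_weights(base + shift), akaike_weights(base), atol=1e-12
    )


def test_akaike_rejects_nan():
    with pytest.raises(ValueError):
        akaike_weights([1.0, np.nan])
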