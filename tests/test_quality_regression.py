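import numpy as np
import pandas as pd
import pytest

from brtsdm import (
    GridHeader,
    RasterGrid,
    RegressionEquation,
    apply_equation,
    build_stack,
    builtin_equations,
    partial_f_test,
    stepwise_regression,
)
from brtsdm.errors import ConfigurationError, DegenerateFitError
from brtsdm.synthetic_data import (
    LayerSpec,
    generate_env_stack,
    simulate_compound_contents,
)


# -- partial F test ------------------------------------------------------------

def test_partial_f_no_reduction_means_f_zero_p_one():
    F, p = partial_f_test(5.0, 5.0, 1, 20, 3)
    assert F == 0.0 and p == 1.0


def test_partial_f_hand_computed_value():
    F, p = partial_f_test(10.0, 5.0, 1, 13, 2)
    assert F == pytest.approx(10.0, abs=1e-12)
    assert 0.0 < p < 0.05


def test_partial_f_p_decreases_with_f():
    ps = [partial_f_test(5.0 + d, 5.0, 1, 30, 2)[1] for d in (0.5, 1.0, 2.0, 4.0)]
    assert all(b < a for a, b in zip(ps, ps[1:]))


def test_partial_f_degrees_of_freedom_guard():
    with pytest.raises(ConfigurationError):
        partial_f_test(10.0, 5.0, 1, 4, 3)


# -- stepwise selection --------------------------------------------------------

def test_exact_linear_truth_recovered():
    """y = 2 + 3 x1 exactly: selects x1 only, coefficients exact, R^2 = 1."""
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"x1": rng.normal(size=40), "x2": rng.normal(size=40)})
    y = 2.0 + 3.0 * X["x1"]
    eq = stepwise_regression(y.to_numpy(), X)
    assert list(eq.coefficients) == ["x1"]
    assert eq.intercept == pytest.approx(2.0, abs=1e-8)
    assert eq.coefficients["x1"] == pytest.approx(3.0, abs=1e-8)
    assert eq.r_squared == pytest.approx(1.0, abs=1e-10)


def test_fully_permissive_thresholds_reproduce_full_ols():
    """p_enter = p_remove = 1 enters everything; matches statsmodels OLS."""
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
    y = 1.0 + 0.5 * X["a"] - 0.2 * X["b"] + rng.normal(scale=0.3, size=60)
    eq = stepwise_regression(y.to_numpy(), X, p_enter=1.0, p_remove=1.0)
    assert set(eq.coefficients) == {"a", "b", "c"}
    ref = sm.OLS(y, sm.add_constant(X)).fit()
    assert eq.intercept == pytest.approx(ref.params["const"], abs=1e-8)
    for name in ("a", "b", "c"):
        assert eq.coefficients[name] == pytest.approx(ref.params[name], abs=1e-8)
    assert eq.r_squared == pytest.approx(ref.rsquared, abs=1e-8)


def test_constant_response_rejected():
    X = pd.DataFrame({"x": np.arange(10.0)})
    with pytest.raises(DegenerateFitError):
        stepwise_regression(np.ones(10), X)


def test_collinear_candidate_skipped():
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    X = pd.DataFrame({"x1": x, "x2": 2.0 * x})  # exact collinearity
    y = 1.0 + x + rng.normal(scale=0.1, size=30)
    eq = stepwise_regression(y, X)
    assert len(eq.coefficients) == 1  # only one of the pair can enter


def test_null_data_rarely_admits_predictors():
    """Type-I behavior: with 2 pure-noise candidates the intercept-only model
    is kept with probability (1 - p_enter)^2 ~= 0.9025; the observed rate over
    400 seeded replicates must fall within a 3-sigma binomial band of that.
    """
    hits = 0
    reps = 400
    for rep in range(reps):
        rng = np.random.default_rng(5000 + rep)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = rng.normal(size=30)
        eq = stepwise_regression(y, X)
        hits += eq.intercept_only
    expected = (1 - 0.05) ** 2
    sd = np.sqrt(reps * expected * (1 - expected))
    assert abs(hits - reps * expected) <= 3 * sd, hits


def test_simulated_y4_structure_predictors_recovered():
    """Contents generated from the two-predictor seasonality/precipitation
    equation (n=50, noise sized for clear partial-F signal) are recovered --
    both true predictors enter with the right signs -- in >= 80% of 50
    seeded replicates.
    """
    header = GridHeader(12, 12, 0.0, 0.0, 1.0)
    specs = [
        LayerSpec("bio3", mean=1300.0, sd=30.0, gradient=(200.0, 0.0)),
        LayerSpec("bio4", mean=325.0, sd=25.0, gradient=(0.0, 250.0)),
        LayerSpec("inert", mean=0.0, sd=1.0),
    ]
    truth = RegressionEquation("y4", 14.493, {"bio3": -0.01, "bio4": 0.02})
    recovered = 0
    for rep in range(50):
        stack = generate_env_stack(header, specs, seed=300 + rep)
        rng = np.random.default_rng(600 + rep)
        pts = [(rng.uniform(0, 12), rng.uniform(0, 12)) for _ in range(50)]
        table = simulate_compound_contents(pts, stack, [truth], {"y4": 0.3},
                                           seed=900 + rep)
        eq = stepwise_regression(table["y4"].to_numpy(),
                                 table[["bio3", "bio4", "inert"]])
        ok = (
            {"bio3", "bio4"} <= set(eq.coefficients)
            and eq.coefficients["bio3"] < 0
            and eq.coefficients["bio4"] > 0
        )
        recovered += ok
    assert recovered >= 40  # 80% of 50


# -- applying equations to rasters ---------------------------------------------

def _climate_stack(bio1, bio3, bio4):
    h = GridHeader(1, 1, 0.0, 0.0, 1.0)
    return build_stack(
        {
            "BIO1": RasterGrid.from_array([[bio1]], h),
            "BIO3": RasterGrid.from_array([[bio3]], h),
            "BIO4": RasterGrid.from_array([[bio4]], h),
        },
        {},
    )


def _builtin(response):
    (eq,) = [e for e in builtin_equations() if e.response == response]
    return eq


def test_equation_linearity_in_coefficients():
    stack = _climate_stack(5.0, 1200.0, 300.0)
    eq = _builtin("gentiopicroside")
    base = apply_equation(eq, stack).values[0, 0]
    scaled = RegressionEquation(eq.response, eq.intercept,
                                {k: 3.0 * v for k, v in eq.coefficients.items()})
    out = apply_equation(scaled, stack).values[0, 0]
    assert out - eq.intercept == pytest.approx(3.0 * (base - eq.intercept), rel=1e-12)


def test_missing_layer_rejected():
    h = GridHeader(1, 1, 0.0, 0.0, 1.0)
    stack = build_stack({"BIO1": RasterGrid.from_array([[5.0]], h)}, {})
    with pytest.raises(ConfigurationError):
        apply_equation(_builtin("sweroside"), stack)


def test_nodata_propagates_through_equation():
    h = GridHeader(2, 1, 0.0, 0.0, 1.0)
    mask = np.array([[False, True]])
    stack = build_stack(
        {"BIO4": RasterGrid(h, np.array([[300.0, -9999.0]]), mask)}, {}
    )
    out = apply_equation(_builtin("sweroside"), stack)
    assert not out.mask[0, 0] and out.mask[0, 1]


def test_builtin_catalogue_contents():
    eqs = builtin_equations()
    assert len(eqs) == 5
    y2 = _builtin("gentiopicroside")
    assert y2.intercept == -0.581
    assert y2.coefficients == {"BIO1": 0.53, "BIO4": 0.021}
    assert _builtin("total_iridoids").r_squared == 0.336
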