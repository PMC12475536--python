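"""Mixed-model fitter against closed-form oracles, plus the hypothesis models."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from overyield.errors import InvalidInputError, SingularFitWarning
from overyield.mixedmodels import (
    ModelSpec,
    build_design,
    fit_h1,
    fit_h3,
    fit_h4,
    fit_lmm,
)
from overyield.synthetic import simulate_richness_response


@pytest.fixture(autouse=True)
def _quiet_singular_fits():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SingularFitWarning)
        yield


def test_design_builder_terms():
    df = pd.DataFrame({"x": [1.0, 2.0], "w": [3.0, 5.0]})
    X, names = build_design(df, ["x", "x^2", "x:w"])
    assert names == ["(Intercept)", "x", "x^2", "x:w"]
    assert np.allclose(X[1], [1.0, 2.0, 4.0, 10.0])
    with pytest.raises(InvalidInputError):
        build_design(df, ["missing"])


def test_reduces_to_ols_without_random_terms(rng):
    n = 150
    df = pd.DataFrame({"x": rng.normal(size=n)})
    df["y"] = 0.7 + 1.3 * df["x"] + rng.normal(0, 0.5, n)
    fit = fit_lmm(ModelSpec("y", ("x",)), df)
    X = np.column_stack([np.ones(n), df["x"]])
    beta_ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
    assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-7)
    # ML residual variance (n denominator)
    resid = df["y"] - X @ beta_ols
    assert math.exp(fit.disp_params.iloc[0]) == pytest.approx(
        float((resid**2).mean()), rel=1e-4
    )


def test_balanced_one_way_matches_anova_closed_form(rng):
    """ML estimates for the balanced random-intercept layout have a closed form:
    sigma_e^2 = MSW and sigma_b^2 = (SSB/k - MSW)/m."""
    k, m = 25, 6
    g = np.repeat(np.arange(k), m)
    y = 1.0 + rng.normal(0, 0.8, k)[g] + rng.normal(0, 0.5, k * m)
    df = pd.DataFrame({"y": y, "grp": g.astype(str)})
    fit = fit_lmm(ModelSpec("y", (), groups=(("grp",),)), df)
    ybar_g = df.groupby("grp", sort=False)["y"].mean().to_numpy()
    ssw = float(((y - ybar_g[g]) ** 2).sum())
    msw = ssw / (k * (m - 1))
    ssb = m * float(((ybar_g - y.mean()) ** 2).sum())
    assert math.exp(fit.disp_params.iloc[0]) == pytest.approx(msw, rel=1e-4)
    assert fit.vc["grp"] == pytest.approx((ssb / k - msw) / m, rel=1e-3)


def test_row_order_invariance():
    data = simulate_richness_response(seed=42, n_experiments=6, plots_per_experiment=40)
    fit1 = fit_h1(data)
    shuffled = data.sample(frac=1.0, random_state=7).reset_index(drop=True)
    fit2 = fit_h1(shuffled)
    assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-8)
    assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)


def test_zero_heterogeneity_collapses_to_ols(rng):
    """No between-group signal: random variances ~ 0, coefficients match OLS."""
    n = 300
    df = pd.DataFrame(
        {
            "x": rng.normal(size=n),
            "grp": rng.integers(0, 10, n).astype(str),
        }
    )
    df["y"] = 2.0 - 0.5 * df["x"] + rng.normal(0, 1.0, n)
    fit = fit_lmm(ModelSpec("y", ("x",), groups=(("grp",),)), df)
    assert fit.vc["grp"] < 5e-2
    X = np.column_stack([np.ones(n), df["x"]])
    beta_ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
    assert np.allclose(fit.params.to_numpy(), beta_ols, atol=5e-3)


def test_free_dispersion_never_fits_worse():
    """The constant-variance model is nested in the dispersion model."""
    data = simulate_richness_response(seed=3, n_experiments=8, plots_per_experiment=50)
    free = fit_h1(data, dispersion="richness")
    const = fit_h1(data, dispersion=None)
    assert free.loglik >= const.loglik - 1e-6
    assert free.aic == pytest.approx(2 * (3 + 4) - 2 * free.loglik)


def test_h1_recovers_injected_effect():
    data = simulate_richness_response(
        seed=21, beta=(0.0, 0.4, -0.05), disp_slope=-0.1,
        n_experiments=12, plots_per_experiment=80,
    )
    fit = fit_h1(data)
    assert fit.params["richness"] > 0 and fit.pvalues["richness"] < 0.01
    assert fit.params["richness^2"] < 0
    assert fit.disp_params["richness"] < 0


def test_h1_null_scenario_covers_zero():
    data = simulate_richness_response(
        seed=8, beta=(0.0, 0.0, 0.0), disp_slope=0.0,
        n_experiments=12, plots_per_experiment=60,
    )
    fit = fit_h1(data)
    ci = fit.conf_int()
    assert ci.loc["richness", "lower"] <= 0.0 <= ci.loc["richness", "upper"]
    assert abs(fit.disp_params["richness"]) < 3 * fit.disp_bse["richness"] + 0.05


def test_h3_recovers_trait_linked_effect(rng):
    """Selection effect rising with FDis_WD: coefficient sign and significance."""
    n = 600
    df = pd.DataFrame(
        {
            "experiment": np.repeat([f"e{i}" for i in range(10)], n // 10),
            "composition": [f"c{i % 60}" for i in range(n)],
            "block": [f"b{i % 3}" for i in range(n)],
            "richness": rng.integers(2, 7, n),
            "cwm_wd": rng.normal(size=n),
            "cwm_lnc": rng.normal(size=n),
            "fdis_wd": rng.uniform(0, 1, n),
            "fdis_lnc": rng.uniform(0, 1, n),
        }
    )
    df["se"] = 0.2 + 1.2 * df["fdis_wd"] + rng.normal(0, 0.4, n)
    fit = fit_h3(df, "se")
    assert fit.params["fdis_wd"] == pytest.approx(1.2, abs=0.15)
    assert fit.pvalues["fdis_wd"] < 1e-6
    with pytest.raises(InvalidInputError):
        fit_h3(df, "productivity")


class TestH4:
    def _species_data(self, rng, n=800):
        df = pd.DataFrame(
            {
                "experiment": np.repeat([f"e{i}" for i in range(8)], n // 8),
                "composition": [f"c{i % 50}" for i in range(n)],
                "block": [f"b{i % 2}" for i in range(n)],
                "class": rng.choice(["angiosperm", "gymnosperm"], n),
                "richness": rng.integers(1, 7, n),
                "wd": rng.normal(size=n),
                "lnc": rng.normal(size=n),
            }
        )
        lp = 0.1 * df["richness"] + 0.2 * df["lnc"] - 0.03 * df["richness"] * df["wd"] \
            + 0.03 * df["richness"] * df["lnc"] + rng.normal(0, 0.3, n)
        df["productivity"] = np.exp(lp - 1.0)  # strictly positive response
        return df

    def test_interaction_signs_recovered(self, rng):
        fit = fit_h4(self._species_data(rng))
        assert fit.params["richness:wd"] < 0
        assert fit.params["richness:lnc"] > 0

    def test_back_transform_inverts_log_link(self, rng):
        df = self._species_data(rng)
        fit = fit_h4(df, constant=0.05)
        new = df.head(7)
        lp = fit.predict(new, transformed=True)
        assert np.allclose(fit.predict(new), np.exp(lp) - 0.05, rtol=1e-12)

    def test_mean_species_slope_is_main_effect(self, rng):
        """At wd = lnc = 0 the fitted log-scale slope over richness equals beta1."""
        fit = fit_h4(self._species_data(rng))
        grid = pd.DataFrame({"richness": [2.0, 3.0], "wd": 0.0, "lnc": 0.0})
        lp = fit.predict(grid, transformed=True)
        assert lp[1] - lp[0] == pytest.approx(fit.params["richness"], abs=1e-10)


def test_grouping_validation():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "g": ["a", "a", "a"]})
    with pytest.raises(InvalidInputError):
        fit_lmm(ModelSpec("y", (), groups=(("g",),)), df)
    with pytest.raises(InvalidInputError):
        fit_lmm(ModelSpec("z", ()), df)
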