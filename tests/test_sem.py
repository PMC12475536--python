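"""d-separation basis sets, Fisher's C, standardized paths and the piecewise fit."""

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from overyield.errors import InvalidInputError, InvalidModelError, SingularFitWarning
from overyield.mixedmodels import ModelSpec, fit_lmm
from overyield.sem import (
    SemSpec,
    basis_set,
    fishers_c,
    fit_piecewise,
    indirect_effect,
    standardized_paths,
)
from overyield.synthetic import simulate_sem_dataset


@pytest.fixture(autouse=True)
def _quiet_singular_fits():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SingularFitWarning)
        yield


class TestBasisSet:
    def test_chain_graph(self):
        dag = nx.DiGraph([("X", "M"), ("M", "Y")])
        claims = basis_set(dag)
        assert len(claims) == 1
        (c,) = claims
        assert {c.x, c.y} == {"X", "Y"} and c.given == ("M",)

    def test_study_dag_single_claim(self):
        """The fitted DAG implies exactly one claim: FDis and structural
        diversity independent given richness, hence df = 2."""
        claims = basis_set(SemSpec().dag())
        assert len(claims) == 1
        (c,) = claims
        assert {c.x, c.y} == {"structural", "fdis_all"}
        assert c.given == ("richness",)

    def test_fully_connected_is_saturated(self):
        dag = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c")])
        assert basis_set(dag) == []

    def test_cycle_rejected(self):
        dag = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(InvalidModelError):
            basis_set(dag)


class TestFishersC:
    def test_all_evidence_absent(self):
        c, df, p = fishers_c([1.0])
        assert c == 0.0 and df == 2 and p == pytest.approx(1.0)

    def test_single_half(self):
        c, df, p = fishers_c([0.5])
        assert c == pytest.approx(-2 * math.log(0.5))
        assert p == pytest.approx(0.5)

    def test_printed_statistic_reproduced(self):
        """C = 1.063 with one claim gives p = exp(-C/2) = 0.588."""
        p_in = math.exp(-1.063 / 2)
        c, df, p = fishers_c([p_in])
        assert c == pytest.approx(1.063, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(0.5877, abs=1e-4)

    def test_single_claim_fixed_point(self, rng):
        """With one claim, chi^2_2 makes the combined p equal the input p."""
        for p_in in rng.uniform(1e-6, 1.0, 100):
            _, _, p_out = fishers_c([p_in])
            assert p_out == pytest.approx(p_in, rel=1e-9)

    def test_additive_over_independent_claim_sets(self, rng):
        pa = list(rng.uniform(0.05, 1.0, 3))
        pb = list(rng.uniform(0.05, 1.0, 2))
        ca, dfa, _ = fishers_c(pa)
        cb, dfb, _ = fishers_c(pb)
        cab, dfab, _ = fishers_c(pa + pb)
        assert cab == pytest.approx(ca + cb)
        assert dfab == dfa + dfb

    def test_zero_pvalue_flagged(self):
        with pytest.warns(UserWarning):
            c, _, p = fishers_c([0.0, 0.5])
        assert math.isinf(c) and p == 0.0
        with pytest.raises(InvalidInputError):
            fishers_c([])


class TestIndirectEffects:
    def test_printed_products(self):
        assert indirect_effect([0.59, 0.27]) == pytest.approx(0.159, abs=5e-4)
        assert indirect_effect([0.38, -0.55]) == pytest.approx(-0.209, abs=5e-4)

    def test_identity_leg(self):
        assert indirect_effect([1.0, 0.73]) == pytest.approx(0.73)
        with pytest.raises(InvalidInputError):
            indirect_effect([])


class TestStandardizedPaths:
    def test_sd_ratio(self, rng):
        n = 2000
        x = rng.normal(0, 1.0, n)
        y = 2.0 * x + rng.normal(0, 2.0, n)  # sd(y) ~ 2*sqrt(2)
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_lmm(ModelSpec("y", ("x",)), df)
        std = standardized_paths(fit, df, "y")
        expect = fit.params["x"] * df["x"].std(ddof=1) / df["y"].std(ddof=1)
        assert std["x"] == pytest.approx(expect, rel=1e-12)

    def test_prestandardized_is_identity(self, rng):
        n = 3000
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(0, math.sqrt(1 - 0.36), n)
        df = pd.DataFrame({"x": (x - x.mean()) / x.std(ddof=1)})
        df["y"] = (y - y.mean()) / y.std(ddof=1)
        fit = fit_lmm(ModelSpec("y", ("x",)), df)
        std = standardized_paths(fit, df, "y")
        assert std["x"] == pytest.approx(fit.params["x"], rel=1e-12)

    def test_recovers_known_recursive_model(self):
        """Unit-variance recursive system with paths 0.6, 0.3, -0.5 at n=2000."""
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.normal(size=n)
        m = 0.6 * x + math.sqrt(1 - 0.36) * rng.normal(size=n)
        resid = 1 - (0.3**2 + 0.5**2 + 2 * 0.3 * (-0.5) * 0.6)
        y = 0.3 * m - 0.5 * x + math.sqrt(resid) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        fm = fit_lmm(ModelSpec("m", ("x",)), df)
        fy = fit_lmm(ModelSpec("y", ("m", "x")), df)
        assert standardized_paths(fm, df, "m")["x"] == pytest.approx(0.6, abs=0.05)
        sy = standardized_paths(fy, df, "y")
        assert sy["m"] == pytest.approx(0.3, abs=0.05)
        assert sy["x"] == pytest.approx(-0.5, abs=0.05)


class TestFitPiecewise:
    def test_paths_and_claim_on_dag_data(self):
        data = simulate_sem_dataset(seed=3, n_plots=1500)
        res = fit_piecewise(SemSpec(), data)
        assert res.df == 2 and len(res.claims) == 1
        assert res.pvalue == pytest.approx(
            res.claims[0]["p"], rel=1e-9
        )  # single-claim fixed point
        paths = res.paths.set_index(["response", "term"])["std_estimate"]
        assert paths[("structural", "richness")] == pytest.approx(0.38, abs=0.08)
        assert paths[("fdis_all", "richness")] == pytest.approx(0.59, abs=0.08)
        assert paths[("productivity", "structural")] == pytest.approx(-0.55, abs=0.08)
        assert paths[("productivity", "fdis_all")] == pytest.approx(0.27, abs=0.08)
        assert 0.0 <= res.r2_marginal["productivity"] <= 1.0
        assert "Fisher's C" in res.report()

    def test_interaction_model_selection_by_aic(self):
        """On interaction-bearing truth, AIC prefers the interaction variant."""
        data = simulate_sem_dataset(
            seed=11, n_plots=1500, paths={"interaction": 0.25}
        )
        plain = fit_piecewise(SemSpec(interaction="none"), data)
        inter = fit_piecewise(SemSpec(interaction="richness:structural"), data)
        assert inter.aic < plain.aic

    def test_path_tracing_consistency(self):
        """Direct + indirect standardized effects reproduce the total effect of
        richness in a fully linear, no-interaction system."""
        data = simulate_sem_dataset(seed=19, n_plots=5000, re_sd=0.05)
        res = fit_piecewise(SemSpec(interaction="none"), data)
        total_fit = fit_lmm(
            ModelSpec("productivity", ("richness",),
                      groups=(("experiment", "composition"), ("experiment", "block"))),
            data,
        )
        total = standardized_paths(total_fit, data, "productivity")["richness"]
        assert res.total_richness_effect == pytest.approx(total, abs=0.02)

    def test_missing_columns_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_piecewise(SemSpec(), pd.DataFrame({"richness": [1.0]}))
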