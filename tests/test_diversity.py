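"""CWM, FDis, Gini, CV and trait PCA against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overyield import diversity as dv
from overyield.errors import InvalidInputError, UndefinedMetricError


def brute_gini(x):
    x = np.asarray(x, float)
    n = len(x)
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean()))


def brute_fdis(abund, traits):
    """Expand species counts into individuals, then mean distance to centroid."""
    pts = []
    for sp, a in abund.items():
        pts += [np.atleast_1d(np.asarray(traits[sp], float))] * int(a)
    pts = np.vstack(pts)
    centroid = pts.mean(axis=0)
    return float(np.linalg.norm(pts - centroid, axis=1).mean())


class TestCwm:
    @pytest.mark.parametrize(
        "abund, trait, expected",
        [
            ({"A": 3, "B": 1}, {"A": 2.0, "B": 4.0}, 2.5),
            ({"A": 7}, {"A": 3.3}, 3.3),
            ({"A": 2, "B": 2}, {"A": 1.0, "B": 5.0}, 3.0),
        ],
    )
    def test_known_values(self, abund, trait, expected):
        assert dv.cwm(abund, trait) == pytest.approx(expected)

    def test_all_zero_abundance(self):
        with pytest.raises(UndefinedMetricError):
            dv.cwm({"A": 0}, {"A": 1.0})

    @given(
        st.lists(st.tuples(st.integers(1, 20), st.floats(-5, 5)), min_size=1, max_size=8)
    )
    @settings(max_examples=60, deadline=None)
    def test_bounded_by_trait_range(self, pairs):
        abund = {f"s{i}": a for i, (a, _) in enumerate(pairs)}
        trait = {f"s{i}": t for i, (_, t) in enumerate(pairs)}
        value = dv.cwm(abund, trait)
        assert min(trait.values()) - 1e-12 <= value <= max(trait.values()) + 1e-12


class TestFdis:
    def test_monoculture_is_zero(self):
        assert dv.fdis({"A": 9}, {"A": [0.3, 1.2]}) == 0.0

    def test_symmetric_pair(self):
        assert dv.fdis({"A": 1, "B": 1}, {"A": [0.0], "B": [1.0]}) == pytest.approx(0.5)

    def test_weighted_pair(self):
        assert dv.fdis({"A": 3, "B": 1}, {"A": [0.0], "B": [1.0]}) == pytest.approx(0.375)

    def test_matches_individual_expansion_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            abund = {f"s{i}": int(rng.integers(1, 7)) for i in range(k)}
            traits = {f"s{i}": rng.normal(size=3) for i in range(k)}
            assert dv.fdis(abund, traits) == pytest.approx(
                brute_fdis(abund, traits), rel=1e-12
            )

    def test_unequal_vector_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            dv.fdis({"A": 1, "B": 1}, {"A": [0.0], "B": [1.0, 2.0]})


class TestGini:
    @pytest.mark.parametrize(
        "values, expected",
        [([5.0, 5.0, 5.0], 0.0), ([0.0, 1.0], 0.5), ([1.0, 2.0, 3.0], 8 / 36)],
    )
    def test_known_values(self, values, expected):
        assert dv.gini(values) == pytest.approx(expected)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            x = rng.lognormal(1.0, 0.6, size=int(rng.integers(2, 30)))
            assert dv.gini(x) == pytest.approx(brute_gini(x), rel=1e-10)

    @given(st.lists(st.floats(0.1, 50.0), min_size=2, max_size=15), st.floats(0.5, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_scale_invariant(self, values, k):
        assert dv.gini(values) == pytest.approx(dv.gini([k * v for v in values]), abs=1e-9)

    def test_spreading_at_fixed_mean_increases(self):
        base = [4.0, 6.0, 5.0, 5.0]
        spread = [4.0, 6.0, 3.0, 7.0]
        assert dv.gini(spread) > dv.gini(base)

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedMetricError):
            dv.gini([0.0, 0.0])


class TestCv:
    def test_known_values(self):
        assert dv.cv([7.0, 7.0, 7.0]) == 0.0
        assert dv.cv([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_scale_invariant(self):
        x = [2.0, 5.0, 11.0]
        assert dv.cv(x) == pytest.approx(dv.cv([3 * v for v in x]))

    def test_needs_two_values(self):
        with pytest.raises(InvalidInputError):
            dv.cv([1.0])


class TestTraitPca:
    def test_two_correlated_plus_one_independent(self, rng):
        """Correlation matrix with a duplicated axis: eigenvalues 2, 1, 0."""
        a = rng.normal(size=400)
        b = rng.normal(size=400)
        ac = a - a.mean()
        b = b - b.mean() - (b - b.mean()) @ ac / (ac @ ac) * ac  # exactly uncorrelated
        df = pd.DataFrame({"wd": a, "lnc": 3 * a + 1, "sla": b})
        _, fractions = dv.trait_pca(df)
        assert fractions[0] == pytest.approx(2 / 3, abs=1e-9)
        assert fractions[1] == pytest.approx(1 / 3, abs=1e-9)

    def test_identical_rows_degenerate(self):
        df = pd.DataFrame({"wd": [0.5] * 4, "lnc": [2.0] * 4, "sla": [100.0] * 4})
        with pytest.raises(UndefinedMetricError):
            dv.trait_pca(df)

    def test_independent_traits_split_evenly(self, rng):
        df = pd.DataFrame(rng.normal(size=(4000, 3)), columns=["wd", "lnc", "sla"])
        _, fractions = dv.trait_pca(df)
        assert np.allclose(fractions, 1 / 3, atol=0.05)

    def test_loadings_orthonormal(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["wd", "lnc", "sla"])
        loadings, fractions = dv.trait_pca(df)
        assert np.allclose(loadings.to_numpy() @ loadings.to_numpy().T, np.eye(3), atol=1e-9)
        assert fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(fractions) <= 1e-12)


def test_plot_metrics_invariants():
    """Monocultures have zero FDis; structural diversity needs two heights."""
    from overyield.diversity import plot_metrics
    from overyield.synthetic import generate, scenario

    ds = generate(scenario("paper_like", seed=2, n_experiments=2))
    met = plot_metrics(ds.trees, ds.plots, ds.traits)
    mono = met[met["richness"] == 1]
    assert np.allclose(mono[["fdis_wd", "fdis_lnc", "fdis_all"]].to_numpy(), 0.0)
    mixed = met[met["richness"] > 1].dropna(subset=["fdis_all"])
    assert (mixed["fdis_all"] > 0).all()
    ok = met.dropna(subset=["gini_height"])
    assert ((ok["gini_height"] >= 0) & (ok["gini_height"] < 1)).all()
    assert (met.loc[met["n_heights"] < 2, "gini_height"].isna()).all()
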