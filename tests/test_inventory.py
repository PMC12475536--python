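"""Tree-level arithmetic, plot productivity and table round-trips."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overyield import inventory as inv
from overyield.errors import ConsistencyError, InvalidInputError


class TestEquivalentDiameter:
    @pytest.mark.parametrize(
        "stems, expected",
        [([3.0, 4.0], 5.0), ([7.5], 7.5), ([1.0, 1.0, 1.0, 1.0], 2.0)],
    )
    def test_known_values(self, stems, expected):
        assert inv.equivalent_diameter(stems) == pytest.approx(expected)

    @given(st.lists(st.floats(0.1, 200.0), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_conserves_total_basal_area(self, stems):
        """The one-stem equivalent must carry exactly the summed cross-section."""
        d = inv.equivalent_diameter(stems)
        total = sum(inv.tree_basal_area(s) for s in stems)
        assert inv.tree_basal_area(d) == pytest.approx(total, rel=1e-12)

    @pytest.mark.parametrize("bad", [[], [0.0], [5.0, -1.0]])
    def test_invalid_stems_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            inv.equivalent_diameter(bad)


class TestBasalArea:
    def test_two_metre_tree_is_pi(self):
        assert inv.tree_basal_area(200.0) == pytest.approx(math.pi)

    def test_twenty_cm(self):
        assert inv.tree_basal_area(20.0) == pytest.approx(math.pi * 0.1**2)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            inv.tree_basal_area(0.0)


class TestPlotProductivity:
    def test_arithmetic(self, two_species_plot):
        trees, design = two_species_plot
        # three live 10 cm equivalents: 3 * pi * 0.05^2 m2 over 0.01 ha, 10 yr
        expect = 3 * math.pi * 0.05**2 / 0.01 / 10.0
        assert inv.plot_productivity(trees, design) == pytest.approx(expect)

    def test_subsample_scaling(self, two_species_plot):
        trees, design = two_species_plot
        full = inv.plot_productivity(trees, design)
        design.sampled_fraction = 0.5
        assert inv.plot_productivity(trees, design) == pytest.approx(2 * full)

    def test_no_live_trees_gives_zero(self, two_species_plot):
        trees, design = two_species_plot
        dead = [inv.TreeRecord(t.tree_id, t.plot_id, t.species, t.stems, alive=False)
                for t in trees]
        assert inv.plot_productivity(dead, design) == 0.0

    def test_include_dead_recovers_last_size(self, two_species_plot):
        trees, design = two_species_plot
        with_dead = inv.plot_productivity(trees, design, include_dead=True)
        assert with_dead > inv.plot_productivity(trees, design)

    def test_wrong_plot_raises(self, two_species_plot):
        trees, design = two_species_plot
        trees[0].plot_id = "other"
        with pytest.raises(ConsistencyError):
            inv.plot_productivity(trees, design)

    def test_linear_in_inverse_age(self, two_species_plot):
        trees, design = two_species_plot
        base = inv.plot_productivity(trees, design)
        design.age_years = 20.0
        assert inv.plot_productivity(trees, design) == pytest.approx(base / 2)


class TestSpeciesProductivity:
    def test_partitions_plot_total(self, two_species_plot):
        trees, design = two_species_plot
        per = [inv.species_productivity(trees, design, sp) for sp in ("oak", "pine")]
        assert sum(per) == pytest.approx(inv.plot_productivity(trees, design), rel=1e-14)
        assert per[0] == pytest.approx(2 * per[1])  # oak has two live 10 cm equivalents

    def test_unplanted_species_rejected(self, two_species_plot):
        trees, design = two_species_plot
        with pytest.raises(InvalidInputError):
            inv.species_productivity(trees, design, "birch")

    def test_fully_dead_species_is_zero(self):
        design = inv.PlotDesign("p", "e", "b", {"a": 1, "c": 1}, area_ha=0.01)
        trees = [
            inv.TreeRecord("t1", "p", "a", [10.0]),
            inv.TreeRecord("t2", "p", "c", [10.0], alive=False),
        ]
        assert inv.species_productivity(trees, design, "c") == 0.0


def test_table_and_record_productivity_agree(rng):
    """Vectorized table computation equals the per-record reference path."""
    from overyield.synthetic import generate, scenario

    ds = generate(scenario("null", seed=3, n_experiments=2))
    table = inv.productivity_table(ds.trees, ds.plots).set_index("plot_id")
    some = ds.plots.sample(5, random_state=1)
    records = inv.records_from_table(ds.trees)
    for row in some.itertuples(index=False):
        design = inv.design_from_row(row)
        mine = [t for t in records if t.plot_id == row.plot_id]
        assert table.loc[row.plot_id, "productivity"] == pytest.approx(
            inv.plot_productivity(mine, design), rel=1e-12
        )


def test_species_table_sums_to_plot_total():
    from overyield.synthetic import generate, scenario

    ds = generate(scenario("selection", seed=5, n_experiments=2))
    plot = inv.productivity_table(ds.trees, ds.plots).set_index("plot_id")["productivity"]
    per = inv.species_productivity_table(ds.trees, ds.plots)
    summed = per.groupby("plot_id")["productivity"].sum()
    assert np.allclose(summed.reindex(plot.index).to_numpy(), plot.to_numpy(), rtol=1e-12)


def test_csv_round_trip(tmp_path):
    from overyield.synthetic import generate, scenario

    ds = generate(scenario("null", seed=9, n_experiments=1))
    inv.write_trees(ds.trees, tmp_path / "trees.csv")
    inv.write_plots(ds.plots, tmp_path / "plots.csv")
    inv.write_traits(ds.traits, tmp_path / "traits.csv")
    trees = inv.read_trees(tmp_path / "trees.csv")
    plots = inv.read_plots(tmp_path / "plots.csv")
    traits = inv.read_traits(tmp_path / "traits.csv")
    assert len(trees) == len(ds.trees) and len(plots) == len(ds.plots)
    pd.testing.assert_series_equal(
        trees["stems"].map(sum), ds.trees["stems"].map(sum), check_names=False
    )
    assert plots["composition"].iloc[0] == ds.plots["composition"].iloc[0]
    assert np.allclose(traits["wd"], ds.traits["wd"])
    # productivity identical through the round trip
    a = inv.productivity_table(ds.trees, ds.plots)["productivity"]
    b = inv.productivity_table(trees, plots)["productivity"]
    assert np.allclose(a, b, rtol=1e-12)


def test_column_map_reader(tmp_path):
    df = pd.DataFrame(
        {"treeID": ["a"], "plotID": ["p"], "species_name": ["x"], "stems": ["5.0"],
         "alive": [1], "sampled": [1]}
    )
    df.to_csv(tmp_path / "alt.csv", index=False)
    out = inv.read_trees(
        tmp_path / "alt.csv",
        {"treeID": "tree_id", "plotID": "plot_id", "species_name": "species",
         "sampled": "in_sample"},
    )
    assert out.loc[0, "tree_id"] == "a" and out.loc[0, "stems"] == [5.0]


def test_missing_trait_rows_detected():
    plots = pd.DataFrame(
        {"plot_id": ["p"], "composition": [{"a": 1, "b": 1}]}
    )
    traits = pd.DataFrame({"species": ["a"], "wd": [0.5], "lnc": [2.0], "sla": [100.0],
                           "class": ["angiosperm"], "provenance": ["measured"]})
    with pytest.raises(ConsistencyError):
        inv.validate_traits(traits, plots)
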