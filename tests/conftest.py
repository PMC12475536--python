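import numpy as np
import pytest
from hypothesis import settings

from overyield.inventory import PlotDesign, TreeRecord

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_species_plot():
    """A tiny two-species plot: known basal areas, one dead tree, one multi-stem."""
    design = PlotDesign(
        plot_id="p1", experiment="e1", block="b1",
        composition={"oak": 2, "pine": 2}, area_ha=0.01, sampled_fraction=1.0,
        age_years=10.0,
    )
    trees = [
        TreeRecord("t1", "p1", "oak", [10.0], height_m=8.0),
        TreeRecord("t2", "p1", "oak", [6.0, 8.0], height_m=7.0),   # multi-stem, eq. diam 10
        TreeRecord("t3", "p1", "pine", [10.0], height_m=9.0),
        TreeRecord("t4", "p1", "pine", [20.0], alive=False),        # dead: excluded
    ]
    return trees, design
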