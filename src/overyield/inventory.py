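"""Individual-tree inventory data model and basal-area productivity.

The basic currency of a planted diversity experiment is the individual tree:
a stem (or several stems from one root) with a diameter in cm, an optional
height in m, and an alive flag, sitting in a plot whose design (species
composition, area, block, age) is known exactly because it was planted.

Stand productivity is annual basal-area increment per hectare
(m^2 ha^-1 yr^-1): the summed cross-sectional area of all live measured
stems, adjusted for the sampled fraction of the plot, scaled per hectare
and divided by stand age. Multi-stemmed trees are collapsed to the single
equivalent diameter that conserves total basal area, D = sqrt(sum_i d_i^2),
so per-tree basal area remains additive over stems.

Tables are plain CSV. In memory, trees and plots travel as pandas
DataFrames with the column schemas documented in :data:`TREE_COLUMNS` and
:data:`PLOT_COLUMNS`; list/mapping-valued cells (stems, composition) are
serialized with ``;`` / ``:`` separators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidInputError

#: canonical tree-table columns
TREE_COLUMNS = ["tree_id", "plot_id", "species", "stems", "height_m", "alive", "in_sample"]
#: canonical plot-table columns
PLOT_COLUMNS = [
    "plot_id",
    "experiment",
    "block",
    "composition",
    "area_ha",
    "sampled_fraction",
    "age_years",
    "abiotic_manipulation",
    "height_diam_interval_yr",
]
#: canonical trait-table columns (wd g cm^-3, lnc %, sla cm^2 g^-1)
TRAIT_COLUMNS = ["species", "wd", "lnc", "sla", "class", "provenance"]

_CM_PER_M = 100.0  # unit convention: diameters cm, basal area m^2


@dataclass
class TreeRecord:
    """One measured tree.

    ``stems`` holds the diameters (cm) of every stem growing from the root;
    most trees have exactly one. ``in_sample`` marks whether the tree lies in
    the inventoried subset of the plot (some experiments measure only a core
    subplot).
    """

    tree_id: str
    plot_id: str
    species: str
    stems: Sequence[float]
    height_m: float | None = None
    alive: bool = True
    in_sample: bool = True

    def __post_init__(self) -> None:
        self.stems = list(self.stems)
        if self.alive and not self.stems:
            raise InvalidInputError(f"tree {self.tree_id}: live tree with no stems")
        if any(d <= 0 for d in self.stems):
            raise InvalidInputError(f"tree {self.tree_id}: non-positive stem diameter")
        if self.height_m is not None and not math.isnan(self.height_m) and self.height_m <= 0:
            raise InvalidInputError(f"tree {self.tree_id}: non-positive height")


@dataclass
class PlotDesign:
    """Design attributes of one experimental plot.

    ``composition`` maps species label -> planted count. Richness is derived
    as the number of distinct species planted. ``sampled_fraction`` is the
    fraction of the plot area covered by the inventory (1 = full census).
    """

    plot_id: str
    experiment: str
    block: str
    composition: Mapping[str, int]
    area_ha: float
    sampled_fraction: float = 1.0
    age_years: float = 1.0
    abiotic_manipulation: bool = False
    height_diam_interval_yr: float = 0.0

    def __post_init__(self) -> None:
        self.composition = dict(self.composition)
        if not self.composition:
            raise InvalidInputError(f"plot {self.plot_id}: empty composition")
        if any(c <= 0 for c in self.composition.values()):
            raise InvalidInputError(f"plot {self.plot_id}: non-positive planted count")
        if self.area_ha <= 0:
            raise InvalidInputError(f"plot {self.plot_id}: area_ha must be > 0")
        if not 0 < self.sampled_fraction <= 1:
            raise InvalidInputError(f"plot {self.plot_id}: sampled_fraction outside (0, 1]")
        if self.age_years <= 0:
            raise InvalidInputError(f"plot {self.plot_id}: age_years must be > 0")

    @property
    def richness(self) -> int:
        return len(self.composition)

    @property
    def proportions(self) -> dict[str, float]:
        """Planted proportions p_i (sum to 1)."""
        total = sum(self.composition.values())
        return {sp: n / total for sp, n in self.composition.items()}


# ---------------------------------------------------------------------------
# core arithmetic


def equivalent_diameter(stems: Sequence[float]) -> float:
    """Collapse a multi-stemmed tree to one basal-area-conserving diameter.

    D = sqrt(sum_i d_i^2): the unique single diameter whose circular
    cross-section equals the summed cross-sections of the stems.
    """
    stems = list(stems)
    if not stems:
        raise InvalidInputError("equivalent_diameter: empty stem list")
    if any(d <= 0 for d in stems):
        raise InvalidInputError("equivalent_diameter: non-positive stem diameter")
    return math.sqrt(sum(d * d for d in stems))


def tree_basal_area(diameter_cm: float) -> float:
    """Basal area (m^2) of a stem of the given diameter (cm): pi (d/2)^2."""
    if diameter_cm <= 0:
        raise InvalidInputError("tree_basal_area: diameter must be > 0")
    return math.pi * (diameter_cm / (2 * _CM_PER_M)) ** 2


def _record_basal_area(tree: TreeRecord, include_dead: bool) -> float:
    if not tree.in_sample:
        return 0.0
    if not tree.alive and not include_dead:
        return 0.0
    if not tree.stems:
        return 0.0
    return tree_basal_area(equivalent_diameter(tree.stems))


def plot_productivity(
    trees: Iterable[TreeRecord], design: PlotDesign, include_dead: bool = False
) -> float:
    """Annual basal-area increment per hectare for one plot.

    Sums basal area over live in-sample trees, divides by the sampled
    fraction (so partial inventories extrapolate to the full plot), by plot
    area and by stand age. Dead trees contribute zero unless
    ``include_dead`` retains their last-known size.
    """
    total = 0.0
    for tree in trees:
        if tree.plot_id != design.plot_id:
            raise ConsistencyError(
                f"tree {tree.tree_id} belongs to plot {tree.plot_id}, not {design.plot_id}"
            )
        total += _record_basal_area(tree, include_dead)
    return total / design.sampled_fraction / design.area_ha / design.age_years


def species_productivity(
    trees: Iterable[TreeRecord],
    design: PlotDesign,
    species: str,
    include_dead: bool = False,
) -> float:
    """Per-species share of plot productivity; sums over species to the plot value."""
    if species not in design.composition:
        raise InvalidInputError(f"species {species!r} not planted in plot {design.plot_id}")
    return plot_productivity(
        [t for t in trees if t.species == species], design, include_dead=include_dead
    )


# ---------------------------------------------------------------------------
# table-level (vectorized) computations


def _stem_sumsq(stems: Sequence[float]) -> float:
    return float(sum(d * d for d in stems))


def productivity_table(trees: pd.DataFrame, plots: pd.DataFrame, include_dead: bool = False) -> pd.DataFrame:
    """Plot-level productivity for whole tables.

    Returns one row per plot: (plot_id, experiment, block, richness, age_years,
    productivity), including plots with no surviving trees (productivity 0).
    """
    unknown = set(trees["plot_id"]) - set(plots["plot_id"])
    if unknown:
        raise ConsistencyError(f"trees reference unknown plots: {sorted(unknown)[:5]}")
    use = trees[trees["in_sample"].astype(bool)]
    if not include_dead:
        use = use[use["alive"].astype(bool)]
    sumsq = use["stems"].map(_stem_sumsq)
    ba = math.pi * sumsq / (2 * _CM_PER_M) ** 2
    plot_ba = ba.groupby(use["plot_id"].to_numpy()).sum()
    out = plots.copy()
    out["total_ba_m2"] = out["plot_id"].map(plot_ba).fillna(0.0)
    out["richness"] = out["composition"].map(len)
    out["productivity"] = (
        out["total_ba_m2"] / out["sampled_fraction"] / out["area_ha"] / out["age_years"]
    )
    return out[
        ["plot_id", "experiment", "block", "richness", "age_years", "productivity"]
    ].reset_index(drop=True)


def species_productivity_table(
    trees: pd.DataFrame, plots: pd.DataFrame, include_dead: bool = False
) -> pd.DataFrame:
    """Long table of per-species productivity: (plot_id, species, productivity).

    Every planted species appears, including those with no surviving trees
    (productivity 0); within each plot the values sum to the plot total.
    """
    unknown = set(trees["plot_id"]) - set(plots["plot_id"])
    if unknown:
        raise ConsistencyError(f"trees reference unknown plots: {sorted(unknown)[:5]}")
    use = trees[trees["in_sample"].astype(bool)]
    if not include_dead:
        use = use[use["alive"].astype(bool)]
    sumsq = use["stems"].map(_stem_sumsq)
    ba = math.pi * sumsq / (2 * _CM_PER_M) ** 2
    key = pd.MultiIndex.from_arrays([use["plot_id"], use["species"]])
    ba_by = ba.groupby(key).sum()

    rows = []
    for plot in plots.itertuples(index=False):
        scale = plot.sampled_fraction * plot.area_ha * plot.age_years
        for sp in plot.composition:
            total = ba_by.get((plot.plot_id, sp), 0.0)
            rows.append((plot.plot_id, plot.experiment, sp, total / scale))
    return pd.DataFrame(rows, columns=["plot_id", "experiment", "species", "productivity"])


def live_species_counts(trees: pd.DataFrame) -> pd.DataFrame:
    """Counts of live in-sample trees per (plot_id, species) — the FDis/CWM abundances."""
    use = trees[trees["alive"].astype(bool) & trees["in_sample"].astype(bool)]
    out = (
        use.groupby(["plot_id", "species"], sort=True).size().rename("count").reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# CSV I/O


def _encode_stems(stems: Sequence[float]) -> str:
    return ";".join(repr(float(d)) for d in stems)


def _decode_stems(text) -> list[float]:
    if isinstance(text, (int, float, np.floating, np.integer)):
        return [] if pd.isna(text) else [float(text)]
    if not isinstance(text, str) or not text:
        return []
    return [float(tok) for tok in text.split(";")]


def _encode_composition(comp: Mapping[str, int]) -> str:
    return ";".join(f"{sp}:{int(n)}" for sp, n in sorted(comp.items()))


def _decode_composition(text: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for tok in str(text).split(";"):
        sp, _, n = tok.partition(":")
        out[sp] = int(n)
    return out


def write_trees(trees: pd.DataFrame, path) -> None:
    df = trees.copy()
    df["stems"] = df["stems"].map(_encode_stems)
    df["alive"] = df["alive"].astype(int)
    df["in_sample"] = df["in_sample"].astype(int)
    df[TREE_COLUMNS].to_csv(path, index=False)


def read_trees(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a tree table; ``column_map`` renames source columns to the canonical
    schema (this is how external deposit schemas are adapted — see
    :data:`DRYAD_TREE_COLUMNS`). Unknown columns are ignored."""
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in TREE_COLUMNS if c not in df.columns and c != "height_m"]
    if missing:
        raise InvalidInputError(f"tree table missing columns: {missing}")
    if "height_m" not in df.columns:
        df["height_m"] = np.nan
    df["stems"] = df["stems"].map(_decode_stems)
    df["alive"] = df["alive"].astype(bool)
    df["in_sample"] = df["in_sample"].astype(bool)
    return df[TREE_COLUMNS]


def write_plots(plots: pd.DataFrame, path) -> None:
    df = plots.copy()
    df["composition"] = df["composition"].map(_encode_composition)
    df["abiotic_manipulation"] = df["abiotic_manipulation"].astype(int)
    df[PLOT_COLUMNS].to_csv(path, index=False)


def read_plots(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    optional = {"abiotic_manipulation": 0, "height_diam_interval_yr": 0.0, "sampled_fraction": 1.0}
    for col, default in optional.items():
        if col not in df.columns:
            df[col] = default
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"plot table missing columns: {missing}")
    df["composition"] = df["composition"].map(_decode_composition)
    df["abiotic_manipulation"] = df["abiotic_manipulation"].astype(bool)
    return df[PLOT_COLUMNS]


def write_traits(traits: pd.DataFrame, path) -> None:
    traits[TRAIT_COLUMNS].to_csv(path, index=False)


def read_traits(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "provenance" not in df.columns:
        df["provenance"] = "literature"
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"trait table missing columns: {missing}")
    bad = df[(df[["wd", "lnc", "sla"]] <= 0).any(axis=1)]
    if len(bad):
        raise InvalidInputError(f"non-positive trait values for species {list(bad['species'])[:5]}")
    return df[TRAIT_COLUMNS]


def validate_traits(traits: pd.DataFrame, plots: pd.DataFrame) -> None:
    """Every species planted anywhere must have a trait row."""
    planted: set[str] = set()
    for comp in plots["composition"]:
        planted.update(comp)
    missing = planted - set(traits["species"])
    if missing:
        raise ConsistencyError(f"species missing from trait table: {sorted(missing)}")


#: example column-name mapping for a Dryad-style deposited archive, applied
#: via the ``column_map`` argument of the readers; adjust the keys to the
#: actual deposit's headers. The data itself stays external to this package.
DRYAD_TREE_COLUMNS = {
    "treeID": "tree_id",
    "plotID": "plot_id",
    "species_name": "species",
    "stem_diameters_cm": "stems",
    "height_m": "height_m",
    "alive": "alive",
    "sampled": "in_sample",
}
DRYAD_PLOT_COLUMNS = {
    "plotID": "plot_id",
    "experiment_name": "experiment",
    "block": "block",
    "composition": "composition",
    "plot_area_ha": "area_ha",
    "prop_area_sampled": "sampled_fraction",
    "stand_age_yr": "age_years",
}


def records_from_table(trees: pd.DataFrame) -> list[TreeRecord]:
    """Materialize TreeRecord objects (with validation) from a tree table."""
    return [
        TreeRecord(
            tree_id=str(r.tree_id),
            plot_id=str(r.plot_id),
            species=str(r.species),
            stems=list(r.stems),
            height_m=None if pd.isna(r.height_m) else float(r.height_m),
            alive=bool(r.alive),
            in_sample=bool(r.in_sample),
        )
        for r in trees.itertuples(index=False)
    ]


def design_from_row(row) -> PlotDesign:
    """Build a validated PlotDesign from one plot-table row (namedtuple or Series)."""
    get = row._asdict() if hasattr(row, "_asdict") else dict(row)
    return PlotDesign(
        plot_id=str(get["plot_id"]),
        experiment=str(get["experiment"]),
        block=str(get["block"]),
        composition=get["composition"],
        area_ha=float(get["area_ha"]),
        sampled_fraction=float(get.get("sampled_fraction", 1.0)),
        age_years=float(get.get("age_years", 1.0)),
        abiotic_manipulation=bool(get.get("abiotic_manipulation", False)),
        height_diam_interval_yr=float(get.get("height_diam_interval_yr", 0.0)),
    )
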