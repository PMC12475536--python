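"""Functional identity/diversity and structural diversity metrics.

Functional identity is summarized by community-weighted means (CWM) of wood
density (WD) and leaf nitrogen content (LNC); functional diversity by
functional dispersion (FDis): the abundance-weighted mean distance of the
species present to the abundance-weighted centroid of trait space. FDis is
computed per single trait (FDis_WD, FDis_LNC) and on the full trait profile
(FDis_all), with traits z-scored across the species pool first so axes are
commensurable.

Structural diversity is inequality of individual tree heights within a plot:
the Gini coefficient (population n^2 denominator) and the coefficient of
variation (sample SD / mean). Both are relative metrics — invariant to
uniform height scaling — so they measure size hierarchy, not stature.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, RankWarning, UndefinedMetricError
import warnings


def cwm(abundances: Mapping[str, float], trait: Mapping[str, float]) -> float:
    """Community-weighted mean: sum(a_j x_j) / sum(a_j) over species with a_j > 0."""
    pairs = [(a, trait[sp]) for sp, a in abundances.items() if a > 0]
    if any(a < 0 for a in abundances.values()):
        raise InvalidInputError("cwm: negative abundance")
    if not pairs:
        raise UndefinedMetricError("cwm: all abundances zero")
    total = sum(a for a, _ in pairs)
    return sum(a * x for a, x in pairs) / total


def fdis(abundances: Mapping[str, float], traits: Mapping[str, Sequence[float]]) -> float:
    """Functional dispersion: weighted mean Euclidean distance to the weighted centroid.

    ``traits`` maps species to a trait vector (all the same length); pass
    1-vectors for a single-trait FDis. Monocultures return exactly 0.
    """
    if any(a < 0 for a in abundances.values()):
        raise InvalidInputError("fdis: negative abundance")
    species = [sp for sp, a in abundances.items() if a > 0]
    if not species:
        raise UndefinedMetricError("fdis: all abundances zero")
    vecs = [np.atleast_1d(np.asarray(traits[sp], dtype=float)) for sp in species]
    if len({v.shape for v in vecs}) > 1:
        raise InvalidInputError("fdis: trait vectors of unequal length")
    x = np.vstack(vecs)
    a = np.asarray([abundances[sp] for sp in species], dtype=float)
    w = a / a.sum()
    centroid = w @ x
    dist = np.linalg.norm(x - centroid, axis=1)
    return float(w @ dist)


def gini(values: Sequence[float]) -> float:
    """Gini coefficient, population form: sum_ij |x_i - x_j| / (2 n^2 mean)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidInputError("gini: need at least 2 values")
    if np.any(x < 0):
        raise InvalidInputError("gini: negative values")
    mean = x.mean()
    if mean <= 0:
        raise UndefinedMetricError("gini: zero mean")
    # O(n log n) via sorted form: G = (2 sum_i i*x_(i) / (n sum x)) - (n+1)/n
    xs = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float(2 * (ranks @ xs) / (n * xs.sum()) - (n + 1) / n)


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidInputError("cv: need at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise UndefinedMetricError("cv: zero mean")
    return float(x.std(ddof=1) / mean)


def trait_pca(traits: pd.DataFrame, columns: Sequence[str] = ("wd", "lnc", "sla")):
    """PCA of the species x trait matrix after z-scoring each trait.

    Returns ``(loadings, fractions)``: orthonormal loadings (rows = components,
    columns = traits, as a DataFrame) and the variance fractions per component
    (non-increasing, summing to 1). Equivalent to an eigendecomposition of the
    trait correlation matrix.
    """
    x = traits.loc[:, list(columns)].to_numpy(dtype=float)
    n, p = x.shape
    if n < p:
        warnings.warn(f"trait_pca: only {n} species for {p} traits", RankWarning)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0) or n < 2:
        raise UndefinedMetricError("trait_pca: a trait has zero variance across species")
    z = (x - x.mean(axis=0)) / sd
    corr = z.T @ z / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    fractions = evals / evals.sum()
    loadings = pd.DataFrame(
        evecs.T, index=[f"PC{i+1}" for i in range(p)], columns=list(columns)
    )
    return loadings, fractions


# ---------------------------------------------------------------------------
# plot-level metric table

#: minimum number of measured heights for structural diversity to be defined
MIN_HEIGHTS = 2


def plot_metrics(
    trees: pd.DataFrame,
    plots: pd.DataFrame,
    traits: pd.DataFrame,
    structural_metric: str = "gini",
) -> pd.DataFrame:
    """One row of raw diversity metrics per plot.

    Abundances are counts of live in-sample trees at the inventory. Trait
    axes are z-scored across the supplied species pool before any FDis;
    CWMs stay in native trait units. Heights come only from live in-sample
    trees with a measurement; plots with fewer than :data:`MIN_HEIGHTS`
    measured heights get NaN structural diversity.
    """
    from .inventory import live_species_counts, productivity_table, validate_traits

    validate_traits(traits, plots)
    trait_idx = traits.set_index("species")
    zt = trait_idx[["wd", "lnc", "sla"]].copy()
    sd = zt.std(ddof=1)
    if (sd == 0).any():
        sd = sd.replace(0, 1.0)
    zt = (zt - zt.mean()) / sd

    counts = live_species_counts(trees)
    counts_by_plot = {k: dict(zip(g["species"], g["count"])) for k, g in counts.groupby("plot_id")}

    live = trees[trees["alive"].astype(bool) & trees["in_sample"].astype(bool)]
    heights = live[live["height_m"].notna()]
    heights_by_plot = {k: g["height_m"].to_numpy(float) for k, g in heights.groupby("plot_id")}

    prod = productivity_table(trees, plots).set_index("plot_id")

    rows = []
    for plot in plots.itertuples(index=False):
        ab = counts_by_plot.get(plot.plot_id, {})
        row = {
            "plot_id": plot.plot_id,
            "experiment": plot.experiment,
            "block": plot.block,
            "richness": len(plot.composition),
            "productivity": prod.loc[plot.plot_id, "productivity"],
        }
        if ab:
            wd = trait_idx["wd"].to_dict()
            lnc = trait_idx["lnc"].to_dict()
            row["cwm_wd"] = cwm(ab, wd)
            row["cwm_lnc"] = cwm(ab, lnc)
            row["fdis_wd"] = fdis(ab, {sp: [zt.at[sp, "wd"]] for sp in ab})
            row["fdis_lnc"] = fdis(ab, {sp: [zt.at[sp, "lnc"]] for sp in ab})
            row["fdis_all"] = fdis(ab, {sp: zt.loc[sp].to_numpy() for sp in ab})
        else:  # every planted tree dead: no community to describe
            row.update(
                cwm_wd=np.nan, cwm_lnc=np.nan, fdis_wd=np.nan, fdis_lnc=np.nan, fdis_all=np.nan
            )
        h = heights_by_plot.get(plot.plot_id)
        if h is not None and h.size >= MIN_HEIGHTS and h.mean() > 0:
            row["gini_height"] = gini(h)
            row["cv_height"] = cv(h)
            row["n_heights"] = int(h.size)
        else:
            row["gini_height"] = np.nan
            row["cv_height"] = np.nan
            row["n_heights"] = 0 if h is None else int(h.size)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["structural"] = out["gini_height"] if structural_metric == "gini" else out["cv_height"]
    return out
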