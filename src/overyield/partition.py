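"""Additive partitioning of the net diversity effect (Loreau & Hector 2001).

For a mixture of N species with planted proportions p_i, observed per-species
yields Y_i and monoculture references M_i, define the relative-yield
deviations dRY_i = Y_i / M_i - p_i. Then

    NBE = sum_i Y_i - sum_i p_i M_i          (net biodiversity effect)
    CE  = N * mean(dRY) * mean(M)            (complementarity effect)
    SE  = N * cov_pop(dRY, M)                (selection effect)

with the population covariance (divide by N), under which SE + CE = NBE is
an algebraic identity, not an approximation. SE > 0 means species that are
already productive in monoculture overperform disproportionately in mixture;
CE > 0 means species overperform on average regardless of their monoculture
rank.

Monoculture references M_i are means over a species' monoculture plots
within the same experiment (blocks pooled). Mixtures containing a species
with no monoculture, or with M_i = 0, are flagged missing rather than
partitioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError


@dataclass
class PartitionResult:
    """Partition of one mixture plot's net diversity effect."""

    plot_id: str
    observed: float
    expected: float
    nbe: float
    se: float
    ce: float
    species: list[str] = field(default_factory=list)
    delta_ry: dict[str, float] = field(default_factory=dict)
    monoculture: dict[str, float] = field(default_factory=dict)


def monoculture_reference(plots: pd.DataFrame, plot_productivity: pd.Series) -> dict[str, dict[str, float]]:
    """Per-experiment monoculture reference M_i.

    ``plots`` is a plot design table; ``plot_productivity`` maps plot_id ->
    productivity. Returns {experiment: {species: mean monoculture
    productivity}}; species without a monoculture are simply absent.
    """
    refs: dict[str, dict[str, list[float]]] = {}
    for plot in plots.itertuples(index=False):
        if len(plot.composition) != 1:
            continue
        (sp,) = plot.composition
        refs.setdefault(plot.experiment, {}).setdefault(sp, []).append(
            float(plot_productivity[plot.plot_id])
        )
    return {
        exp: {sp: float(np.mean(v)) for sp, v in by_sp.items()} for exp, by_sp in refs.items()
    }


def expected_productivity(proportions: dict[str, float], M: dict[str, float]) -> float:
    """Expected mixture productivity sum_i p_i M_i from planted proportions."""
    missing = [sp for sp in proportions if sp not in M]
    if missing:
        raise InvalidInputError(f"no monoculture reference for species {missing}")
    return sum(p * M[sp] for sp, p in proportions.items())


def partition(
    plot_id: str,
    yields: dict[str, float],
    M: dict[str, float],
    proportions: dict[str, float],
) -> PartitionResult:
    """Partition one mixture plot; raises on N < 2 or non-positive M_i."""
    species = sorted(yields)
    n = len(species)
    if n < 2:
        raise InvalidInputError("partition: need at least 2 species (mixtures only)")
    if sorted(proportions) != species:
        raise InvalidInputError("partition: yields and proportions must cover the same species")
    missing = [sp for sp in species if sp not in M]
    if missing:
        raise InvalidInputError(f"partition: no monoculture reference for {missing}")
    m = np.array([M[sp] for sp in species], float)
    if np.any(m <= 0):
        raise InvalidInputError("partition: non-positive monoculture reference")
    y = np.array([yields[sp] for sp in species], float)
    p = np.array([proportions[sp] for sp in species], float)

    dry = y / m - p
    observed = float(y.sum())
    expected = float(p @ m)
    nbe = observed - expected
    ce = n * dry.mean() * m.mean()
    cov_pop = float(np.mean((dry - dry.mean()) * (m - m.mean())))
    se = n * cov_pop
    return PartitionResult(
        plot_id=plot_id,
        observed=observed,
        expected=expected,
        nbe=nbe,
        se=se,
        ce=ce,
        species=species,
        delta_ry=dict(zip(species, dry)),
        monoculture=dict(zip(species, m)),
    )


def partition_table(
    plots: pd.DataFrame,
    plot_productivity: pd.Series,
    species_yields: pd.DataFrame,
    use_surviving_proportions: bool = False,
    surviving_counts: pd.DataFrame | None = None,
    return_details: bool = False,
):
    """Partition every mixture plot of every experiment.

    ``species_yields`` is the long (plot_id, species, productivity) table.
    Proportions default to planted counts; set ``use_surviving_proportions``
    (with a (plot_id, species, count) table) to weight by survivors instead.
    Plots whose reference is unavailable are returned with NaN effects and
    ``flag = 'missing_monoculture'`` rather than dropped silently.
    """
    refs = monoculture_reference(plots, plot_productivity)
    yields_by_plot = {
        k: dict(zip(g["species"], g["productivity"])) for k, g in species_yields.groupby("plot_id")
    }
    surv_by_plot = {}
    if use_surviving_proportions:
        if surviving_counts is None:
            raise InvalidInputError("surviving proportions requested but no counts supplied")
        surv_by_plot = {
            k: dict(zip(g["species"], g["count"])) for k, g in surviving_counts.groupby("plot_id")
        }

    rows = []
    details: list[PartitionResult] = []
    for plot in plots.itertuples(index=False):
        if len(plot.composition) < 2:
            continue
        M = refs.get(plot.experiment, {})
        total = sum(plot.composition.values())
        props = {sp: c / total for sp, c in plot.composition.items()}
        if use_surviving_proportions:
            counts = surv_by_plot.get(plot.plot_id, {})
            tot = sum(counts.get(sp, 0) for sp in plot.composition)
            if tot > 0:
                props = {sp: counts.get(sp, 0) / tot for sp in plot.composition}
        base = {
            "plot_id": plot.plot_id,
            "experiment": plot.experiment,
            "block": plot.block,
            "richness": len(plot.composition),
        }
        absent = [sp for sp in plot.composition if sp not in M or M.get(sp, 0) <= 0]
        if absent:
            rows.append(
                base
                | {
                    "observed": np.nan,
                    "expected": np.nan,
                    "nbe": np.nan,
                    "se": np.nan,
                    "ce": np.nan,
                    "flag": "missing_monoculture",
                }
            )
            continue
        yields = {sp: yields_by_plot.get(plot.plot_id, {}).get(sp, 0.0) for sp in plot.composition}
        res = partition(plot.plot_id, yields, M, props)
        details.append(res)
        rows.append(
            base
            | {
                "observed": res.observed,
                "expected": res.expected,
                "nbe": res.nbe,
                "se": res.se,
                "ce": res.ce,
                "flag": "ok",
            }
        )
    table = pd.DataFrame(rows)
    if return_details:
        return table, details
    return table


def delta_ry_table(results: list[PartitionResult]) -> pd.DataFrame:
    """Long per-species dRY table from a list of partition results."""
    rows = [
        (r.plot_id, sp, r.delta_ry[sp], r.monoculture[sp]) for r in results for sp in r.species
    ]
    return pd.DataFrame(rows, columns=["plot_id", "species", "delta_ry", "monoculture"])
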