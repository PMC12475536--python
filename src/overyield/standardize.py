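"""Grouped variable scaling applied per analysis subset.

Experiments differ hugely in absolute growth (biome, age, species pool), so
every variable that varies within experiments is rescaled within each
experiment before modelling: z-scores for productivity, CWMs and structural
diversity; min-max (0..1) for functional dispersion. Species trait values,
constant within an experiment, are z-scored across experiments instead.
Diversity effects (NBE/SE/CE) stay in m^2 ha^-1 yr^-1 — they are already
centred on each mixture's own monocultures.

Scalings are always recomputed on the data subset entering a given analysis,
never inherited from the full table; `apply_scaling` therefore operates on
(a copy of) whatever frame it is handed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateScalingWarning, InvalidInputError


def _grouped(values, groups):
    x = np.asarray(values, dtype=float)
    if groups is None:
        g = np.zeros(x.shape, dtype=int)
    else:
        g = np.asarray(groups)
        if g.shape != x.shape:
            raise InvalidInputError("groups must match values in length")
    return x, g


def zscore(values, groups=None) -> np.ndarray:
    """Per-group z-scores (sample SD). Zero-spread groups map to 0 with a warning."""
    x, g = _grouped(values, groups)
    out = np.empty_like(x)
    for key in np.unique(g):
        mask = g == key
        v = x[mask]
        sd = v.std(ddof=1) if v.size > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"zscore: group {key!r} has zero spread", DegenerateScalingWarning)
            out[mask] = 0.0
        else:
            out[mask] = (v - v.mean()) / sd
    return out


def minmax(values, groups=None) -> np.ndarray:
    """Per-group min-max scaling to [0, 1]. Zero-range groups map to 0 with a warning."""
    x, g = _grouped(values, groups)
    out = np.empty_like(x)
    for key in np.unique(g):
        mask = g == key
        v = x[mask]
        rng = v.max() - v.min()
        if rng == 0 or not np.isfinite(rng):
            warnings.warn(f"minmax: group {key!r} has zero range", DegenerateScalingWarning)
            out[mask] = 0.0
        else:
            out[mask] = (v - v.min()) / rng
    return out


@dataclass(frozen=True)
class ScalingRule:
    """How one variable is scaled: method in {zscore, minmax, none}; grouping in
    {within-experiment, across-experiments}."""

    variable: str
    method: str = "zscore"
    grouping: str = "within-experiment"

    def __post_init__(self):
        if self.method not in {"zscore", "minmax", "none"}:
            raise InvalidInputError(f"unknown scaling method {self.method!r}")
        if self.grouping not in {"within-experiment", "across-experiments"}:
            raise InvalidInputError(f"unknown grouping {self.grouping!r}")


#: the study's standard rule set, keyed by metric-table column name
DEFAULT_RULES: tuple[ScalingRule, ...] = (
    ScalingRule("productivity", "zscore"),
    ScalingRule("cwm_wd", "zscore"),
    ScalingRule("cwm_lnc", "zscore"),
    ScalingRule("gini_height", "zscore"),
    ScalingRule("cv_height", "zscore"),
    ScalingRule("structural", "zscore"),
    ScalingRule("fdis_wd", "minmax"),
    ScalingRule("fdis_lnc", "minmax"),
    ScalingRule("fdis_all", "minmax"),
    ScalingRule("wd", "zscore", "across-experiments"),
    ScalingRule("lnc", "zscore", "across-experiments"),
    ScalingRule("nbe", "none"),
    ScalingRule("se", "none"),
    ScalingRule("ce", "none"),
)


def apply_scaling(
    df: pd.DataFrame,
    rules: Sequence[ScalingRule] = DEFAULT_RULES,
    experiment_col: str = "experiment",
) -> pd.DataFrame:
    """Return a copy of ``df`` with each ruled column replaced by its scaled form.

    Rules naming columns absent from ``df`` are skipped, so one default rule
    set serves every analysis subset. NaNs are left NaN (scaled on the
    non-missing values of each group).
    """
    out = df.copy()
    for rule in rules:
        if rule.variable not in out.columns or rule.method == "none":
            continue
        col = out[rule.variable].to_numpy(dtype=float)
        mask = np.isfinite(col)
        if not mask.any():
            continue
        if rule.grouping == "within-experiment":
            if experiment_col not in out.columns:
                raise InvalidInputError(f"no {experiment_col!r} column for within-experiment rule")
            groups = out[experiment_col].to_numpy()[mask]
        else:
            groups = None
        fn = zscore if rule.method == "zscore" else minmax
        scaled = np.full_like(col, np.nan)
        scaled[mask] = fn(col[mask], groups)
        out[rule.variable] = scaled
    return out
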