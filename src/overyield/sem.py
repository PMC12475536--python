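"""Piecewise structural equation modelling with d-separation tests.

A piecewise SEM is a set of local regressions over a directed acyclic graph
(DAG): here richness -> structural diversity, richness -> functional
dispersion, and {richness, structural, FDis, optional interaction} ->
productivity, each fitted as a mixed model with composition and block
intercepts nested in experiment. Overall fit is judged by testing the
independence claims the DAG implies but the regressions do not use: for
every non-adjacent variable pair, the claim that they are independent given
the union of their parents. Each claim is tested by adding the claimed
independent variable to the mixed model of the pair's downstream member and
reading its two-tailed Wald p-value. The claim p-values combine into
Fisher's C = -2 sum(ln p_i) ~ chi-squared with 2k degrees of freedom; a
large p indicates the DAG is consistent with the data.

Path coefficients are reported standardized (beta * SD(x) / SD(y), SDs taken
on the analysis data), indirect effects as products of standardized
coefficients along directed routes, and per-submodel marginal R^2 as the
fixed-effect share of total modelled variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, InvalidInputError, InvalidModelError, UndefinedMetricError
from .mixedmodels import FitResult, ModelSpec, build_design, fit_lmm

_PLOT_GROUPS = (("experiment", "composition"), ("experiment", "block"))


@dataclass(frozen=True)
class Claim:
    """One independence claim: x and y independent given ``given``; tested with
    ``response`` as the regression's dependent variable."""

    x: str
    y: str
    given: tuple[str, ...]
    response: str


@dataclass(frozen=True)
class SemSpec:
    """The SEM variants fitted here, differing only in the productivity
    submodel's interaction term: 'none', 'richness:structural' or
    'fdis:structural'."""

    interaction: str = "richness:structural"
    structural_metric: str = "gini"  # which height-inequality metric feeds 'structural'
    groups: tuple[tuple[str, ...], ...] = _PLOT_GROUPS

    def __post_init__(self):
        if self.interaction not in {"none", "richness:structural", "fdis:structural"}:
            raise InvalidInputError(f"unknown interaction choice {self.interaction!r}")

    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(
            [
                ("richness", "structural"),
                ("richness", "fdis_all"),
                ("richness", "productivity"),
                ("structural", "productivity"),
                ("fdis_all", "productivity"),
            ]
        )
        return g

    def interaction_term(self) -> str | None:
        return {
            "none": None,
            "richness:structural": "richness:structural",
            "fdis:structural": "fdis_all:structural",
        }[self.interaction]


@dataclass
class SemResult:
    spec: SemSpec
    paths: pd.DataFrame                  # response, term, estimate, std_estimate, p
    claims: list[dict]                   # x, y, given, p
    c_stat: float
    df: int
    pvalue: float
    aic: float
    r2_marginal: dict[str, float]
    indirect: dict[str, float]
    total_richness_effect: float
    saturated: bool
    fits: dict[str, FitResult] = field(default_factory=dict)

    def report(self) -> str:
        lines = ["piecewise SEM" + (" (saturated)" if self.saturated else ""), ""]
        for row in self.paths.itertuples(index=False):
            lines.append(
                f"  {row.response} <- {row.term}: std {row.std_estimate:+.3f} (p={row.p:.3g})"
            )
        lines.append("")
        for c in self.claims:
            lines.append(
                f"  claim {c['x']} _||_ {c['y']} | {{{', '.join(c['given'])}}}: p={c['p']:.3g}"
            )
        if not self.saturated:
            lines.append(
                f"  Fisher's C = {self.c_stat:.3f}, df = {self.df}, p = {self.pvalue:.3f}"
            )
        lines.append(f"  AIC (sum of submodels) = {self.aic:.1f}")
        for resp, r2 in self.r2_marginal.items():
            lines.append(f"  marginal R2 [{resp}] = {r2:.3f}")
        for route, eff in self.indirect.items():
            lines.append(f"  indirect {route}: {eff:+.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# d-separation machinery


def basis_set(dag: nx.DiGraph) -> list[Claim]:
    """Independence claims for every non-adjacent pair of the DAG.

    Conditioning set: the union of both variables' parents. The regression
    response is the pair member later in topological order (the downstream
    one), matching how the claims are tested.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise InvalidModelError("SEM graph must be acyclic")
    order = list(nx.topological_sort(dag))
    pos = {v: i for i, v in enumerate(order)}
    claims = []
    nodes = sorted(dag.nodes, key=pos.get)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if dag.has_edge(u, v) or dag.has_edge(v, u):
                continue
            first, later = (u, v) if pos[u] < pos[v] else (v, u)
            cond = (set(dag.predecessors(u)) | set(dag.predecessors(v))) - {u, v}
            claims.append(Claim(x=first, y=later, given=tuple(sorted(cond)), response=later))
    return claims


def fishers_c(pvalues) -> tuple[float, int, float]:
    """Combine independence-claim p-values: C = -2 sum ln p, df = 2k, p from chi2."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise InvalidInputError("fishers_c: no claims (saturated model)")
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("fishers_c: p-values must lie in [0, 1]")
    df = 2 * p.size
    if np.any(p == 0):
        warnings.warn("fishers_c: a claim p-value of 0 gives infinite C", UserWarning)
        return math.inf, df, 0.0
    c = float(-2.0 * np.log(p).sum())
    return c, df, float(stats.chi2.sf(c, df))


def standardized_paths(fit: FitResult, data: pd.DataFrame, response: str) -> pd.Series:
    """beta * SD(term) / SD(response) for every non-intercept term of a fit."""
    sd_y = float(data[response].std(ddof=1))
    if sd_y == 0 or not np.isfinite(sd_y):
        raise UndefinedMetricError(f"zero-variance response {response!r}")
    terms = [t for t in fit.params.index if t != "(Intercept)"]
    X, names = build_design(data, terms)
    out = {}
    for j, term in enumerate(terms):
        sd_x = float(np.std(X[:, j + 1], ddof=1))
        if sd_x == 0:
            raise UndefinedMetricError(f"zero-variance predictor {term!r}")
        out[term] = float(fit.params[term]) * sd_x / sd_y
    return pd.Series(out)


def indirect_effect(coefficients) -> float:
    """Product of (standardized) path coefficients along one directed route."""
    coefs = list(coefficients)
    if not coefs:
        raise InvalidInputError("indirect_effect: empty route")
    return float(np.prod(coefs))


def _marginal_r2(fit: FitResult) -> float:
    var_fixed = float(np.var(fit.fitted))
    var_random = float(sum(fit.vc.values()))
    var_resid = float(math.exp(fit.disp_params.iloc[0]))
    return var_fixed / (var_fixed + var_random + var_resid)


# ---------------------------------------------------------------------------
# fitting


def fit_piecewise(spec: SemSpec, data: pd.DataFrame) -> SemResult:
    """Fit the SEM's submodels, test its basis set and assemble the result.

    ``data`` must carry richness, structural, fdis_all, productivity plus the
    grouping labels; rows with missing values in any of these are dropped
    (structural diversity is undefined for plots with < 2 measured heights).
    """
    needed = ["richness", "structural", "fdis_all", "productivity"] + sorted(
        {c for g in spec.groups for c in g}
    )
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise InvalidInputError(f"SEM data missing columns: {missing}")
    d = data.dropna(subset=["richness", "structural", "fdis_all", "productivity"]).reset_index(
        drop=True
    )
    if len(d) < 10:
        raise InvalidInputError("too few complete rows for SEM")

    dag = spec.dag()
    prod_terms = ["richness", "structural", "fdis_all"]
    inter = spec.interaction_term()
    if inter is not None:
        prod_terms.append(inter)
    submodels = {
        "structural": ModelSpec("structural", ("richness",), spec.groups),
        "fdis_all": ModelSpec("fdis_all", ("richness",), spec.groups),
        "productivity": ModelSpec("productivity", tuple(prod_terms), spec.groups),
    }

    fits: dict[str, FitResult] = {}
    failures = []
    for resp, ms in submodels.items():
        try:
            fits[resp] = fit_lmm(ms, d)
        except ConvergenceError as err:
            failures.append(f"{resp}: {err}")
    if failures:
        raise ConvergenceError(
            "SEM submodels failed to converge: " + "; ".join(failures), trace=failures
        )

    # d-separation claims: add the claimed-independent variable to the
    # response's submodel (same random structure) and Wald-test it
    claims = []
    for claim in basis_set(dag):
        other = claim.x if claim.response == claim.y else claim.y
        terms = tuple(dict.fromkeys(list(claim.given) + [other]))
        cm = ModelSpec(claim.response, terms, spec.groups)
        cf = fit_lmm(cm, d)
        claims.append(
            dict(x=claim.x, y=claim.y, given=list(claim.given), p=float(cf.pvalues[other]))
        )

    saturated = len(claims) == 0
    if saturated:
        c_stat, dof, pval = float("nan"), 0, float("nan")
    else:
        c_stat, dof, pval = fishers_c([c["p"] for c in claims])

    rows = []
    for resp, fit in fits.items():
        std = standardized_paths(fit, d, resp)
        for term in std.index:
            rows.append(
                dict(response=resp, term=term, estimate=float(fit.params[term]),
                     std_estimate=float(std[term]), p=float(fit.pvalues[term]))
            )
    paths = pd.DataFrame(rows)

    def _std(resp, term):
        hit = paths[(paths["response"] == resp) & (paths["term"] == term)]
        return float(hit["std_estimate"].iloc[0]) if len(hit) else float("nan")

    indirect = {
        "richness->structural->productivity": indirect_effect(
            [_std("structural", "richness"), _std("productivity", "structural")]
        ),
        "richness->fdis_all->productivity": indirect_effect(
            [_std("fdis_all", "richness"), _std("productivity", "fdis_all")]
        ),
    }
    direct = _std("productivity", "richness")
    total = direct + sum(indirect.values())

    return SemResult(
        spec=spec,
        paths=paths,
        claims=claims,
        c_stat=c_stat,
        df=dof,
        pvalue=pval,
        aic=float(sum(f.aic for f in fits.values())),
        r2_marginal={resp: _marginal_r2(f) for resp, f in fits.items()},
        indirect=indirect,
        total_richness_effect=total,
        saturated=saturated,
        fits=fits,
    )
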