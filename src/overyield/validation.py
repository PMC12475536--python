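"""Simulation studies that check the pipeline against its own ground truth.

Each routine generates data with known parameters, runs the corresponding
estimator, and reports recovery/calibration summaries. They are used by the
test suite and by the reproduction script; they are deliberately written as
library functions so the problem sizes are explicit at the call site.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import inventory as inv
from . import partition as pt
from .mixedmodels import fit_h1
from .sem import SemSpec, fit_piecewise
from .synthetic import (
    GeneratorConfig,
    generate,
    scenario,
    simulate_richness_response,
    simulate_sem_dataset,
)


def random_partition_identity(n: int = 1000, seed: int = 0) -> float:
    """Max |SE + CE - NBE| over random mixtures: the Loreau-Hector identity."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        k = int(rng.integers(2, 9))
        species = [f"s{i}" for i in range(k)]
        m = dict(zip(species, rng.lognormal(0.0, 1.0, k)))
        y = dict(zip(species, rng.lognormal(0.0, 1.0, k)))
        p_raw = rng.dirichlet(np.ones(k))
        p = dict(zip(species, p_raw))
        res = pt.partition("x", y, m, p)
        worst = max(worst, abs(res.se + res.ce - res.nbe))
    return worst


def h1_recovery_study(
    n_reps: int = 100,
    seed: int = 1,
    beta: tuple[float, float, float] = (0.0, 0.3, -0.03),
    disp_slope: float = -0.1,
    **sim_kwargs,
) -> dict:
    """Parameter recovery for the richness-productivity mixed model.

    For each replicate, draws a 20-experiment / 1500-plot dataset from the
    model's own structure and refits it; reports 95% Wald-CI coverage of the
    linear and quadratic terms and the rate at which the dispersion-slope
    sign is recovered.
    """
    ss = np.random.SeedSequence(seed).spawn(n_reps)
    cover1 = cover2 = sign_ok = 0
    est = []
    for r in range(n_reps):
        rep_seed = int(ss[r].generate_state(1)[0] % (2**31))
        data = simulate_richness_response(
            seed=rep_seed, beta=beta, disp_slope=disp_slope, **sim_kwargs
        )
        fit = fit_h1(data)
        ci = fit.conf_int()
        if ci.loc["richness", "lower"] <= beta[1] <= ci.loc["richness", "upper"]:
            cover1 += 1
        if ci.loc["richness^2", "lower"] <= beta[2] <= ci.loc["richness^2", "upper"]:
            cover2 += 1
        slope = float(fit.disp_params.iloc[1])
        if math.copysign(1.0, slope) == math.copysign(1.0, disp_slope):
            sign_ok += 1
        est.append((fit.params["richness"], fit.params["richness^2"], slope))
    est = np.asarray(est)
    return {
        "n_reps": n_reps,
        "coverage_linear": cover1 / n_reps,
        "coverage_quadratic": cover2 / n_reps,
        "dispersion_sign_rate": sign_ok / n_reps,
        "mean_estimates": est.mean(axis=0),
    }


def sem_calibration_study(
    n_reps: int = 200,
    seed: int = 7,
    violation: float = 0.0,
    n_plots: int = 1000,
    interaction: str = "none",
) -> dict:
    """Distribution of Fisher's C p-values over repeated fits.

    With ``violation = 0`` the fitted DAG is the truth and the p-values
    should be Uniform(0, 1) (KS test reported); with a nonzero
    structural -> FDis dependence the claim should reject, and the rejection
    rate at alpha = 0.05 is the d-separation test's power.
    """
    ss = np.random.SeedSequence(seed).spawn(n_reps)
    spec = SemSpec(interaction=interaction)
    pvals = []
    for r in range(n_reps):
        rep_seed = int(ss[r].generate_state(1)[0] % (2**31))
        data = simulate_sem_dataset(seed=rep_seed, n_plots=n_plots, violation=violation)
        res = fit_piecewise(spec, data)
        pvals.append(res.pvalue)
    pvals = np.asarray(pvals)
    ks = stats.kstest(pvals, "uniform")
    return {
        "n_reps": n_reps,
        "pvalues": pvals,
        "ks_pvalue": float(ks.pvalue),
        "rejection_rate": float(np.mean(pvals < 0.05)),
    }


def dataset_partition(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate one synthetic network and partition all its mixtures."""
    ds = generate(config)
    prod = inv.productivity_table(ds.trees, ds.plots)
    spt = inv.species_productivity_table(ds.trees, ds.plots)
    part = pt.partition_table(ds.plots, prod.set_index("plot_id")["productivity"], spt)
    return part[part["flag"] == "ok"], ds.truth


def selection_share_study(seeds=range(1, 21), scenario_name: str = "selection") -> pd.DataFrame:
    """Realized vs expected selection share of the net effect, per seed.

    The share is mean(SE) / mean(NBE) over all partitioned mixture plots;
    the band comes from the generator's truth record. Within-seed shares are
    ratio estimates over correlated plots, so individual seeds scatter
    around their expectation with an SD comparable to the band half-width;
    recovery claims should use :func:`selection_share_summary`.
    """
    rows = []
    for seed in seeds:
        part, truth = dataset_partition(scenario(scenario_name, seed=seed))
        share = float(part["se"].mean() / part["nbe"].mean())
        lo, hi = truth["se_share_band"]
        rows.append(
            dict(seed=seed, share=share, expected=truth["expected_se_share"],
                 lo=lo, hi=hi, within=bool(lo <= share <= hi))
        )
    return pd.DataFrame(rows)


def selection_share_summary(seeds=range(1, 21), scenario_name: str = "selection") -> dict:
    """Pooled recovery of the selection share across a multi-seed study.

    Compares the across-seed mean realized share with the mean truth-record
    expectation; ``within`` states whether the pooled deviation lies inside
    the truth record's tolerance.
    """
    table = selection_share_study(seeds=seeds, scenario_name=scenario_name)
    tol = float(scenario(scenario_name, seed=0).se_share_tolerance)
    share = float(table["share"].mean())
    expected = float(table["expected"].mean())
    return {
        "n_seeds": len(table),
        "share": share,
        "expected": expected,
        "abs_error": abs(share - expected),
        "tolerance": tol,
        "within": bool(abs(share - expected) <= tol),
        "per_seed": table,
    }
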