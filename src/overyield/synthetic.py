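"""Synthetic planted-diversity experiments with known ground truth.

The generator emulates the design of a network of young tree-diversity
experiments: multiple sites, each with its own species pool, randomized
blocks, replicated monocultures, and mixtures at richness levels up to six,
all planted at one date and inventoried once. It exists so that every stage
of the pipeline — productivity, diversity metrics, partitioning, the mixed
models and the SEM — can be exercised against a recorded truth without any
external data.

Mechanism (deliberately the simplest able to produce the qualitative
patterns of interest, not a process-based growth model): each species has a
trait syndrome (WD, LNC, SLA) drawn from a correlated Gaussian — SLA and LNC
share one axis (correlation 0.7), WD is independent, which puts ~57%/33% of
trait variance on the first two principal axes. An acquisitiveness score
A = z(LNC) - z(WD) sets the species' baseline annual diameter increment
g = g0 * exp(ga * A). A tree's realized increment multiplies baseline by
site, block and plot lognormal effects, a mixing response

    m = 1 + f(r) * (s * A + k * FDis_plot) - c * (r - 1),
    f(r) = 1 - exp(-(r-1)/tau)

(unity in monoculture), and mean-one lognormal tree noise. ``s`` boosts
acquisitive species in mixture (a selection mechanism: the gain covaries
with monoculture performance), ``k`` boosts every species in proportion to
the plot's functional dispersion (a complementarity mechanism), and the
linear mixing cost ``c`` is a uniform competitive burden that only
high-gain species overcome — it depresses complementarity and lets the
richness-productivity curve peak at intermediate richness. The
log-variance of the plot-level noise is linear in richness, giving the
dispersion trend the mixed models estimate. Mortality, multi-stem trees and
a power-law height-diameter allometry complete the inventory.

The truth record carries the injected parameters and the *expected*
NBE/SE/CE per mixture plot, computed by pushing the noise-free growth model
through the same partition arithmetic the analysis uses.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import fdis
from .errors import InvalidInputError
from .partition import partition

_BA = lambda d_cm: math.pi * (d_cm / 200.0) ** 2


@dataclass(frozen=True)
class GeneratorConfig:
    """All dials of the synthetic experiment network; ``seed`` is mandatory."""

    seed: int
    n_experiments: int = 21
    pool_size: int = 8
    richness_levels: tuple[int, ...] = (1, 2, 3, 4, 6)
    mixtures_per_level: int = 4
    mono_replicates: int = 2  # monoculture plots per species per block
    n_blocks: int = 2
    trees_per_plot: int = 36
    area_ha: float = 0.0144
    age_years: float = 9.0
    sampled_fraction: float = 1.0
    # trait syndrome (WD g cm^-3, LNC %, SLA cm^2 g^-1)
    wd_mean: float = 0.55
    wd_sd: float = 0.12
    lnc_mean: float = 2.2
    lnc_sd: float = 0.55
    sla_mean: float = 150.0
    sla_sd: float = 45.0
    sla_lnc_corr: float = 0.7
    # growth model
    g0: float = 1.0                 # cm / yr baseline diameter increment
    trait_growth: float = 0.18      # log-increment per unit acquisitiveness
    species_jitter_sd: float = 0.10
    site_sd: float = 0.25
    block_sd: float = 0.08
    plot_sd: float = 0.10
    tree_noise_sd: float = 0.22
    # mixing responses
    selection_strength: float = 0.0       # s
    complementarity_strength: float = 0.0  # k
    mixing_cost: float = 0.0              # uniform growth cost per added species
    richness_tau: float = 2.0
    dispersion_slope: float = -0.03  # d log(plot-noise variance) / d richness
    # demography and form
    mortality: float = 0.12
    multistem_prob: float = 0.08
    max_stems: int = 3
    height_a: float = 1.4
    height_b: float = 0.8
    height_noise_sd: float = 0.08
    n_height_lagged: int = 5  # experiments whose heights lag diameters > 1 yr
    #: half-width of the tolerance band around the expected SE share
    se_share_tolerance: float = 0.15

    def __post_init__(self):
        if max(self.richness_levels) > self.pool_size:
            raise InvalidInputError("richness level exceeds species pool size")
        if not all(0 <= p <= 1 for p in (self.mortality, self.multistem_prob)):
            raise InvalidInputError("probabilities must lie in [0, 1]")
        if abs(self.sla_lnc_corr) >= 1:
            raise InvalidInputError("sla_lnc_corr must form a positive-definite matrix")
        for r in self.richness_levels:
            if self.trees_per_plot % r:
                raise InvalidInputError(
                    f"trees_per_plot={self.trees_per_plot} not divisible by richness {r}"
                )


@dataclass
class SyntheticDataset:
    trees: pd.DataFrame
    plots: pd.DataFrame
    traits: pd.DataFrame
    truth: dict


def scenario(name: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Named presets.

    - ``null``: no mixing response (s = k = 0); NBE centred on zero.
    - ``selection``: acquisitive species gain in mixture (s > 0, k = 0).
    - ``complementarity``: all species gain with plot trait dispersion (k > 0).
    - ``paper_like``: both mechanisms, calibrated once so the selection effect
      carries roughly three quarters of the net effect, with a saturating
      richness response and a negative dispersion slope.
    """
    presets = {
        "null": dict(selection_strength=0.0, complementarity_strength=0.0),
        "selection": dict(selection_strength=0.15, complementarity_strength=0.0),
        "complementarity": dict(selection_strength=0.0, complementarity_strength=0.12),
        "paper_like": dict(selection_strength=0.10, complementarity_strength=0.005,
                           mixing_cost=0.005, richness_tau=1.5, dispersion_slope=-0.1),
    }
    if name not in presets:
        raise InvalidInputError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    return GeneratorConfig(seed=seed, **{**presets[name], **overrides})


def _mixing_multiplier(cfg: GeneratorConfig, acq: float, fdis_plot: float, richness: int) -> float:
    f = 1.0 - math.exp(-(richness - 1) / cfg.richness_tau)
    m = (
        1.0
        + f * (cfg.selection_strength * acq + cfg.complementarity_strength * fdis_plot)
        - cfg.mixing_cost * (richness - 1)
    )
    return max(m, 0.1)


def generate(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate the full experiment network; same config -> identical tables.

    Each experiment draws from its own random stream spawned from the master
    seed, so adding experiments never perturbs existing ones.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_experiments)
    tree_rows, plot_rows, trait_rows, truth_rows = [], [], [], []

    for e in range(cfg.n_experiments):
        rng = np.random.default_rng(streams[e])
        exp_id = f"E{e:02d}"
        pool = [f"{exp_id}_S{j}" for j in range(cfg.pool_size)]

        # correlated trait z-scores: lnc-sla share an axis, wd independent
        cov = np.array(
            [[1.0, 0.0, 0.0], [0.0, 1.0, cfg.sla_lnc_corr], [0.0, cfg.sla_lnc_corr, 1.0]]
        )
        z = rng.multivariate_normal(np.zeros(3), cov, size=cfg.pool_size)
        z_wd, z_lnc, z_sla = z[:, 0], z[:, 1], z[:, 2]
        wd = np.maximum(cfg.wd_mean + cfg.wd_sd * z_wd, 0.05)
        lnc = np.maximum(cfg.lnc_mean + cfg.lnc_sd * z_lnc, 0.2)
        sla = np.maximum(cfg.sla_mean + cfg.sla_sd * z_sla, 10.0)
        acq = z_lnc - z_wd
        jitter = rng.normal(0.0, cfg.species_jitter_sd, cfg.pool_size)
        baseline = cfg.g0 * np.exp(cfg.trait_growth * acq + jitter)
        sp_index = {sp: j for j, sp in enumerate(pool)}
        for j, sp in enumerate(pool):
            trait_rows.append(
                dict(species=sp, wd=wd[j], lnc=lnc[j], sla=sla[j],
                     class_="gymnosperm" if z_wd[j] > 1.0 else "angiosperm",
                     provenance="measured")
            )

        site_mult = math.exp(rng.normal(0.0, cfg.site_sd) - cfg.site_sd**2 / 2)
        block_mult = {
            f"B{b}": math.exp(rng.normal(0.0, cfg.block_sd) - cfg.block_sd**2 / 2)
            for b in range(cfg.n_blocks)
        }
        interval = 2.0 if e < cfg.n_height_lagged else 0.0

        # design: replicated monocultures + sampled mixtures, across blocks
        compositions: list[tuple[str, ...]] = [
            (sp,) for sp in pool for _ in range(cfg.mono_replicates)
        ]
        for r in cfg.richness_levels:
            if r == 1:
                continue
            seen = {c for c in compositions if len(c) == r}
            # cannot ask for more distinct mixtures than the pool admits
            target = min(cfg.mixtures_per_level, math.comb(cfg.pool_size, r))
            while len(seen) < target:
                comp = tuple(sorted(rng.choice(pool, size=r, replace=False)))
                seen.add(comp)
            compositions.extend(sorted(seen))

        # z-scored traits for the plot FDis entering the mixing response
        ztr = np.column_stack([z_wd, z_lnc, z_sla])

        plot_counter = 0
        for comp in compositions:
            r = len(comp)
            idx = [sp_index[sp] for sp in comp]
            if r > 1:
                ab = {sp: 1 for sp in comp}
                fd = fdis(ab, {sp: ztr[sp_index[sp]] for sp in comp})
            else:
                fd = 0.0
            counts = {sp: cfg.trees_per_plot // r for sp in comp}
            mult = {
                sp: _mixing_multiplier(cfg, acq[sp_index[sp]], fd, r) for sp in comp
            }
            for block in sorted(block_mult):
                plot_id = f"{exp_id}_P{plot_counter:03d}"
                plot_counter += 1
                plot_logvar = 2 * math.log(cfg.plot_sd) + cfg.dispersion_slope * (r - 1)
                plot_noise_sd = math.exp(plot_logvar / 2)
                plot_mult = math.exp(rng.normal(0.0, plot_noise_sd) - plot_noise_sd**2 / 2)
                plot_rows.append(
                    dict(plot_id=plot_id, experiment=exp_id, block=block,
                         composition=dict(counts), area_ha=cfg.area_ha,
                         sampled_fraction=cfg.sampled_fraction, age_years=cfg.age_years,
                         abiotic_manipulation=False, height_diam_interval_yr=interval)
                )
                t = 0
                for sp in comp:
                    j = sp_index[sp]
                    n_sp = counts[sp]
                    noise = rng.normal(0.0, cfg.tree_noise_sd, n_sp)
                    incr = (
                        baseline[j] * site_mult * block_mult[block] * plot_mult * mult[sp]
                        * np.exp(noise - cfg.tree_noise_sd**2 / 2)
                    )
                    diam = np.maximum(incr * cfg.age_years, 0.1)
                    dead = rng.random(n_sp) < cfg.mortality
                    multi = rng.random(n_sp) < cfg.multistem_prob
                    hnoise = rng.normal(0.0, cfg.height_noise_sd, n_sp)
                    heights = cfg.height_a * diam**cfg.height_b * np.exp(hnoise)
                    in_sample = (
                        rng.random(n_sp) < cfg.sampled_fraction
                        if cfg.sampled_fraction < 1
                        else np.ones(n_sp, bool)
                    )
                    for i in range(n_sp):
                        d = float(diam[i])
                        if dead[i]:
                            # died partway; last-known size is a fraction of final
                            d *= float(rng.uniform(0.3, 0.8))
                        if multi[i]:
                            n_stems = int(rng.integers(2, cfg.max_stems + 1))
                            w = rng.dirichlet(np.full(n_stems, 2.0))
                            stems = list(d * np.sqrt(w))
                        else:
                            stems = [d]
                        tree_rows.append(
                            dict(tree_id=f"{plot_id}_T{t:03d}", plot_id=plot_id,
                                 species=sp,
                                 stems=stems,
                                 height_m=float("nan") if dead[i] else float(heights[i]),
                                 alive=not dead[i], in_sample=bool(in_sample[i]))
                        )
                        t += 1

                # truth: noise-free expected partition for this mixture plot
                if r > 1:
                    scale = cfg.area_ha * cfg.age_years
                    surv = 1.0 - cfg.mortality
                    M = {
                        sp: cfg.trees_per_plot * surv
                        * _BA(baseline[sp_index[sp]] * cfg.age_years) / scale
                        for sp in comp
                    }
                    Y = {
                        sp: counts[sp] * surv
                        * _BA(baseline[sp_index[sp]] * mult[sp] * cfg.age_years) / scale
                        for sp in comp
                    }
                    props = {sp: counts[sp] / cfg.trees_per_plot for sp in comp}
                    res = partition(plot_id, Y, M, props)
                    truth_rows.append(
                        dict(plot_id=plot_id, experiment=exp_id, richness=r,
                             nbe=res.nbe, se=res.se, ce=res.ce)
                    )

    trees = pd.DataFrame(tree_rows)
    plots = pd.DataFrame(plot_rows)
    traits = pd.DataFrame(trait_rows).rename(columns={"class_": "class"})
    expected = pd.DataFrame(truth_rows)
    total_nbe = float(expected["nbe"].mean()) if len(expected) else 0.0
    share = (
        float(expected["se"].mean() / expected["nbe"].mean())
        if len(expected) and abs(expected["nbe"].mean()) > 1e-12
        else float("nan")
    )
    truth = {
        "config": asdict(cfg),
        "expected_partition": expected,
        "expected_mean_nbe": total_nbe,
        "expected_se_share": share,
        "se_share_band": (share - cfg.se_share_tolerance, share + cfg.se_share_tolerance)
        if np.isfinite(share)
        else (float("nan"), float("nan")),
    }
    return SyntheticDataset(trees=trees, plots=plots, traits=traits, truth=truth)


# ---------------------------------------------------------------------------
# direct simulators for model-level studies (no trees involved)


def simulate_richness_response(
    seed: int,
    n_experiments: int = 20,
    plots_per_experiment: int = 75,
    comps_per_experiment: int = 24,
    n_blocks: int = 3,
    beta: Sequence[float] = (0.0, 0.3, -0.03),
    sd_comp: float = 0.3,
    sd_block: float = 0.2,
    disp_intercept: float = -1.0,
    disp_slope: float = -0.1,
) -> pd.DataFrame:
    """Plot table drawn directly from the richness-productivity model:

    y = b0 + b1 r + b2 r^2 + u_comp + u_block + e,  Var(e) = exp(d0 + d1 r),

    with compositions nested in experiments (each composition has a fixed
    richness) and blocks nested in experiments. Used for parameter-recovery
    studies of the mixed-model fitter.
    """
    rng = np.random.default_rng(seed)
    rows = []
    b0, b1, b2 = beta
    for e in range(n_experiments):
        exp_id = f"X{e:02d}"
        comp_rich = [(f"{exp_id}_C{c:02d}", 1 + c % 6) for c in range(comps_per_experiment)]
        u_comp = {c: rng.normal(0.0, sd_comp) for c, _ in comp_rich}
        u_block = {f"B{b}": rng.normal(0.0, sd_block) for b in range(n_blocks)}
        for p in range(plots_per_experiment):
            comp, r = comp_rich[p % len(comp_rich)]
            block = f"B{p % n_blocks}"
            resid_sd = math.exp(0.5 * (disp_intercept + disp_slope * r))
            y = b0 + b1 * r + b2 * r * r + u_comp[comp] + u_block[block] + rng.normal(0, resid_sd)
            rows.append(
                dict(experiment=exp_id, composition=comp, block=block, richness=r,
                     productivity=y)
            )
    return pd.DataFrame(rows)


def simulate_sem_dataset(
    seed: int,
    n_plots: int = 1000,
    n_experiments: int = 8,
    comps_per_experiment: int = 15,
    n_blocks: int = 2,
    paths: dict | None = None,
    violation: float = 0.0,
    re_sd: float = 0.15,
) -> pd.DataFrame:
    """Plot table drawn directly from the SEM's own DAG.

    richness (z-scored levels 1..6) drives structural diversity and
    functional dispersion, which with richness (and an optional
    richness x structural interaction) drive productivity. ``violation``
    adds a structural -> FDis path absent from the fitted DAG, the
    misspecification the d-separation test should detect. Residual scales
    are chosen so all variables are approximately unit-variance, making raw
    and standardized paths comparable.
    """
    p = dict(rs=0.38, rf=0.59, sp=-0.55, fp=0.27, rp=0.03, interaction=0.0)
    if paths:
        p.update(paths)
    rng = np.random.default_rng(seed)
    rows = []
    per_exp = n_plots // n_experiments

    def resid_sd(explained):
        return math.sqrt(max(1.0 - explained - 2 * re_sd**2, 0.05))

    for e in range(n_experiments):
        exp_id = f"X{e:02d}"
        comps = [f"{exp_id}_C{c:02d}" for c in range(comps_per_experiment)]
        u = {
            var: {c: rng.normal(0, re_sd) for c in comps} for var in ("s", "f", "y")
        }
        ub = {
            var: {f"B{b}": rng.normal(0, re_sd) for b in range(n_blocks)}
            for var in ("s", "f", "y")
        }
        for i in range(per_exp):
            comp = comps[i % len(comps)]
            block = f"B{i % n_blocks}"
            r = 1 + (i % 6)
            rz = (r - 3.5) / 1.7078  # z-score of uniform levels 1..6
            s = p["rs"] * rz + u["s"][comp] + ub["s"][block] + rng.normal(0, resid_sd(p["rs"] ** 2))
            f = (
                p["rf"] * rz + violation * s + u["f"][comp] + ub["f"][block]
                + rng.normal(0, resid_sd(p["rf"] ** 2 + violation**2))
            )
            explained_y = p["rp"] ** 2 + p["sp"] ** 2 + p["fp"] ** 2 + p["interaction"] ** 2
            y = (
                p["rp"] * rz + p["sp"] * s + p["fp"] * f + p["interaction"] * rz * s
                + u["y"][comp] + ub["y"][block] + rng.normal(0, resid_sd(explained_y))
            )
            rows.append(
                dict(experiment=exp_id, composition=comp, block=block, richness=rz,
                     structural=s, fdis_all=f, productivity=y)
            )
    return pd.DataFrame(rows)
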