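# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of the `overyield` pipeline. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Productivity from inventories

Stand productivity is annual basal-area increment per hectare. Every
inventory tree contributes π(d/200)² m² with d in cm; a multi-stemmed tree
contributes through the equivalent diameter D = sqrt(Σ dᵢ²), the unique
single-stem diameter with the same summed cross-section, so per-tree basal
area stays additive over stems. Plot totals are divided by the sampled
fraction (partial inventories extrapolate proportionally), by plot area
(ha) and by stand age (years since planting). Trees dead at the inventory
contribute zero by default — mortality lowers the live-tree sum — with an
`include_dead` option that retains the last recorded size instead; the
choice only matters for plots with heavy, size-biased mortality.

## Additive partitioning

The Loreau–Hector decomposition is computed per mixture plot from
per-species yields, planted proportions and monoculture references, with
the population covariance (divide by N), the convention under which
SE + CE = NBE is an exact algebraic identity rather than an approximation;
the test suite enforces it to 1e−10 on random inputs. Proportions come from
planted counts by default (a surviving-count option exists): the design
proportion is what the expectation "weighted mean of monocultures" refers
to at establishment. Monoculture references pool all of a species'
monoculture plots within an experiment (blocks are pooled; no block
matching is attempted). Mixtures containing a species with no monoculture,
or with a zero reference, are flagged missing rather than silently dropped
or zero-filled.

Because references are estimated from finitely many monoculture plots,
ΔRY = Y/M̂ − p inherits a Jensen-inequality bias (E[1/M̂] > 1/M) that
inflates CE and deflates SE by the same amount. With the default
replication (two monoculture plots per species per block) the bias is small
relative to the truth-band tolerance, but it is the reason the realized
selection share sits slightly below the noise-free expectation.

## Diversity metrics

CWMs weight trait values by counts of live trees at the inventory. FDis is
the abundance-weighted mean Euclidean distance of species to the
abundance-weighted trait centroid; trait axes are z-scored across the
species pool first (traits are experiment-constant, so the scaling is
across experiments), and Gower distances are unnecessary because all three
traits are quantitative. Structural diversity uses only trees with a height
measurement; plots with fewer than two measured heights yield missing
values and are excluded from the SEM subset. The Gini coefficient uses the
population (n²) denominator without small-sample correction and the CV uses
the sample SD — both choices only shift within-experiment z-scores by a
constant factor, so downstream models are unaffected; both metrics are
reported.

## Standardization

Experiments differ enormously in absolute growth, so all within-experiment
variables are rescaled inside each experiment: z-scores for productivity,
CWMs and structural diversity; min–max to [0, 1] for the FDis metrics.
Species trait values, constant within experiments, are z-scored across
experiments. NBE/SE/CE stay in m² ha⁻¹ yr⁻¹. Z-scores use the sample SD.
Scalings are recomputed on every analysis subset — the SEM's 16-experiment
subset gets its own scaling, not the full-table one — and degenerate groups
(zero spread) map to zero with a logged warning rather than dropping plots.

## Mixed models

All hypothesis models are Gaussian LMMs with random intercepts for species
composition and block nested in experiment (nesting is encoded by
concatenated labels, so each grouping is an independent intercept factor);
the species-level model adds an angiosperm/gymnosperm intercept nested in
experiment. The residual variance follows a log-linear dispersion submodel
exp(δ₀ + δ₁·richness); δ₁ is reported on this log-variance scale.

Estimation is marginal maximum likelihood: the fixed effects are profiled
out by GLS at each variance-parameter value and the variance parameters
(log σ²_g, δ₀, δ₁) are optimized by L-BFGS-B (Nelder–Mead fallback) on the
profile likelihood, computed through the Woodbury identity so only a q×q
system (q = number of random-effect levels) is ever factorized. ML rather
than REML is used throughout so that AIC comparisons across fixed-effect
structures are valid. Wald inference: t statistics with n − p residual
degrees of freedom for fixed effects; normal-approximation SEs for the
dispersion coefficients from the numerical Hessian. Random-effect variances
are bounded below at exp(−16); hitting the bound raises a singular-fit
warning but keeps the fit. The fitter is checked against closed forms: OLS
when no random terms are present, and the balanced one-way ANOVA ML
estimators (σ̂e² = MSW, σ̂b² = (SSB/k − MSW)/m).

The species-level response is ln(productivity + c) with c = half the
smallest positive species productivity in the analysis subset (recorded on
the fit, configurable). The response stays on its raw nonnegative scale —
a shifted log of a z-scored variable would make the constant rule
meaningless — and between-experiment scale differences are absorbed
additively on the log scale by the nested intercepts. Fitted curves are
back-transformed with exp(·) − c.

## Piecewise SEM

The DAG is richness → structural diversity, richness → FDis_all, and
{richness, structural, FDis_all, optional interaction} → productivity. The
basis set contains one claim per non-adjacent pair, conditioned on the
union of the pair's parents; with this DAG that is the single claim
FDis_all ⟂ structural | richness, hence 2 degrees of freedom. Claims are
tested by adding the claimed-independent variable to the mixed model of the
downstream member (same random structure) and reading its two-tailed Wald
p-value; p-values combine into Fisher's C = −2 Σ ln pᵢ against χ²(2k), so
with a single claim the SEM p equals the claim p exactly. Interaction terms
are product regressors, not DAG nodes, and never enter conditioning sets.
Standardized paths are β·SD(x)/SD(y) with SDs from the analysis data (the
SD of the product column, for interaction terms); indirect effects are
products of standardized coefficients along directed routes. Marginal R² is
the fixed-effect prediction variance over fixed + random + residual
variance. SEM submodels use constant residual variance (no dispersion
submodel), which R² derivation requires. The model AIC is the sum of
submodel AICs; the three variants (no interaction, richness × structural,
FDis × structural) and both structural metrics are compared this way in
`analysis/06_sem.py`.

## Synthetic experiment network

The generator emulates a network of young planted diversity experiments;
it is a study-design emulator, not a process-based forest model. Defaults
(the conditions under which all rate-based guarantees are stated): 21
experiments, pools of 8 species per experiment, richness levels
{1, 2, 3, 4, 6}, two blocks, two monoculture replicates per species per
block and four mixtures per richness level per experiment (1344 plots), 36
trees per plot on 0.0144 ha, inventoried at age 9 — roughly the scale of
the real experiment networks this emulates (~1600 plots, ~50 trees/plot,
mean age 9).

Species traits (WD 0.55 ± 0.12 g cm⁻³, LNC 2.2 ± 0.55 %, SLA 150 ± 45
cm² g⁻¹) are drawn with an SLA–LNC correlation of 0.7 and an independent WD
axis; the implied correlation-matrix eigenvalues put 56.7%/33.3% of
variance on the first two components, the classic two-axis resource-use
structure. Acquisitiveness A = z(LNC) − z(WD) sets baseline diameter
increment g = g₀·exp(0.18·A) (plus species lognormal jitter, SD 0.10). A
tree's increment multiplies baseline by lognormal site (SD 0.25), block
(0.08) and plot effects, by the mixing response

    m = 1 + f(r)·(s·A + k·FDis_plot) − c·(r − 1),   f(r) = 1 − e^{−(r−1)/τ}

(unity in monoculture), and by mean-one lognormal tree noise (SD 0.22).
Final diameter is increment × age; mortality (0.12) removes trees from the
live sum; multi-stem trees (8%) split the squared diameter across stems so
the equivalent diameter is conserved; heights follow h = 1.4·d^0.8 m with
lognormal noise. The log-variance of the plot-level noise is linear in
richness (the injected dispersion trend). Five experiments get a height
inventory lagging diameters by two years, so the SEM subset contains 16 of
21 experiments.

Mechanism semantics: `s` (selection) makes the mixture gain covary with
monoculture performance through A; `k` (complementarity) boosts every
species with the plot's trait dispersion; the linear mixing cost `c` is a
uniform competitive burden that only high-gain species overcome. Two
consequences are worth knowing. First, a pure `s` mechanism cannot push the
selection share of NBE above about (N−1)/N, because the partition assigns
1/N of any sampling effect to CE; the cost term is what lets the calibrated
`paper_like` preset (s = 0.10, k = 0.005, c = 0.005, τ = 1.5, dispersion
slope −0.1) reach a ~0.78 expected share, with a ±0.15 tolerance band fixed
in the truth record. Second, because growth noise is multiplicative,
overyielding raises the absolute spread at high richness; an injected
dispersion slope must be clearly negative (−0.1) for its sign to survive
this mean–variance coupling, which is why the sign-recovery property is
tested under the `null` scenario where no mean trend interferes.

The truth record pushes the noise-free growth model through the same
partition arithmetic the analysis uses, giving expected NBE/SE/CE per
mixture plot. On `paper_like` data the SEM d-separation test *rejects* the
three-node DAG — height inequality genuinely depends on trait dispersion
given richness in this generator (diverse growth rates spread heights) — so
SEM calibration and power are assessed on a direct DAG simulator
(`simulate_sem_dataset`), where the fitted DAG is exactly true under the
null and violated by a configurable structural → FDis path. Mixed-model
recovery likewise uses a direct simulator of the richness model's own
structure (20 experiments × 75 plots, compositions carrying fixed richness
levels, β = (0, 0.3, −0.03), dispersion slope ±0.1).

What passing tests on this generator do **not** show: realism of absolute
growth rates, spatially explicit competition, climate drivers, or temporal
dynamics of diversity effects; conclusions transfer to real inventories
only insofar as those share the design features emulated here.

## Numerical choices and degenerate inputs

- Optimizer: L-BFGS-B with log-variance bounds ±16 and dispersion-slope
  bounds ±8; ftol 1e−11. Non-convergence raises a diagnostic error carrying
  the optimizer trace.
- Profile quadratic forms are clipped at zero against round-off near
  perfect fits.
- Gini uses the O(n log n) sorted-rank form, equal to the pairwise sum to
  1e−10 (property-tested).
- PCA is an eigendecomposition of the trait correlation matrix; zero-variance
  traits raise a degenerate-input error, and fewer species than traits
  raises a rank warning.
- Empty communities, zero-mean height sets, zero-SD predictors and
  saturated SEMs each raise specific typed errors rather than propagating
  NaNs.

## Problem sizes

The simulation studies are sized to their guarantees: 100 replicates of
1500-plot mixed-model fits for CI coverage and dispersion-sign rates, 200
replicates for d-separation calibration (KS against uniform), 100 for
power, and 20 generator seeds for the selection-share band. The full suite
and the reproduction script each run in minutes on one CPU.
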