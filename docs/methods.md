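# Methods notes

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic data do and do not emulate. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Trees and units

Branch lengths are million years (My) throughout; no unit auto-detection.
Trees are rooted; soft polytomies are allowed (likelihood code treats them
as zero-length resolutions implicitly, since the pruning and covariance
algorithms only need parent links). Ultrametricity is checked against a
relative tolerance of 1e-6 × tree height, since dated trees from Bayesian
samplers carry rounding noise at that level. Tip labels are matched to
trait tables by exact string comparison after whitespace trimming; every
analysis proceeds on the tip-trait intersection, pruning tree and regime
painting consistently (the stem above the retained MRCA is dropped, as in
standard pruning tools).

## Mk models and stochastic mapping

The binary parity character evolves by a 2-state continuous-time Markov
chain. The 2×2 transition probabilities use the closed-form exponential.
Constraints: ER (one rate), SYM (identical to ER for two states, retained
so the three-way comparison mirrors standard usage), ARD (two rates).
Likelihoods by post-order pruning with log-scaling; AICc with n = number of
tips. Optimization is L-BFGS-B on log rates with five log-spaced starts in
[1e-4, 10] per My.

Root prior: stationary distribution of Q by default, with `flat` and
`fitted` (FitzJohn-style data weighting) switchable. The choice matters:
under the stationary prior the root mass is coupled to the rate asymmetry,
which is why an all-rates-different fit to a cleanly clustered derived
state does *not* drive the loss rate to zero — the brute-force likelihood
profile (a unit-test oracle) confirms the optimum is genuinely interior.

Stochastic maps are drawn with rates fixed at the ML estimate (empirical
Bayes without Q resampling): node states are sampled from their joint
conditional distribution given the tips, then branch histories conditional
on endpoints by uniformization (exact; jump count by series inversion,
capped at 10 000 terms). Downstream OU fits use ER maps, following the
least-complex-best-supported convention; the model is a configuration
option.

## OU models on painted trees

The OUM mean at tip i is Σ_r W[i,r] θ_r with weights obtained by
integrating e^{−α(T−t)} over the painted intervals of the root-to-tip path;
the residual root mass e^{−αT} is assigned to the root regime's optimum
(no separate root-state parameter), so weight rows sum to one. The
covariance is the root-conditioned form on an ultrametric tree,
Var = σ²/(2α)(1 − e^{−2αT}) and
Cov(i,j) = σ²/(2α) e^{−2α(T−t_a)}(1 − e^{−2αt_a}). Optima are profiled by
GLS and σ² analytically, leaving a 1-D search over log α on [1e-4, 100]
(8-point grid plus bounded refinement). The exact α→0 Brownian limit is
always evaluated as an extra candidate, which guarantees the nesting
logL(OUM) ≥ logL(OU1) ≥ logL(BM1) to numerical tolerance. k = 2 (BM1),
3 (OU1), 2 + #regimes (OUM); AICc uses the per-trait species count.
Measurement error in species means is not modeled (no within-species SEs
are supplied to the fit); this is a known limitation.

**The α = ∞ flag.** Once α is large enough that all phylogenetic
correlations have vanished, the profile likelihood is flat and an optimizer
stops at an arbitrary point on the plateau. The fit is therefore flagged
"effectively instantaneous adaptation" whenever the profile value at the
upper bound is within 1e-4 log-units of the maximum, not only when the ML
point touches the bound. Traits fitted on log10 scale (mass, size,
offspring size/mass, fecundity) report fold-changes as
10^(θ_ref − θ_alt); fold-changes are computed from the mean per-map optima
(per-map values are also retained).

**Type-I error of OU-vs-BM selection.** Simulating Brownian data on the
125-tip synthetic tree and selecting among BM1/OU1/OUM by AICc prefers an
OU model in roughly 15–25 % of datasets. Diagnostics (mean ΔlogL ≈ 0.36
against ≈ 0.3 expected from the ½χ²₀+½χ²₁ boundary mixture) indicate this
is the statistical behavior of the procedure — α and σ² are weakly jointly
identified on ultrametric trees of this size — not an implementation
defect. Users drawing conclusions from OUM support on ~100-tip trees
should treat AICc preference for OU as anticonservative; the experiment is
exposed as `type1_error_experiment` so the rate can be measured on any
tree. On very small trees the AICc small-sample penalty dominates and the
rate falls instead of rising.

## Ecophysiology

The effectiveness index is computed from per-observation deviations of Tb
and Te from [Tset25, Tset75] (zero inside the range, boundary counts as
inside); E = 1 − d̄b/d̄e is undefined at d̄e = 0 and may be negative. The
symbol E collides between the effectiveness index and the activation
energy; the code separates them as the return value of `effectiveness` and
`MetabolicConstants.E_act`.

Metabolic equations are implemented literally as printed, with
i₀ = ln(20.3), E_act = 0.63 eV, k = 8.617333×10⁻⁵ eV/K (the Boltzmann
constant value is this package's choice; conversions add 273.15 K). The
multiplicative form with i₀ = ln(20.3) makes the absolute scale of I and B
an arbitrary "MTE unit"; only relative comparisons are meaningful, and a
log-scale variant (`log_scale=True`) is provided for dimensional
consistency. The corrected linear forms are 0.71·ln M + 18.02
(temperature-corrected) and −0.69/(kT) + 20.3 (mass-corrected; also applied
to nocturnal operative temperatures for inactivity rates). The SVL→mass
allometry is a deliberately non-phylogenetic OLS of log10 mass on log10
SVL, used only to predict missing masses; it coexists with the much
shallower phylogenetic mass~SVL regression without reconciliation, since
they answer different questions. Species-level energetics use species-mean
mass and temperature; per-observation variants are available through the
observation table (the "fallacy of averages" caveat applies to the means).

## Comparative statistics

PGLS uses a Brownian correlation structure by default (Pagel's λ scaling
optional; the structure used is recorded in the result). Parity-specific
regressions are fitted separately with a Bonferroni level of 0.025 recorded
on each, and a pooled interaction model is available as the alternative
reading. A named species-exclusion option is the supported way to replicate
outlier-sensitivity fits.

The phylogenetic ANOVA simulates the Brownian null on the tree (σ² by ML)
and uses the (r+1)/(n_sim+1) p-value estimator so p is never zero. On a
star tree the simulated null F distribution coincides with F(1, n−2) and
p-values are uniform under the null (both tested).

The evolutionary/optimal regression treats the predictor as a fixed,
error-free covariate: at each grid point over (t½, vy) — 50×50 by default,
t½ log-spaced on [0.01, 5 × tree height], vy scaled to the response
variance — the response is regressed by GLS under the stationary OU
residual covariance vy·e^{−α·d}, and the optimal slope is the evolutionary
slope divided by the attenuation ρ(α) = 1 − (1 − e^{−αT})/(αT). ρ → 1 as
t½ → 0 (slopes coincide) and |evolutionary| ≤ |optimal| always. The
2-log-likelihood support set is reported with the grid.

Mann-Whitney U uses midranks (exact p for min(n) ≤ 8 without ties, normal
approximation with tie correction otherwise; both U and its complement are
reported). The two-sample t is pooled-variance by default (df = n₁+n₂−2),
Welch optional.

## Threshold model

The binary state is the sign of a latent Brownian liability; (liability,
continuous trait) evolve as a correlated bivariate BM, giving a joint
Gaussian over tips with covariance R ⊗ C. The liability BM rate is fixed at
1 and the tree is rescaled to unit height for identifiability; the
parameters are the two trait means, the continuous-trait rate σ²ₓ
(log-uniform prior) and the correlation r (uniform prior). Tip liabilities
are Gibbs-sampled from their sign-truncated univariate conditionals with
the precision matrix maintained incrementally (O(n²) per generation);
(μ, σ²ₓ, r) move by random-walk Metropolis. A joint move that rescales
liability deviations from their conditional mean when proposing r is
essential: without it the sampler freezes near |r| = 1, because liabilities
sampled at the current r make any solo change of r unacceptable. The
canonical run length (10⁶ generations, thin 100, burn-in 2×10⁵ → 8 000
retained draws) runs in well under a minute at n ≈ 100 thanks to the
compiled kernel; ESS of r is reported (warning below 100). Calibration and
r = 0.7 recovery are exercised in the test suite.

## Wheatsheaf index

Traits are standardized per column; w is the ratio of the mean penalized
pairwise Euclidean distance among all species to that among focal species,
with each distance multiplied by (1 + shared-history fraction t_MRCA/T) so
that phenotypic similarity between close relatives is discounted as
ancestry rather than convergence. This penalty is this package's
formulation of the relatedness correction (the original is specified in
the convergence-measure literature; no Python implementation exists), kept
in one documented function with a literal-formula oracle in the tests.
Significance: n_boot (default 500) random same-size focal sets,
p = (r+1)/(n_boot+1). Univariate per-trait tests are the default; any
column subset can be passed.

## Synthetic data

The generator emulates the study conditions: a birth-death tree (default
125 tips, birth 0.08, death 0.03 per My, rescaled to 65 My — the
approximate crown depth of the family), a parity history with exactly five
origins of viviparity, no reversals, each origin visible as a distinct
viviparous tip clade, and 15–55 % viviparous tips (rejection sampling; the
one-sided gain rate is set to expect five events on the realized tree
length). The tip-count-conditioned simulator stops at the n-th birth, which
would leave a zero-length cherry; terminal branches are extended by the
waiting time to the next event so the present falls strictly between
events.

Trait defaults are the fitted optima of the system being emulated: Tb
34.9/29.7 °C, Tpref 34.6/31.9, CTmin 13.0/10.0, CTmax 41.9/37.6
(oviparous/viviparous), shared optima for log10 SVL (61.1 mm) and offspring
mass (0.83 g); α = 0.3/My and σ² = 2 °C²/My for thermal traits (stationary
SD ≈ 1.8 °C against ~3–5 °C regime contrasts — a signal-to-noise ratio at
which OUM is clearly but not trivially favored). Clutch size and offspring
size hang off dam size through log-log slopes of 1.1321 and 0.2893 with
regime-specific OU residuals; the viviparous clutch deficit (−0.097 dex)
plus a fixed single annual litter against 2 oviparous clutches produces the
~2.5-fold oviparous advantage in annual fecundity. Mean annual temperature
(bio1) is a slow OU with optima 18/16 °C, so the climate-parity correlation
is present but weak. Thermoregulation observations draw operative
temperatures around bio1 + 8 °C (SD 4), and body temperatures are pulled
toward [Tpref ± 1.5 °C] with precision 0.8, which puts the mean
effectiveness index near 0.8. Missingness is off by default and applied
per-trait on request.

What the generator does **not** emulate: correlated residuals across
traits, intraspecific variance, CTmin tracking climate at high α (the
generator keeps CTmin a regime OU; the evolutionary/optimal regression is
validated on its own model-matched simulator), sampling biases in which
species carry which traits, and phylogenetic uncertainty (posterior tree
sets are emulated by branch-length jitter in the robustness helper).
Passing tests on these data therefore demonstrate estimator correctness
and pipeline integrity under the assumed models, not robustness to the
messiness of field data.

## Problem sizes in the shipped runs

The default test suite uses 40–200-tip trees, 10–25 stochastic maps per
map-averaged fit, 20-replicate recovery loops, 150–200-simulation
calibration experiments, and 1.5–2×10⁵-generation threshold chains; the
acceptance script uses the 125-tip study scale with 100 maps (25 per OU
trait fit), 500 phylANOVA simulations and bootstrap replicates, a
2×10⁵-generation chain, and a 100-simulation type-I experiment. These sizes
were chosen so a complete run stays in the minutes range on a single core
while keeping Monte-Carlo error well inside the asserted tolerances; the
pipeline defaults (500 maps, 500 bootstraps, 10⁶ generations) match the
canonical analysis and remain practical.
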