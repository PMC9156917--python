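# Methods

This note documents the models, estimators and numerical choices behind
`clinemap`, and what the synthetic-data tests do and do not establish.

## Genotype classes and Hardy–Weinberg allele frequencies

Each record carries, per locus, one of two phenotype-derived genotype
classes — homozygous recessive or the combined dominant class — or a missing
call. Heterozygotes are never inferred: with full dominance and variable
penetrance they are not reliably scorable, so the dominant homozygote and
heterozygote are pooled by construction, and the package stores classes, not
diploid genotypes.

Within a grid cell, let n be the number of records scored at a locus and
n_rec the recessive-class count. Under Hardy–Weinberg equilibrium the
recessive-class frequency estimates q², so

    q̂ = sqrt(n_rec / n).

q̂ is consistent but slightly biased downward at small n (Jensen's
inequality applied to the square root); the test suite bounds the bias at
|E q̂ − q| < 0.02 with 500 genotypes. Pooling is at the cell level: counts
are summed over records, not averaged over per-record estimates. Records
with all three loci missing still count toward cell occupancy (they carry
abundance information) but contribute to no frequency.

Grid cells are half-open `[lo, lo + size)` squares anchored at
(−180°, −90°); anchoring is arbitrary but fixed, so indexing is
reproducible. The cell size must divide 360° evenly (4° and 2° are the
conventional choices). Latitude 90° is folded into the top row.

Fixation classes use thresholds 0.95/0.05: frequency > 0.95 near-fixed,
0.05–0.95 polymorphic, < 0.05 near-absent. The denominator is the set of
cells with at least `min_n` scored records (default 1, configurable); both
the any-record and locus-scorable occupancy counts are exposed because the
appropriate denominator depends on the question.

## Geodesy

All geometry is spherical with mean Earth radius R = 6371.0088 km.
Ellipsoidal corrections are below 0.5 % — far below the 4° cell
granularity — so a geodesic library adds nothing here. Distances are
haversine; cross-track and along-track distances use the standard spherical
triangle identities

    d_xt = R · asin( sin(d13/R) · sin(θ13 − θ12) )
    d_at = R · acos( cos(d13/R) / cos(d_xt/R) ),

signed by the side of the great circle and by whether the projection falls
behind the segment start. A transect is a sequence of great-circle
segments; a cell is projected onto the segment minimizing |cross-track|
among segments whose span contains its perpendicular foot, and its
along-path position is cumulative. Cells whose foot falls beyond every
segment (past the path ends, or in the outer wedge of a bend) are excluded
rather than snapped. Both functions are validated against a dense
nearest-point scan along the path (10⁵ interpolated points, agreement
required within 1 km) and cross-checked against the geosphere R package's
primitives.

## Cline model

The central cline is the hybrid-zone sigmoid

    f(x) = 1 / (1 + exp(−4 (x − c) / w)),

with centre c at the 0.5 crossing and width w = 4 / (max slope). Optional
exponential tails attach at distances δL, δR from the centre with slope
ratios τL, τR ∈ [0, 1]; the tail expressions are chosen so the value is
continuous at the junction for every τ and the derivative is continuous at
τ = 1 (verified by finite differences in the tests). Scaling maps f onto
[pmin, pmax]: *none* pins (0, 1), *fixed* pins the observed frequency
extremes of the corridor cells, *free* estimates both. Six models combine
scaling ∈ {none, fixed, free} × tails ∈ {none, both}; parameter counts are
2, 2, 4 and 6, 6, 8 respectively. Models are always named by their
(scaling, tails) pair, never by an index.

The likelihood treats the per-cell HWE-estimated frequency q̂_i as a
binomial proportion of m_i trials,

    logL = Σ m_i [ q̂_i ln p(x_i) + (1 − q̂_i) ln(1 − p(x_i)) ],

with m_i = 2 n_i alleles by default (`allele_counts="n"` switches to
individuals). p is clamped to [10⁻⁶, 1 − 10⁻⁶] so observed fixed cells stay
finite. The convention matters for uncertainty, not point estimates: q̂
from dominance-scored genotypes is noisier than a true binomial allele
count of the same size (the delta method gives Var q̂ = (1 − q²)/4n versus
q(1−q)/2n), so credible intervals on real dominance data are somewhat
anticonservative. The coverage tests therefore generate binomial allele
counts — a correctly specified check of the sampler — while the end-to-end
test on dominance-scored synthetic records asserts only point recovery
(centre offset), which is robust to this.

Decreasing clines are fitted on the complement frequency with the
orientation recorded, so w > 0 always and reported predictions are restored
to the data's orientation.

Maximum likelihood is bounded L-BFGS-B from 10 dispersed deterministic
starts (centres spread across the data span crossed with geometrically
spaced widths). Free scaling is reparameterized smoothly as
(pmin, s) with pmax = pmin + (1 − pmin)s to keep the box constraints
independent. A fitted width at ≥ 95 % of its bound (4 × data span) flags a
degenerate, effectively unbounded fit with a warning. Model comparison uses
AICc = −2 logL + 2k + 2k(k+1)/(n−k−1) with n = number of cells; ties break
toward fewer parameters, and a model that fails to fit is reported with its
error rather than aborting the comparison.

Posterior uncertainty comes from Metropolis sampling: by default three
independent chains, 10⁴ burn-in and 10⁵ retained generations each, joint
Gaussian proposals with per-parameter scales set to 5 % of each prior range
times a per-chain factor tuned toward ~30 % acceptance every 100 burn-in
generations and frozen afterwards (so the post-burn-in kernel is valid
Metropolis). Priors are uniform: c over the data span widened by one span
each side, w ∈ (0, 4·span], δ ∈ [0, 2·span], τ, pmin, pmax ∈ [0, 1] with
pmin < pmax. Chains start at the ML estimate jittered by 1 % of the prior
range. Convergence is monitored by Gelman–Rubin R̂ per parameter across
chains; R̂ > 1.1 attaches a warning, it does not fail the fit. Chains are
pooled for all summaries. Credible intervals are 2.5–97.5 % posterior
quantiles; the "fuzzy cline" envelope is the pointwise 2.5/50/97.5 %
band of p(x) over (at most 2000 subsampled) posterior draws. The centre
offset between two loci is |median c_A − median c_B| with an interval from
the 2.5–97.5 % quantiles of differences of independently paired draws,
sign-oriented so the median difference is non-negative (hence the interval
contains the point offset).

`ClineFitter` exposes all of this as a scikit-learn-style estimator
(`fit(X, y, sample_weight)` on positions, frequencies and per-cell counts;
fitted attributes `params_`, `aicc_`, `posterior_`, `centre_ci_`, …), so it
composes with sklearn tooling; `fit_ml`, `mcmc_sample`, `compare_models`
and `fitter_from_cells` are thin functional wrappers.

## Spatial GLS for environmental association

The response y is, by default, the per-cell frequency of the dominant
(dark-background) class at the B locus; recessive-class or allele frequency
are a column swap away. Covariates are annual mean temperature (bio01, °C),
solar radiation (bio20), annual precipitation (bio12, mm) and soil moisture
index (bio28), averaged over record locations within each cell.

The model is Gaussian GLS with covariance

    Σ_ij = σ² √(v_i v_j) exp(−d_ij / ρ)   (i ≠ j),   Σ_ii = σ² v_i,

where v_i = 1/n_i (inverse record counts as variance weights) and d_ij is
the Euclidean distance between cell centres in raw degrees. Euclidean
degrees, not great-circle km, is the deliberate default — it matches how
such correlation structures are conventionally specified on coordinate
pairs — with great-circle distance available via `distance="greatcircle"`.
There is no nugget by default (pure exponential decay); a nugget fraction
is available behind a flag. For fixed ρ, β̂ and σ̂² have closed forms
through a Cholesky whitening, so fitting is a bounded 1-D profile search
over ρ (default bounds 10⁻⁴–4 × the maximum inter-cell distance). ML
rather than REML, because AIC must be comparable across mean structures;
AIC uses k = (#coefficients) + 2 for σ² and ρ. Standard errors are Wald,
from (Xᵀ Σ⁻¹ X)⁻¹, and coefficient tests use the normal approximation — no
small-sample correction. The likelihood is verified against a dense
multivariate-normal density oracle (≤ 1e−8), against nlme::gls in R on a
shared fixture, and against weighted OLS in the ρ → 0 limit.

The model grid fits the null model plus all 15 covariate subsets and ranks
by AIC. A covariate's verdict combines three criteria: (i) present in all
five best-fitting models, (ii) Wald-significant in the best-ranked model
containing it, (iii) significant in both the pairwise weighted linear
regression and the unweighted Pearson correlation. Collinearity is
diagnosed with VIF_j = 1/(1 − R²_j) and pairwise correlations.

`ExponentialGLS` is the second sklearn-style estimator
(`fit(X, y, coords=…, sample_weight=…)`, attributes `coef_`, `se_`,
`rho_`, `aic_`); `fit_gls`, `model_grid`, `screens` and `criteria_report`
wrap it over env-cell tables.

## Synthetic worlds

`WorldSpec` defines ground truth: per-locus clines along great-circle axes,
hotspot-mixture sampling, a source mix, B-locus missingness among citizen
records, and parametric covariate surfaces. Defaults encode the study
conditions the pipeline is meant to detect: loci A and C share one axis
(~4650 km, northwest→southeast) with centres at 1000 and 2500 km and widths
of 500 km — a 1500 km mismatched-cline offset — while B is broad
(w = 1500 km) and scaled to [0.1, 0.9], i.e. polymorphic nearly everywhere;
20 000 records, 32 % citizen source, 50 % B-call loss among citizen
records; five Gaussian sampling hotspots of unequal weight along and off
the axis. Genotypes are drawn under HWE at the local cline frequency
(recessive homozygote with probability q²) and collapsed to dominance
classes. Points beyond the axis span take the end values, so frequencies
plateau outside the cline.

Covariates: bio01 = 28 − 0.35·|lat| + N(0, 0.5); bio20 = 180 + 2.5·bio01 +
N(0, 5); bio12 = 800 + 6·lon + N(0, 5). Soil moisture is constructed from
standardized precipitation plus an orthogonalized independent component,
half smooth-spatial (|lat|) and half iid, giving a record-level
precipitation–soil correlation of exactly 0.90 by construction; the 50/50
split keeps the cell-averaged correlation near the target too (a purely
iid component would average out and push it toward 1, a purely spatial one
carries more between-cell variance and pulls it down). This emulates the
strong precipitation/soil-moisture collinearity real climate layers show.

What the generator does **not** emulate: land/ocean masking (immaterial to
the statistics), duplicate records across databases, temporal trends,
heterozygote excess from a male-killing endosymbiont (which in the real
system biases HWE-based q̂ at the C locus), and raster-based covariate
extraction. Passing tests therefore demonstrate correctness of the
estimators under the stated sampling model — not robustness to HWE
violations or to spatially structured scoring error.

## Problem sizes in tests and the acceptance script

The test suite runs the statistical checks at reduced sizes chosen for a
fast default run: cline recovery with 10 replicates and shortened chains
(3·10³ burn-in, 1.5·10⁴ generations — the posterior for a 2-parameter
sigmoid mixes in well under that), model selection with 25 replicates,
geodesy with 250 scan cases, end-to-end offset as a single 20 000-record
world. `scripts/acceptance.py` repeats them larger: 1000 geodesy cases, 16
cline-recovery replicates at the full 3 × (10⁴ + 10⁵) schedule, 50
model-selection and 50 GLS-coverage replicates, and the full end-to-end
run. All randomness descends from the single `--seed` via spawned
`SeedSequence` streams.

## Known limitations

- Credible intervals inherit the binomial-allele-count convention and are
  anticonservative for dominance-scored data (see above); widths and
  centres themselves are unbiased in the tested designs.
- Transects crossing the antimeridian are not supported; longitudes are
  treated on [−180, 180).
- The GLS response is a frequency treated as Gaussian; cells with extreme
  frequencies and tiny n strain that approximation, mitigated but not
  removed by the 1/n variance weights.
- "Fixed" scaling pins pmin/pmax to the corridor's observed extremes,
  which slightly overfits at small cell counts relative to free scaling
  with a prior.
- No deduplication across record databases is attempted.
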