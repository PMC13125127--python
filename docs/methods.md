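# Methods

This note documents the models implemented by `tricoord`, the numerical
choices made where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Composite subsystem indices

Indicators are min-max standardized over the **whole panel** (all units
and years jointly) by default, so that scores are comparable across
time; per-year pooling is available via `pool="year"`. Positive
indicators map through `(x − min)/(max − min)`, negative ones through
`(max − x)/(max − min)`, so standardized values are always
larger-is-better and span exactly [0, 1] in the pool. A constant
indicator within its pool raises a `DegenerateIndicatorError` naming the
indicator: surfacing a data problem beats silently imputing.

CRITIC weights are computed **once per subsystem block** over the whole
panel (one weight per indicator, as weight tables are conventionally
published). `σ_j` uses the sample (m−1) standard deviation of the
standardized column; the conflict sum `c_j = Σ_k (1 − r_jk)` runs over
every indicator of the block including `j` itself, whose term is zero —
self-inclusion is a convention choice that only rescales all capacities
by the same structure and cannot change the normalized weights' ranking.
Correlations are computed on standardized (not raw) values; because the
Pearson correlation is invariant to positive affine maps, this choice
only matters through the direction reflection, which is intended.
Entropy weighting (`method="entropy"`) is a robustness alternative:
shares are formed after a 1e−6 offset (entropy is undefined at zero) and
weights are proportional to the divergence `1 − e_j`.

## Coupling coordination

`C = 3(U1·U2·U3)^{1/3}/(U1+U2+U3)` is 1 exactly when the three scores
are equal (AM–GM) and 0 when any score is 0; the all-zero case is
undefined and raises. `T` uses equal weights 1/3 by default and `D =
√(C·T)`. The ten classification intervals are left-closed; the top
interval is closed at 1 so the attainable maximum classifies
("Excellent coordination").

Growth summaries use the geometric average annual rate (CAGR) over
`years − 1` intervals. On published endpoint levels this exactly
reproduces the conventional national (0.443→0.616: 3.35%) and central
(0.447→0.631: 3.51%) CCD figures. Note that the same formula applied to
the healthcare endpoints 0.414→0.524 yields 2.38%, not the 2.3%
sometimes quoted; the discrepancy is inherent to the source figures and
is not absorbed here.

Trajectory grouping (Leading / Advantageous / CatchingUp / Lagging) is
not standardized in the literature; the default rule takes quartiles of
final-year D (ties broken by unit id, ascending id winning the higher
group; with 31 units the groups are 8/8/8/7). The rule is a pluggable
callable for studies that define membership differently.

## Distribution dynamics

Kernel densities use the Gaussian kernel `f(x) = (1/Nh) Σ K((X_i−x)/h)`
with Silverman's rule `h = 0.9·min(sd, IQR/1.34)·N^{−1/5}` as the
automatic bandwidth and an evaluation grid spanning the data range ±4h
(so the grid captures essentially all mass; the trapezoid integral is
within 1% of 1).

CCD tiers I–IV are quartiles of the **pooled** unit-year distribution by
default (per-year quartiles by flag); percentiles use linear
interpolation, and values equal to a cut point go to the lower tier — a
deterministic, documented tie-break. Transition matrices are
maximum-likelihood row-normalized counts over all consecutive-year
pairs. The spatial chain conditions each transition on the tier of the
unit's spatial lag at the start year; lag tiers use the same quartile
scheme applied to the pooled lag values, and the W used for conditioning
defaults to the same matrix configured for the Moran analyses, since
coordination studies typically use one weight matrix throughout. The
four conditioned count matrices partition the unconditional counts
exactly.

## Spatial statistics

Weight matrices: binary symmetric contiguity from an adjacency list,
inverse-distance from centroids, or k-nearest-neighbor (symmetrized)
fallback; optional row standardization; zero diagonal enforced. Isolated
units are linked to their single nearest neighbor with a logged warning
rather than silently dropped. Defaults: row-standardized queen
contiguity for Moran/LISA/Markov conditioning, row-standardized inverse
distance for the SDM (the spatial-distance choice conventional for
spillover models); every pipeline result records which W produced it.

Global Moran's I uses the randomization-moments z-test by default
(E(I) = −1/(n−1); the variance formula accounts for sample kurtosis),
with a seeded permutation pseudo-p as cross-check. Local Moran's I is
normalized with `S² = z'z/n` so that `Σ_i I_i = n·I` under a
row-standardized W; pseudo-p values come from conditional permutations
(hold unit i, permute the rest), α = 0.05 and 999 permutations by
default, with no multiple-testing correction — standard LISA practice —
though a corrected variant can be layered on the returned p-values.

## Spatial Durbin model

Estimation concentrates the likelihood over ρ: `ln|I − ρW|` is evaluated
from the eigenvalues of W (exact and cheap at n = 31; sparse or
Chebyshev approximations are out of scope), the scalar problem is solved
by bounded optimization inside the spectral interval, and the slopes
follow by least squares at the optimum. Fixed effects are removed by
within-demeaning before the spatial step (demeaning commutes with W,
which acts within periods). Random effects use the Swamy–Arora
quasi-demeaning factor estimated from the non-spatial within/between
regressions, then the same spatial ML — the standard error-component
transformation route. Both unit-only; time effects can be added as year
dummies by the caller. Coefficient covariance comes from a
central-difference Hessian of the full log-likelihood in
(δ, ρ, ln σ²) — deterministic and agnostic to the effects
transformation. The reported R² is the squared correlation between
observed and fitted values.

The specification battery: VIF from auxiliary regressions with constant;
Anselin–Bera–Florax LM and robust LM statistics for lag and error
dependence from pooled OLS residuals (χ²₁); LR tests of the SDM against
SAR (θ = 0) and SEM (common factor); a Wald test of θ = 0 and a
delta-method Wald of the common-factor restriction θ + ρβ = 0; and a
Hausman contrast of the fixed- and random-effects slope vectors (clipped
at zero when the finite-sample covariance difference is not positive
definite). Covariates enter in the units they are supplied in — no log
or rescaling transform is applied silently.

## Threshold regression

Hansen's fixed-effects panel threshold model: the focal slope switches
where the threshold variable q crosses γ. Candidate thresholds are the
observed values of q inside a 5%-per-tail trimmed support (optionally
quantile-thinned via `max_candidates` for speed); for each candidate the
regime-split design is rebuilt, within-demeaned and fit by least
squares, and γ̂ minimizes the RSS — an exhaustive search, so the
optimizer trivially equals enumeration. The threshold-existence F uses
`MSE = RSS/(n(T−1))`, the within-degrees-of-freedom convention that
published threshold tables follow. Its null distribution is approximated
by a residual bootstrap under the no-threshold model (300 replicates by
default, seeded), re-estimating γ in every replicate; the second
threshold is searched conditional on the first, the first refined given
the second, and tested against the single-threshold null the same way.
The threshold model is deliberately estimated with fixed effects even
when the SDM uses random effects — the two models are independent, as is
standard in this literature.

## Synthetic panel generator

The generator is the package's study condition, not a tuning knob. It
emulates: 31 units in three regional tiers (11 east / 8 central / 12
west, matching the conventional three-belt partition) on an 8×5 grid
(minus 9 cells) whose three longitudinal bands stand in for the regions;
11 years (2013–2023) of strictly positive annual drift; a 29-indicator
schema with the same subsystem/direction mix as published indicator
tables (10 healthcare with 2 negative, 11 insurance with 2 negative, 8
pharmaceutical); east > central > west level offsets; positive spatial
autocorrelation through a spatially filtered unit effect
`(I − ρW)^{-1}η` with ρ = 0.4; covariates drawn inside published
descriptive ranges (per-capita GDP 22.4k–216.7k, health-expenditure
share 3.97–13.93%, urbanization 23.97–89.58%, education 0.89–4.37%,
old-age dependency 7.01–30.6) with AR(1) persistence 0.8 and a mild
upward drift in the dependency ratio; and configurable SDM
(ρ = 0.4, β = (1, −0.5), θ = (0.5, 0.2)) and threshold
(γ = 15.06, slopes 0.006/0.011) generating processes with ground truth
recorded exactly.

Each unit-year carries a latent subsystem quality; indicators are noisy
affine transforms with a sign flip for negative-direction indicators, so
direction handling is genuinely exercised. Gaussian observation noise
(sd 0.05) is a modelling convenience — real yearbook indicators have
heavier tails, measurement revisions, and within-year dependence the
generator does not emulate, so passing tests certify the estimators'
mechanics and recovery behavior, not the empirical conclusions of any
real panel. Indicator scale/offset constants are drawn once per
indicator from the seeded generator; all randomness flows through
`numpy.random.default_rng` child seeds derived by stable hashing of
stage names (no global random state), so enabling or disabling a
pipeline stage never perturbs another stage's draws.

## Problem sizes and determinism

Monte-Carlo suites in the tests use the panel dimensions of the study
design (n = 31, T = 11) for recovery checks (100 replicates for ρ̂, 500
for test sizes) and a reduced 20×6 panel with 100 bootstrap draws and
200 outer replicates for the threshold-F size study — sizes chosen so
the whole chain remains comfortably reproducible on a single CPU.
Pipeline outputs are plain CSV with a provenance header (config hash +
seed); two runs with identical config and seed are byte-identical, which
the test suite asserts by file hash.

## Known limitations

* The SEM fit reports the spatial error coefficient and likelihood (for
  LR tests) but not per-coefficient inference.
* The LeSage–Pace direct/indirect effects decomposition of the SDM is
  out of scope (coefficients, Wx terms and ρ are reported).
* Ergodic/stationary Markov forecasting and mobility indices are not
  implemented.
* Within-demeaned spatial ML carries the usual incidental-parameters
  caveat for short panels; at T = 11 the bias is negligible for the
  purposes here and the random-effects route is the default.
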