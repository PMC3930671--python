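# Methods

`icomosaic` analyses fully mapped forest plots ("stem maps") the way
spatial studies of frequent-fire conifer forests do: second-order
point-pattern statistics describe where trees sit relative to one
another, a crown-overlap rule decomposes the stand into tree patches,
single trees and canopy gaps (the individuals–clumps–openings, or ICO,
view of stand structure), and composite fire-return intervals summarise
the fire regime recorded in fire-scarred wood. This note documents the
models, estimators, defaults and design choices.

## Point-pattern statistics

**Pair correlation function.** For a stationary point process with
intensity λ, g(r) is the density of pairs at distance r relative to a
Poisson process: g = 1 under complete spatial randomness (CSR), g > 1
under aggregation, g < 1 under regularity. The estimator is the kernel
form

  ĝ(r) = Σ_{i≠j} e_ij · k_δ(r − d_ij) / (2π d_ij) / (λ̂² |W|),

with an Epanechnikov kernel k_δ of half-width δ, Ripley's isotropic
edge-correction weight e_ij (reciprocal of the fraction of the circle
through j centred at i lying inside the rectangular window, symmetrised
over the two orderings so that ĝ₁₂ ≡ ĝ₂₁), and λ̂ = n/|W|. Dividing by
the pair distance d rather than the argument r removes the leading
small-r bias (the `divisor="d"` convention). Bivariate estimates use
λ̂₁λ̂₂|W|; inhomogeneous estimates replace the product of constants by
λ(xᵢ)λ(xⱼ) per pair. Ripley's K/L (isotropic-corrected, cumulative) is
used for the large-scale homogeneity screen, where its cumulation makes
it far more sensitive to intensity trend than g.

**Bandwidth.** Stoyan's rule of thumb: half-width δ = c/√λ̂ with
c = 0.15 (so the kernel sd is δ/√5). Estimates at r < δ are flagged
unreliable rather than suppressed. The default evaluation grid runs
from 0.5 to 50 m in 0.5 m steps; 50 m is the standard maximum for
4-ha plots and keeps the isotropic correction in its exact regime
(r ≤ half the shorter window side).

**Known estimator bias.** Per-realization normalization by λ̂² is a
ratio estimator. For cluster processes E[n²] = (λ|W|)²(1 + CV²(n)), so
ĝ is biased low at long range by ≈ CV²(n) and compensated at short
range where within-cluster pair counts co-vary with n. For the Thomas
benchmark used in the tests (κ = 5·10⁻⁴ m⁻², μ = 8, σ = 5 m on 4 ha,
CV² ≈ 0.053) the measured bias profile is −1.4% (r = 2 m), +2.2%
(mid-range), −3.7% (r = 20 m) — inside the 5% band the closed-form
recovery test uses. That test averages 2000 replicates so its Monte
Carlo standard error (≈0.7%) is small against the band; the quantity
checked is the estimator's bias, not simulation luck.

**Intensity surfaces.** Inhomogeneous analyses need λ(u). The estimate
is a Gaussian kernel smooth with reflection edge correction (mirror
images across edges and corners return leaked mass, so the surface
integrates to ≈ n), evaluated by bilinear interpolation, with
leave-one-out removal of each point's own kernel mass at data points.
The default bandwidth is a quarter of the shorter window side — wide
enough to capture environment-scale trend without absorbing the
biological clustering the PCF is supposed to see. This split of scales
is a modelling choice, not an estimate; both bandwidths are exposed in
configuration.

**Null models and envelopes.** Four Monte Carlo nulls: CSR (Poisson
with λ̂, unconditional count by default; a fixed-n binomial option
exists), inhomogeneous Poisson (thinning under the estimated surface,
which is held fixed across simulations), independence of two patterns
(uniform toroidal shift of the second pattern, preserving its internal
geometry exactly on the window-as-torus), and random labelling (mark
permutation over fixed locations, conserving label counts). Envelopes
take the rank-5 extremes of 199 simulations: the pointwise two-sided
exceedance probability under the null is exactly 2·5/200 = 0.05 by the
order-statistic exchangeability argument. The band is pointwise, never
familywise, and is therefore always reported together with the global
test below.

**Goodness-of-fit.** The Loosemore–Ford statistic
uᵢ = Σ_r (statᵢ(r) − mean of the other curves)² Δr, computed for the
observed curve and every simulation over 0–50 m; p is the rank of
u_obs among all n_sim + 1 values with ties counted conservatively
(as ≥). Under the null p is uniform on {k/(n_sim+1)}.

**Mode selection.** The pipeline screens established trees
(DBH > 25 cm) with both L and g against CSR and switches to
inhomogeneous PCFs when either GoF rejects at α = 0.05. Using two
statistics doubles the screen's nominal size (≈2α); this is accepted
because the cost of missing real heterogeneity (spurious aggregation
at all scales) is much higher than the cost of an unnecessary
inhomogeneous correction. Manual override is available.

## Crown allometry

Crown width follows the western-US largest-crown-width regression form
CW = b₀ + b₁·DBH + b₂·DBH² + b₃·CR + b₄·BA + b₅·HI (crown radius =
CW/2), where CR is the live-crown ratio ((height − crown base)/height,
species default 0.5 when unmeasured), BA the plot-level basal area in
m²/ha, and HI the Hopkins bioclimatic index

  HI = (E_ft − 5449)/100 + 4·(LAT − 42.16) + 1.25·(−116.39 − LON),

affine in elevation (converted to feet), latitude and longitude, zero
at its reference point. A predictor enters a species' model only where
its inclusion flag is set. **The shipped coefficient table is a
synthetic stand-in** (`data/crown_coefficients_synthetic.csv`): the
equation form is the published one, but per-species coefficients are
plausibility-tuned to give crown radii of ~1–6 m over 5–100 cm DBH.
Any analysis of real stem maps should replace it with fitted
coefficients via `CrownModel.from_csv`. Unknown species fall back to a
conifer default with a warning; negative extrapolations clamp to a
0.5 m floor; radii above 30 m are rejected as data errors. Snags get
no crown: patches and gaps are live-canopy constructs.

## Patch, single-tree and gap delineation

**Patches.** Two live trees are connected when their crown disks
strictly overlap (centre distance < r₁ + r₂; tangency, a measure-zero
event, does not connect). Patches are connected components with ≥ 2
members; a component with one member is a single tree. Patch polygons
are unions of crown disks (192-gon approximations, area error ≪ 0.1%)
clipped to the window.

**Edge bookkeeping.** Trees whose stems fall within the 5 m inner
buffer contribute crown geometry — so shapes and gaps near the edge
are right — but are excluded from membership counts, single-tree
tables and proportions. A component is classified by its *interior*
membership (≥ 2 interior members → patch; exactly 1 → single). This
makes the conservation identity exact: interior live trees = Σ patch
members + singles, on every input.

**Gaps.** The canopy mask (union of crown disks, rasterized at 0.25 m)
is filtered morphologically: canopy slivers thinner than the 2 m gap
threshold are absorbed (opening of the canopy with a 1 m-radius disk),
then open corridors thinner than the 12 m spur threshold are removed
(opening of the open space with a 6 m-radius disk). Both openings use
exact Euclidean-disk erosion/dilation via distance transforms, which
avoids discretized structuring-element artifacts; total gap area at
0.5 m vs 0.25 m cells agrees within 1%. The world beyond the window is
treated as canopy, so gaps are measured by their extent inside the
plot; because this truncates boundary gaps, summaries are reported
both with and without *edge gaps* — gaps with more than 10% of their
perimeter (default) or area (alternative mode; the two readings of the
rule differ in the source literature, so both are implemented and
neither is asserted canonical) inside the buffer ring.

**Summaries.** Patch attribute tables by trees-per-patch category
(2, 2–4, 5–9, 10+): counts, proportion of interior live trees, mean ±
SE of per-patch tree density (stems/ha of crown-union area), basal
area and area; single-tree counts, mean DBH and basal area per plot
hectare; stand totals (patches/ha and % area in patches relative to
the full window).

## Patch typology

Feature matrix per patch: mean, max and sd of DBH, trees per patch,
tree density, patch area, patch perimeter. Columns are standardized to
zero mean and unit variance before both PCA and clustering — the
features mix cm, m² and stems/ha, so raw Euclidean distances would be
dominated by units (equivalently, the PCA is on the correlation
matrix). Clustering is agglomerative with Ward's linkage on Euclidean
distances; the number of groups is fixed by the user or chosen in 3–6
by the largest relative merge-height elongation ("branch elongation"
in the dendrogram). Group differences per variable use one-way ANOVA
from first-principles sums of squares with Shapiro–Wilk (residuals)
and Levene screens at α = 0.05 and an automatic log₁₀ re-analysis when
either fails, followed by Bonferroni-adjusted pairwise t tests on the
pooled mean square, summarised as a compact letter display. Across-site
comparisons of fire-interval distributions use Kruskal–Wallis with tie
correction, and — only when the overall test rejects — Nemenyi pairwise
comparisons (studentized range on mean ranks).

## Fire-return intervals

A composite chronology pools scar years across samples; recording
status comes from explicit per-sample recording spans (no pith/bark
inference — conventions vary across archives, so recording is input
data here). Two composites: all fires, and the 25% filter keeping
years with ≥ 3 scarred samples and more than 25% of recording samples
scarred (strict > by default; ≥ available, as the rule is worded both
ways in the source literature). Intervals are successive differences
of retained fire years within a closed analysis period; the summary
reports mean, sample SD (undefined for a single interval) and median.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design — 4-ha rectangular plots
with 1000–1500 stems ≥ 5 cm DBH (CSR default λ = 0.0325 m⁻²),
small-DBH-skewed size distributions (truncated Weibull, shape 1.2,
scale calibrated so P(DBH < 25 | DBH > 5) = 0.6), site-archetype
species mixtures and sparse snag populations (site presets with snag
fractions 1.9–7.4%), Thomas clustering with known closed-form g(r),
log-linear intensity trend with a 3:1 max/min ratio (trend magnitude
is a scenario parameter, not an estimate — the field sites' trends are
not quantified), clustered-snag labelling for random-labelling power,
and Bernoulli fire-scar recording over known fire years. It does *not*
emulate: species-dependent spatial segregation, realistic height/crown
base allometry (monotone-in-DBH defaults only), snag decay classes,
fire-spread or stand dynamics. Passing tests therefore demonstrate
that the estimators and delineation rules behave correctly under
controlled truth, not that any particular field result is reproduced —
the field data behind the original site tables are not deposited, and
no site-specific numbers are asserted anywhere in this package.

## Numerical and reproducibility choices

Every stochastic stage draws from a named stream derived from one
master seed (SeedSequence keyed by stage name), so stages re-run
independently and runs are byte-for-byte reproducible at fixed
configuration (CSV output at fixed precision). Isotropic correction
weights are capped at 100. GoF ties count as ≥. Pair distances below
1 nm are dropped (coincident points carry no distance information for
a kernel in d). Problem sizes in the test suite are chosen so the full
suite runs in a few minutes on one CPU: 200 CSR and 2000 Thomas
replicates for estimator consistency, 500 meta-replicates at
n_sim = 99 for GoF calibration, 100 power replicates at n_sim = 199,
1000 random mosaics for the conservation property.

## Known limitations

- The crown coefficient table is synthetic (above); results on real
  maps are only as good as the coefficients supplied.
- The PCF ratio-normalization bias (above) is inherent to
  single-pattern estimation and is documented rather than corrected.
- Raster gap delineation is approximate at the cell scale; vector-exact
  morphology is out of scope.
- The isotropic correction formula assumes r ≤ min(width, height)/2.
- FHX import is a stub; chronologies enter via the per-sample CSV.
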