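# Methods

`dungprint` reconstructs past herbivore presence and dominant taxa from fecal
steroid biomarkers in lake sediments, and integrates the result with the
standard companion proxies of a small-lake multiproxy study: an age–depth
model and influx calculation, charcoal fire-episode detection, pollen
summaries, and historical census data.  This note records the models, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## Compositional steroid profiles

Steroid concentrations (mass per dry mass) vary strongly with preservation,
organic content and extraction yield, so all multivariate comparison is done
on *relative abundances within a compound family*: (i) sterols, stanols and
stanones and (ii) bile acids, each closed to sum 1 per sample.  Source
attribution in sediments uses only the four 5β-stanols ("zoostanols":
coprostanol, epicoprostanol, 24-ethylcoprostanol, 24-ethylepicoprostanol),
because they are produced in animal digestive tracts, whereas most other
steroids have large non-fecal environmental sources.

Below-detection cells are treated as exact zeros, not missing values: in this
measurement context non-detection of a bile acid is informative absence.
Chenodeoxycholic and ursodeoxycholic acids are excluded from bile-acid
ordination by default because they are essentially undetected in herbivore
dung (configurable).  A sample whose family sum is zero carries no signal in
that family; it is omitted from the profile matrix with a logged warning,
never silently dropped.  Compound names are matched case-insensitively with a
synonym registry ("epi-coprostanol" ≡ "epicoprostanol", etc.), since the
literature uses several spellings.

## Ordination and attribution

The reference dung library is ordinated by PCA of the zoostanol compositions.
Variables are centred and, by default, scaled to unit population (ddof = 0)
standard deviation, the convention of the HCPC workflow in the FactoMineR
tradition; covariance-only PCA is available by flag.  The PCA is computed by
SVD of the standardized matrix.  Component signs are fixed so the
largest-magnitude loading of each component is positive (ties broken toward
the lowest variable index), which makes scores, loadings and downstream plots
fully deterministic; centroid distances are invariant to this choice, and a
test asserts so.

Sediment samples never influence the fit: they are projected as
*supplementary individuals* through the training centring, scaling and
loadings.  Training samples are clustered in the retained 4-component score
space with Ward's method on Euclidean distances.  Ward is run in the
"Ward.D2"-equivalent form (Lance–Williams update on squared Euclidean
distances, heights reported as square roots), so dendrogram heights are
directly comparable with other implementations using that convention.  When
`k` is not given it is chosen as the cut in 2..min(10, n−1) with the maximal
relative loss of within-cluster inertia between successive cuts; the packaged
reproduction configuration pins `k = 3` (bison/elk, moose, and
pronghorn/mule-deer groups), since bison and elk are only partially
differentiated in real dung and a three-group reference is the intended
interpretation frame.  No k-means consolidation is applied after cutting the
dendrogram (off by default, available by flag).

Each sediment sample is attributed to the cluster with the nearest centroid
(Euclidean distance in score space).  Distance ties are broken toward the
lowest cluster id, with a logged warning.  Shorter distance = greater
similarity of the sediment zoostanol signature to that species group — a
categorical indicator of dominant taxa, not a mixture proportion.  Continuous
unmixing is explicitly out of scope.

## Chronology and influx

The age–depth model is a deterministic piecewise-linear interpolant through
the median ages of dated control points (calendar markers, ²¹⁰Pb ages,
calibrated ¹⁴C dates, event layers), linearly extrapolated beyond the
terminal segments.  Bayesian accumulation modelling (rbacon-style) is
deliberately **not** reimplemented: the package's contribution is the
attribution and influx logic, and a transparent interpolant reproduces every
control age exactly, which Bayesian posteriors do not.  The consequence is
accepted and documented: extrapolated basal ages and 2σ age envelopes are out
of scope, and episode ages derived here can differ by decades from those of a
Bayesian chronology built on the same controls.  Non-monotone control medians
are replaced by their pool-adjacent-violators (isotonic) fit, with a logged
warning; a resulting flat segment has undefined accumulation rate and is
rejected if sampled.

Radiocarbon calibration is supported against a user-supplied curve table
(cal BP, ¹⁴C BP, σ — the standard distribution layout).  The posterior over
calendar age on the curve grid is proportional to the normal density of the
measured age at the curve's ¹⁴C age with combined variance (measurement² +
curve²); the median and the highest-density 95.4 % interval are returned.  On
a locally linear curve this reproduces the closed-form normal posterior to
within the grid resolution, which is the accuracy check in the tests.  No
calibration curve is bundled; reservoir corrections and post-bomb curves are
out of scope.

Two reciprocal rate conventions are carried explicitly to prevent inversion
bugs: deposition time (yr cm⁻¹ = Δage/Δdepth per segment) and the sediment
accumulation rate SAR (cm yr⁻¹), its reciprocal.  Influx = concentration ×
dry bulk density × SAR.  Density is an optional scalar or per-sample column;
when absent it defaults to 1 g cm⁻³ with a logged unit caveat (the result is
then per-gram, not per-cm²).  Total zoostanol influx is the sum over the four
zoostanol compounds.  Ages are calendar years BP (before 1950 CE); negative
ages denote post-1950 deposition, year CE = 1950 − age BP.

## Charcoal fire episodes

Counts of macroscopic charcoal (particles > 125 μm) per contiguous interval
are converted to concentration (count/volume) and charcoal accumulation rate
(CHAR = concentration × SAR, particles cm⁻² yr⁻¹), then interpolated to a
constant timestep equal to the record's median temporal resolution rounded to
whole years — the convention of the CharAnalysis-style decomposition this
module follows.  Background CHAR (BCHAR) is a robust LOWESS (tricube-weighted
local linear regression, two bisquare robustness iterations) with a 500-yr
default window.

Peaks are residuals (CHAR − BCHAR, a difference, not a ratio — the
CharAnalysis default).  Within a moving window the same width as the
background window, the residual noise distribution is modelled as the
lower-mean component of a two-component 1-D Gaussian mixture fitted by EM
with deterministic initialization (component means at the 25th/75th residual
percentiles, pooled starting SD, equal weights).  The mixture order (1 vs 2
components) is selected by BIC per window: on a peak-free window a forced
two-component split would badly understate the noise quantile, and the
reference implementation's cluster-order estimation likewise can return a
single component.  A degenerate mixture (vanishing weight or variance) falls
back to the single Gaussian with a logged warning.  The local threshold is
the 99th percentile (configurable) of the noise component, computed at window
centres a quarter-window apart and linearly interpolated between them; a
sample is a peak only if its residual clears the threshold by more than a
scale-relative numerical floor (10⁻⁹ × max |CHAR|), which keeps flat series
peak-free and preserves exact invariance of the episode set under uniform
CHAR rescaling.  Consecutive supra-threshold samples merge into one fire
episode dated at the sample of maximum CHAR.  The mean fire return interval
over an age window is the mean of successive episode age differences;
undefined (reported absent) with fewer than two episodes.

By construction a 99th-percentile noise threshold flags ≈ 1 % of samples on a
pure-noise series; the tests assert this rate (0.5–2 % over 50 seeded
replicates of 1000 timesteps) rather than pretending the method has zero
false-positive rate, and the fire-regime acceptance check therefore asserts
the *median* episode count over replicate synthetic cores.  No Poisson
minimum-count screening is applied by default (available as an option).

## Pollen, biomass and correlation

Terrestrial pollen taxa are converted to percentages on the terrestrial sum;
aquatic taxa (including Cyperaceae, classified aquatic because of its wetland
habit) on the total sum.  With an exotic marker spike, concentration =
(count/spike counted) × spike added / volume, and accumulation rate =
concentration × SAR.  The openness ratio is
(Artemisia % + Poaceae %) / (Pinus % + Pseudotsuga %): high values indicate
open steppe-shrub vegetation; a zero denominator yields an undefined
(absent) value.

Census counts are converted to biomass with average adult body masses of
665 kg (bison) and 235 kg (elk), combined across species by year.  Gaps
within a species' surveyed span are linearly interpolated; values are never
extrapolated beyond the span, because pre-survey trends are unknowable from
the data.  The association between a sediment biomarker series and biomass is
Pearson's r over a calendar-year window (defaults 1920–1970 and 1971–2020,
the two management regimes of the study system), with biomass matched to each
sample's median age by linear interpolation (nearest-year matching available
by flag — the pairing rule is not uniquely determined by the source
workflow, so both are exposed).  Fewer than three pairs in a window is an
error.  Fossil presence/absence uses the minimum-number-of-individuals rule:
present ⟺ MNI ≥ 1.

## Synthetic data: what it emulates and what it does not

The generators produce every pipeline input with the statistical structure
the analysis assumes, so all stages are testable without field data.

* **Dung library.** Per-sample zoostanol and bile-acid compositions are
  Dirichlet draws centred on per-species endmember means with concentration
  parameter 150 (chosen so species clusters separate at roughly the scale
  seen in real dung ordinations: moose fully separated, bison and elk
  overlapping).  The endmember means are calibrated to published per-species
  values (e.g. bison deoxycholic acid 58 %, elk lithocholic 49 %, bison
  hyodeoxycholic 11 %, moose richest in 24-ethylepicoprostanol), and the
  default sample sizes match the reference library (bison 18, elk 7, moose 7,
  mule deer 2, pronghorn 6).  Total yields are log-normally jittered
  (σ = 0.3) around 30 μg g⁻¹ (zoostanols) and 5 μg g⁻¹ (bile acids).
  Dirichlet noise was preferred over logistic-normal for closure and
  simplicity; it cannot represent correlated compositional noise between
  compounds.
* **Sediment core.** Per-depth zoostanol composition = weight-mixture of
  endmember compositions, perturbed by Dirichlet noise (concentration 300;
  ∞ gives the exact mixture), with optional epimerization moving a stated
  fraction of each 3β-stanol to its 3α epimer.  Concentrations (≈ 400 ng g⁻¹
  total zoostanols, plus background phytosterols) are scaled by a deposition-
  intensity series; the default emulates the qualitative 20th-century
  "hay-feeding era" pulse (Gaussian in calendar year, peak ≈ 1923 CE, ×8).
  The default chronology is a piecewise-constant-accumulation control set
  (surface −69 cal BP, an event layer, ²¹⁰Pb-style points, two ¹⁴C medians at
  75 cm → 696 and 148 cm → 2188 cal BP).  Default sampling is denser toward
  the core top (2–4 cm steps above 44 cm, 8 cm below), as in real
  subsampling schemes.  Mechanistic taphonomy (snowmelt transport, carcass
  inputs, degradation kinetics beyond the single epimerization rate) is *not*
  simulated; passing tests show the statistical pipeline recovers planted
  structure, not that real sediments behave this simply.
* **Charcoal.** Counts are Poisson around background CHAR / SAR × volume
  (default background 1 particle cm⁻² yr⁻¹, 2 cm³ samples, 1-cm contiguous
  intervals), with planted episodes adding 10× the local background in the
  interval containing each episode age.
* **Population demo.** A sparse anchor table of historical Northern Range
  census values (bison ≈ 25 → 4000; elk 11,500 → 3224 → 19,048 → 5800),
  linearly interpolated — a deliberately coarse stand-in for real census
  compilations.  The biomass-coupled scenario drives deposition intensity
  with this series so the windowed correlation stage has a known positive
  association to recover; with six samples in the 1920–1970 window and 20 %
  log-normal concentration noise the per-replicate r is wide (≈ 0.0–0.97,
  median ≈ 0.6), which is why the correlation acceptance check asserts the
  median across replicates, not a single draw.

All generators are deterministic given a seed (numpy `default_rng`).

## Numerical choices and degenerate inputs

* Profile closure tolerance 1e-9; orthonormality of loadings checked at 1e-8.
* Constant variables under standardization are an error naming the variable.
* PCA comparisons in tests skip matrices with near-tied eigenvalues
  (< 1e-6 gap), where component directions are not identifiable.
* EM: ≤ 200 iterations, log-likelihood tolerance 1e-8, variance floor
  10⁻¹² × window variance (below it the component is declared degenerate).
* Windows with fewer than 8 residuals use the single-Gaussian threshold.
* Episode and cluster ids are 1-based and stable (order of first appearance).

## Problem sizes in packaged checks

The packaged acceptance computations use: 1000 dung samples per species for
profile means; the 40-sample reference library for ordination; 200 replicate
single-source cores (24 samples each) for attribution recovery; 10 replicate
charcoal cores and 50 replicate 1000-step null series for the fire-episode
statistics.  These sizes give standard errors comfortably inside the asserted
tolerances while keeping a full run under a minute.

## Known limitations

* Attribution is categorical; bison and elk are not separable from zoostanols
  alone (by design of the reference data, the bison/elk group is one cluster).
* The deterministic chronology propagates no age uncertainty; influx and
  episode ages inherit this.
* The charcoal noise model assumes locally stationary residuals within the
  window; strong heteroscedasticity across a window biases the threshold.
* The synthetic generators share the analysis' own distributional assumptions
  (Dirichlet compositions, Poisson counts); they validate the machinery, not
  the geochemistry.
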