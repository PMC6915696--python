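# Methods

## Background and model

Bivalent antibodies raised against polyglutamine (polyQ) tracts bind more
epitopes on longer tracts, so in a sandwich immunoassay the signal per mutant
huntingtin (mHTT) molecule grows with polyQ length (avidity bias).  A
non-polyQ antibody pair reports total HTT independently of tract length.
`polyqlen` turns this bias into a quantitative readout: the ratio of the two
channels' responses is a monotone function of polyQ length, and inverting a
calibration built from purified standards yields the *average* polyQ length
of a mixed protein population — a protein-level analogue of the average CAG
repeat length that fragment-analysis PCR measures at the DNA level in
tissues with somatic repeat instability.

The computation proceeds in four stages.

**1. Dose–response calibration.**  Each standard's signal-vs-concentration
curve is fitted with the four-parameter logistic model

    y(x) = Bottom + x^h (Top − Bottom) / (x^h + EC50^h)

by weighted least squares with weights 1/y², the standard immunoassay choice
when the measurement CV is approximately constant on the relative scale.
The optimizer is a bounded trust-region least-squares run from a
deterministic list of six starts (Bottom = min signal, Top = max signal,
EC50 ∈ {concentration nearest the half-range signal, geometric mean of the
positive concentrations}, Hill ∈ {0.5, 1, 2}); the best converged solution
wins, so fits are reproducible and independent of point ordering.
Replicates enter as individual points, never pre-averaged.  Signals ≤ 0 are
rejected under 1/y² weighting rather than clamped; a fitted Bottom absorbs
the background, so no blank subtraction is performed.  Parameter SDs come
from the Gauss–Newton covariance at the solution.

**2. Linear dynamic range.**  In the proportional regime the assay obeys
`signal = slope × concentration` (after Bottom subtraction).  The linear
range is made operational with immunoassay-validation-style criteria: among
all windows of ≥ 3 consecutive standards, a window is accepted when the
weighted through-origin fit has (uncentered) R² ≥ 0.98 **and** every point's
back-calculated concentration is within ±20 % of nominal; the widest
accepted window wins, ties broken toward lower concentrations.  The
through-origin slope over that window, with its regression SD, is the
channel's response slope.  These two criteria and their thresholds are this
package's design choice for an otherwise under-determined notion of
"linear range"; they are deliberately conservative (at Hill = 1 the ±20 %
rule keeps concentrations below ≈ EC50/4).

When a whole channel's standards come from one assay and one dilution
series, `fit_standard_series` establishes a single linear range for the
channel — the overlap of the windows accepted per standard — and refits
every slope over it (`common_window=True`, the default).  Letting each
standard keep its own window makes slopes jump between windows with
different curvature shrinkage under noise, which inflates the variance of
slope ratios well beyond the replicate noise; a shared window removes that
jitter while `determine_linear_range` remains available as the per-series
primitive.

**3. PolyQ calibration and inversion.**  The per-length ratio
r(Q) = slope_polyQ(Q) / slope_total is regressed on Q with four candidate
families — linear r = a + bQ, logarithmic r = a + b ln Q, power r = aQ^b,
exponential r = a e^{bQ} — each fitted by least squares *on the ratio
scale* (log-scale closed forms serve only as starting values), so the R²
used to select the winning family is comparable across families.  Ties
within 10⁻⁹ go to the simpler family in the order listed.  Each family has
a closed-form inverse; a measured ratio (with SD, from the standard ratio
error-propagation formula sd(A/B) = (A/B)·√((sd_A/A)² + (sd_B/B)²)) maps to
an average-polyQ estimate with delta-method uncertainty
sd_Q = sd_r·|dQ/dr|.  Monte-Carlo inversion is available behind a flag for
nonlinear families at large relative SDs, where the first-order
approximation degrades (at 10 % input CVs it already deviates ≈ 3 % from
the sampling SD of a ratio).  Estimates outside the training ratio range
are returned but flagged `extrapolated`, never clipped — the method is used
far beyond its standards in practice.  Both slope ratios and
background-subtracted signal ratios at a matched load are valid inputs; the
latter requires linear-range operation, which the caller asserts.

**4. Average CAG from peak traces.**  Fragment-analysis traces are reduced
per allele: peaks below 5 % of the allele's tallest peak are discarded, the
surviving heights are normalized to sum to one, and the weighted mean of
repeat lengths is the allele average; a sample's combined value is the mean
of its allele averages.  The 5 % threshold is applied per allele group
because alleles are analyzed individually (a global-threshold mode exists
for traces whose alleles share a height scale).  Without explicit allele
windows, alleles are split at the largest gap between consecutive repeat
lengths, requiring a gap ≥ 2 repeats; expanded knock-in alleles sit far
from wild-type ones, so the gap is unambiguous in practice.  Fragment sizes
in bp are converted as repeat = (size − flank)/3 with a configurable flank
length, and same-repeat peaks merge by summing heights.

## Parameter-trend prediction

Across standards the 4PL parameters separate into length-independent
(Bottom, HillSlope — pooled as means) and strongly length-dependent (Top,
EC50 — each given its own regression family as in stage 3, with a constant
fallback when a parameter shows no Q variation).  `predict_curve_for_q`
assembles a full predicted dose–response curve for any polyQ length in the
calibrated domain, which extends quantification below the strict linear
range.  A non-monotone fitted Top(Q) raises a warning flag rather than an
error.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of the experiments with explicit,
seeded parameters:

- **Standard curves** follow the 4PL with channel rules
  Top_polyQ(Q) = 200·Q counts, EC50 = 500 pM, Hill = 1, Bottom = 100 counts
  (polyQ channel), and constant Top = 10 000 counts for the total channel;
  concentrations are a 2-fold dilution series 0.78–1600 pM (12 levels) with
  duplicate wells.  The series deliberately reaches near-background at the
  low end and > 3×EC50 at the high end so that both plateaus of the 4PL are
  anchored by data: when the lowest standards sit well above background the
  fitted Bottom is an extrapolation whose error propagates into
  length-dependent slope bias.  The implied ratio rule
  r(Q) = (200Q − 100)/9900 is affine in Q,
  matching the strong linear-type correlation the linear range exhibits.
  Noise is multiplicative log-normal, unit mean, default CV 5 %, with
  independent streams per antibody channel (channels are read from separate
  plates; correlated noise would cancel in the ratio and understate its
  variance).
- **Mixtures** are additive over species in the linear range:
  signal = Σᵢ fᵢ·C·slope(Qᵢ) + Bottom.  With an affine ratio rule this
  makes the mixture's ratio exactly the ratio at the fraction-weighted mean
  Q — the identity the zero-noise tests assert to 10⁻⁹.
- **Peak traces** draw n molecules multinomially from a discretized
  Gaussian centered at modal + bias with dispersion `spread` (default 3
  repeats, 2000 molecules).  The kernel is symmetric; expansion bias enters
  as a mean shift rather than a skewed tail, which satisfies every property
  the pipeline relies on while staying analytically transparent.  Real
  traces add PCR stutter and skewed expansion distributions the generator
  does not model.
- **Cohorts** draw each sample's true average CAG uniformly over an
  instability range, take polyQ length equal to the average repeat number
  (any affine CAG→Q map would only rescale the regression slope), and
  report the mean of duplicate noisy ratios.  The attached ratio SD is the
  model-based standard error ratio·CV/√n: with duplicates the empirical SD
  is a χ²(1) variable that exceeds its expectation by > 40 % a quarter of
  the time, and the generator's CV is a characterized constant, so the
  model-based SE is the honest measurement model.

Passing tests on these data therefore demonstrate internal consistency of
the full chain (curve fitting → slopes → calibration → inversion;
trace → weighted average; protein-vs-DNA regression), robustness at a 5 %
measurement CV, and exactness of the closed-form identities.  They do not
demonstrate robustness to matrix effects, antibody lot variation, plate
position effects, PCR stutter, or non-log-normal noise — none of which the
generator models.

## Numerical choices

- 4PL bounds: EC50 ≥ 10⁻¹², Hill ∈ [10⁻⁶, 50]; a solution with Top < Bottom
  is reported in canonical orientation.
- Degenerate calibration inputs (zero response variance, < 3 distinct Q,
  non-positive responses for log/power families) raise typed errors rather
  than returning silently bad fits.
- Family-selection tie tolerance: 10⁻⁹ on R².
- Fractions must sum to 1 within 10⁻⁶; normalized peak weights sum to 1
  within 10⁻¹² (asserted).
- Detection-limit QC uses a strict inequality: a signal exactly at
  background + k·SD fails.
- Problem sizes in the validation scripts — 8 standards × 9 concentrations
  × 2 replicates per channel, 200 replicate cohorts of n = 14, 10⁶
  Monte-Carlo draws, 10³ random traces — were chosen to keep every check
  comfortably overpowered at desk scale.

## Known limitations

- The delta-method SD is first-order; at input CVs ≳ 10 % prefer the
  Monte-Carlo inversion flag.
- The linear-range criteria are a reconstruction of standard validation
  practice, not a universal definition; assays with steep Hill slopes may
  need the back-calculation tolerance revisited.
- Whether mixture fractions are molar or mass is not distinguished; the
  package treats them as molar throughout.
- Allele splitting assumes two well-separated clusters; highly mosaic
  traces whose alleles merge into one cluster require explicit windows.
- Inter-batch (day-to-day) precision is out of scope; all precision
  statements are intra-batch.
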