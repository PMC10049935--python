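# Methods

## Corneal optics

A spherocylindrical surface is represented by the three-component
power vector (veq, v0, v45): the mean meridional power and the
projections of the steep-minus-flat cylinder onto the 0°/90° and
45°/135° meridians. Note that the astigmatic components carry the
**full** cylinder, not the half-cylinder of the Jackson-cross (J0/J45)
notation; for the negative-power back surface the signed cylinder is
negative. Radii and intraocular distances are stored in mm and
converted to metres wherever a power is formed, so powers are always
in dioptres. Axes are degrees of the flat meridian, normalised to
[0, 180); all operations are invariant under axis → axis + 180° and
rotating the axis by 90° negates (v0, v45), which is the same as
swapping the two meridians.

A power vector maps to the symmetric 2×2 matrix
[[veq+v0, v45], [v45, veq−v0]], and back via veq = (p11+p22)/2,
v0 = (p11−p22)/2, v45 = (p12+p21)/2 — the unique extraction that makes
the pair mutually inverse. The Gullstrand thick-lens formula
P = Pa + Pp − Pp·Pa·d/n_C is evaluated on these matrices with the
product in the order Pp·Pa; for crossed surface axes the product is
slightly asymmetric and the off-diagonal mean in the extraction
absorbs that asymmetry. The matrix eigenvalues are the principal
powers veq ± √(v0²+v45²), and for coincident axes the chain reduces
exactly to the scalar thick-lens formula applied meridian by meridian
(both are asserted in the test suite).

Default indices: n_cornea = 1.376, n_aqueous = n_vitreous = 1.336.
The keratometer index (default 1.3375, i.e. 337.5/R with R in mm) is
configuration and only enters the classical keratometric power K12;
the thick-lens total power is independent of it. The radius
back-calculated from an equivalent power takes its index step Δn as an
explicit argument, since conventions (0.376, 0.3375, 0.336) differ
between instruments and papers.

## IOL power

The pseudophakic eye is three refracting surfaces: corneal front and
back surfaces at their spherical-equivalent (mean-radius) powers, and
the IOL as a thin lens at the effective lens position (ELP, from the
corneal front apex). The vergence chain starts from the target
spherical equivalent at the spectacle plane (vertex distance default
12 mm; for a plano target the vertex term drops out exactly), adds the
front surface power, propagates CCT inside the cornea (n = 1.376),
adds the back surface power, propagates ELP − CCT through aqueous
(n = 1.336), and the IOL power is the jump needed for the exit
vergence n_vitreous/(AL′ − ELP).

ELP is a linear predictor a + b·ACD + c·LT + d·AL (Castrop-style;
default ELP = ACD + 0.30·LT + 0.20 mm, representative constants for a
modern hydrophobic acrylic one-piece IOL — per-lens optimised
constants should replace them in clinical use). AL′ is the axial
length remapped for power calculation only, defaulting to the Cooke
modified-axial-length regression 1.23853 + 0.95855·AL − 0.05467·LT.
An `identity()` configuration (ELP = ACD, AL′ = AL) exists for testing
and as a neutral baseline. Guards reject an ELP outside (CCT, AL) and
a conjugate focus landing exactly on a surface; the batch comparison
skips such eyes and logs them.

## Conversion models

Calibration transfer between devices is the affine map y = b + A·x on
power vectors. The full model is three OLS regressions of each target
component on all three source components — identical point estimates
to multivariate Gaussian ML with unrestricted residual covariance.
The reported log-likelihood is the Gaussian likelihood under the ML
(denominator-n) residual covariance with all 2π constants included;
its value is data-dependent and serves only for relative comparison.
The diagonal variant suppresses cross-talk (three simple regressions).
Cross-validation splits the cohort by a seeded random permutation
(default 70% train), fits on the training part and summarises the
Euclidean norm of the prediction error on both parts (mean, SD,
median, empirical 2.5/97.5 percentiles); the seed is an explicit
argument, never hidden state.

The six published IOLMaster700↔Anterion conversions (front, back,
total; both directions) are shipped as data. Their reverse
intercepts are the negated forward intercepts rather than −A⁻¹·b, so a
published forward/reverse pair composes to the identity only to a few
hundredths of a dioptre over the physiologic range, although the
matrices themselves multiply to the identity within ~1e−4 entrywise;
`invert_conversion` provides the exact algebraic inverse instead.

## Statistics

Percentile estimates use linear interpolation of the order statistics
(numpy's default); SDs use the n−1 denominator. The paired-difference
sign convention is everywhere device H minus device Z. Bland-Altman
regresses differences on pairwise means by OLS and reports slope,
intercept, R² (defined as 0 for constant differences) and the RMS of
the fit residuals; Q1/Q3 are reported for violin-style summaries. The
double-angle summary gives the centroid and sample covariance of
(Δv0, Δv45) with an error ellipse scaled to 95% bivariate-normal
coverage (chi-square, 2 df). The empirical CDF is the right-continuous
step function i/n.

## Synthetic cohort generator

The generator draws a latent truth per eye and lets each device
observe it through a systematic offset plus additive noise — the
simplest generative model consistent with reported paired
device differences. Details and deliberate simplifications:

* AL, ACD, LT are a truncated multivariate normal. The correlations
  (AL–ACD +0.45, AL–LT −0.30, ACD–LT −0.45) are **assumptions** chosen
  as physiologically plausible, not measured values. CCT is drawn
  independently. Truncation is rejection sampling at ±3.5 SD.
* Each corneal surface is a latent mean radius plus a latent
  astigmatism vector with independent Gaussian components; the
  positive mean of v0 for the front surface encodes the
  with-the-rule predominance of a cataract-age population. Devices
  add noise in power-vector space, and the record is re-expressed as
  flat/steep radii with a flat-meridian axis — the representation real
  exports use. Latent radius SDs are set slightly below the
  device-visible SDs so that truth plus noise reproduces the observed
  marginal spread.
* Device-H systematics default to: ACD +0.120 mm, CCT −0.0078 mm plus
  a trend −0.05·(CCT − 0.5544) (slope chosen so the Bland-Altman
  regression on synthetic data is clearly negative; no published slope
  value exists), LT +0.0383 mm, AL −0.0146 mm, front mean radius
  −0.0004 mm, back mean radius −0.397 mm. Per-device noise SDs equal
  the target paired-difference SDs divided by √2.
* Not modelled: intra-device repeatability, operator effects, diseased
  or post-surgical corneas, axis-dependent noise anisotropy, and any
  dependence of the device offsets on eye geometry beyond the CCT
  trend. Passing tests therefore demonstrate the pipeline's
  correctness and the plausibility of the propagated magnitudes, not
  properties of any real instrument pair.

`inject_defects` corrupts a cohort (blanked fields, duplicated rows,
fellow-eye rows) so the exclusion filters can be exercised.

## Pipeline

Ingestion normalises device CSV dialects to a canonical schema
(mm, degrees; CCT optionally converted from µm), pairing is an inner
join on patient ID, eye and same calendar date, then one eye per
patient is kept by a seeded random choice. Exclusions run in a fixed
order — exact duplicates (keep first), clinical flags (pseudophakia,
pupil width strictly > 5.2 mm, refractive surgery, ectasia),
incomplete rows — because per-rule counts depend on the order; the
`ExclusionLog` enforces removals + survivors = input. Outputs are
written with 4-decimal precision. The default end-to-end run uses the
854-eye synthetic cohort; at that size the whole pipeline (including
cross-validation of three conversions and 2×854 vergence
calculations) completes in about a second.

## Known limitations

* The ELP and axial-length adjustment constants are representative
  defaults, not optimised for a specific lens; absolute IOL powers
  shift with better constants, while the inter-device *difference* is
  insensitive to them.
* Conversions are affine only; errors-in-variables or nonlinear
  calibration transfer is out of scope.
* Toric IOL power, exact ray tracing and aspheric surface models are
  out of scope.
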