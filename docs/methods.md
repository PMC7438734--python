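# Methods

This note documents the models, the tunable parameters, the synthetic-data
generator and the numerical choices behind `retphen`, in enough detail to
judge what its passing tests do and do not demonstrate about real data.

## ERG decomposition

### Component model

A dark-adapted flash ERG is treated as the sum of four components:

* **P3** (photoreceptoral): delayed-Gaussian saturation function
  `P3(i,t) = −RmP3·(1−exp(−i·S·(t−td)²))` for `t > td`, else 0.  Energy `i`
  is linear cd·s/m² (the public API carries energies in log₁₀ units and
  converts only inside model evaluation).  Time enters in milliseconds, so
  S carries units (cd·s·m⁻²)⁻¹·ms⁻²; the default synthetic truth
  S = 2·10⁻³ ms⁻² corresponds to ~2·10³ s⁻² in the more common
  seconds-based convention, giving a-wave saturation over a realistic
  5–15 ms leading edge at bright flashes.
* **P2** (bipolar): positive b-wave, amplitude Naka-Rushton in energy,
  `V(i) = Vmax·iⁿ/(iⁿ+Kⁿ)` with n fixed at 1 by default (configurable
  free).  The exponent is fixed because three-parameter fits on a
  ten-flash ladder are poorly conditioned; the reported "P2 sensitivity" is
  −log₁₀K.
* **OPs** (amacrine): 50–180 Hz wavelets on the b-wave rising limb.
* **pSTR** (ganglion cell): small positive bump near 110 ms, visible only
  at the dimmest flashes.

### Fitting and measurement chain

1. **Baseline**: each trace minus its mean over the pre-stimulus window
   (all samples with t < 0 by default).
2. **P3 ensemble fit**: one (RmP3, S, td) triple over the leading edges of
   the 3 brightest flashes.  Each segment runs from flash onset to the
   trace's a-wave trough, hard-capped at 20 ms after onset: the cap keeps
   dim-bright traces (whose troughs occur after post-receptoral intrusion
   begins) from biasing the ensemble.  The optimizer is a coarse
   (S, td) grid with RmP3 profiled in closed form (the model is linear in
   RmP3), polished by bounded least squares on (RmP3, log₁₀S, td).  A
   series with no negative deflection yields a flagged non-converged
   record with RmP3 = 0, never an exception.
3. **P3 subtraction** exposes the P2–OP complex.
4. **OP isolation**: zero-phase frequency-domain band-pass.  The amplitude
   response is real (hence exactly zero-phase) with raised-cosine-in-power
   skirts whose half-power points sit exactly at 50 and 180 Hz
   (−3.01 dB); transition half-widths are 20 Hz (low) and 30 Hz (high), so
   the passband (70–150 Hz) has unit gain and DC is fully rejected.  The
   P2 is the arithmetic complement, which makes the decomposition
   additive to machine precision by construction.
5. **Peak measurements**: P2 amplitude is baseline-to-positive-peak in
   20–150 ms (ties → earliest); OPs are summed positive peaks above a
   5 μV floor in 10–60 ms at the reference bright flash
   (2.07 log cd·s/m², the ladder maximum), implicit time at the largest
   peak; pSTR is the mean positive peak in 60–130 ms over the three dim
   flashes −4.90, −5.01, −5.31 log cd·s/m² (each must be present within
   0.01 log units, else the STR fields are flagged missing).  Before P2
   and pSTR peak reads the trace is passed through a zero-phase 55 Hz
   low-pass: both components are spectrally far below the cutoff, and the
   smoothing suppresses the upward bias a raw `max()` takes on broadband
   noise.
6. **Naka-Rushton fit** of P2 amplitude vs energy over flashes at
   ≥ −3.0 log cd·s/m².  Near-threshold flashes are excluded because their
   sub-μV b-waves are dominated by the noise floor of the peak
   measurement, which would bias K downward.  The fit profiles Vmax over a
   log-spaced K grid, then polishes by bounded least squares.

All operations are pure functions of their inputs and configuration;
repeated runs agree bitwise.

## OCT morphometry

Inputs are per-A-scan axial depths (μm, positive downward) of four
boundaries of the ONH-centred B-scan: ILM, posterior RNFL, posterior GCC
and the posterior retina.  Primary thicknesses are per-A-scan differences
averaged over included A-scans; IPL and ORT are then derived from the
averaged values, so `ipl = gcc − rnfl` and `ort = trt − gcc` hold to
machine precision on every record.  A-scans within 100 μm laterally of the
optic nerve head (configurable) are excluded, since the layered retina is
absent there.  Boundary ordering is validated per A-scan and violations
raise with the offending index.

## Histology quantification

The HSI convention is the classic bi-hexcone transform: intensity
I = (R+G+B)/3, saturation S = 1 − min/I, hue from the arccos chromatic
formula, reflected above 180° when B > G, undefined (reported 0 with a
flag) for achromatic pixels.  A pixel is stained iff hue, saturation and
intensity all fall inside the configured gamut; the hue interval may wrap
360°→0°.  The default DAB gamut (hue 10–50°, S ≥ 0.15, I ≤ 0.85) is a
configuration default, not a measured constant — thresholds are per-
magnification user inputs, and all exactness tests use gamuts defined by
the simulator.  Percent area = 100·stained/total; three sections per
location are averaged per animal; burden-vs-age is ordinary least squares
with a two-sided slope p-value.

## Assay quantification

Standard curves: linear or monotone quadratic (default for BCA) and the
four-parameter logistic (default for ELISA), fitted to replicate-averaged
standards.  The 4PL uses relative (1/Y²) weighting — read noise on plate
readers scales with signal — and positivity bounds on slope and midpoint;
a fitted curve that is non-monotone over the standard range raises (assay
failure).  Sample signals are inverted through the curve (closed form for
linear/4PL, bracketed root for quadratic) and multiplied by the dilution
factor; signals outside the standard signal range are flagged
below-detection / above-range, never clipped.  The insoluble-fraction
workup is a dilution chain (formic acid 1:4, Tris 1:20, PBS/casein 1:5 →
×400).  Aβ is reported as pg per mg total protein; the detection limit
rule is mean + 3·SD of control-tissue signals (configurable).

## Cohort statistics

Two-way ANOVA with genotype and age as fixed factors, Type III sums of
squares with sum-to-zero contrasts (group sizes are unbalanced), computed
via OLS.  On balanced designs this reduces to the classical cell-means
decomposition, which the tests verify against an explicit hand-computed
oracle.  The post hoc family is the genotype contrast within each age
(m = number of ages, 3 in the reference design): t statistics on the
pooled residual mean square with residual df, two-sided p, Bonferroni
adjustment `p_adj = min(1, m·p)`.  Normality screening is the one-sample
KS test against a normal with estimated mean/SD using the Lilliefors
correction (the uncorrected KS is anticonservative when parameters are
estimated).  Percent-of-baseline normalization divides each endpoint by
the 6-month WT cell mean; α = 0.05 throughout.  Eyes/animals are treated
as independent records; mixed-effects modelling is out of scope.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test
dial.  Per endpoint it holds a 6-month WT baseline, multiplicative
genotype factors per age, multiplicative age factors, and a between-animal
biological noise SD in endpoint units.  The frozen defaults:

| endpoint | baseline | genotype effect (5xFAD) | age effect | SD |
|---|---|---|---|---|
| RmP3 | 400 μV | ×0.80 at 17 mo | ×0.9/period | 32 μV |
| Vmax | 500 μV | ×0.80 at 17 mo | ×0.9/period | 40 μV |
| OP envelope | 40 μV | ×0.80 at 17 mo | ×0.9/period | 3.2 μV |
| pSTR | 25 μV | ×0.70 all ages | ×0.9/period | 2.5 μV |
| S, K, td | 2e−3, 0.05, 4 ms | — | — | 8–10 % |
| RNFL | 20 μm | ×0.92 all ages | — | 0.6 μm |
| IPL | 60 μm | ×1.06 at 6 mo | — | 1.8 μm |
| ORT | 140 μm | — | — | 4.2 μm |

Biological noise is additive and homoscedastic across cells (matching the
ANOVA's assumption); only stain fractions and Aβ concentrations, which
span orders of magnitude between genotypes, use a multiplicative spread.
Measurement noise is separate: 5 μV white noise on waveforms, 2 μm axial
jitter per OCT boundary, 2 % CV on plate signals.  The SD magnitudes were
fixed once from the power the reference design evidently had (it resolved
these effect sizes at n ≈ 8–16 per cell) and are not revisited.

Waveforms are the four-component sum above: the b-wave is a unit-peak
gamma density with a 15 ms synaptic onset delay peaking at 95 ms; the OP
packet is a 115 Hz Gabor (σ = 8 ms) centred at 40 ms with a smooth onset
gate from 20 ms; the pSTR is a Gaussian bump (110 ms, σ = 15 ms) present
only at flashes ≤ −4.5 log cd·s/m².  The onset delay and gate are
physiological (post-receptoral components do not begin at the flash) and
keep the P3 leading edge component-pure, which is what makes noiseless
round-trip recovery exact to optimizer tolerance rather than merely
approximate.  The stimulus ladder has 10 energies from −5.31 to
2.07 log cd·s/m², containing exactly the STR triple.

OCT boundaries add a common-mode sinusoidal curvature (which leaves every
thickness untouched) plus per-boundary axial noise; with zero noise the
derived thicknesses equal the truths exactly.  Stain images are
flat-colour (DAB brown in-gamut on haematoxylin-blue background) with a
blob mask trimmed to an exact integer pixel count, so programmed area
fractions are recovered to the pixel.  Plates generate standards and
duplicate sample wells from a known curve truth with multiplicative read
noise.

Everything is a pure function of (design, config, seed); per-subject
streams derive from `numpy` `SeedSequence` spawning, so cohorts are
reproducible element-wise.

### What the generator does not emulate

Real ERGs have correlated (non-white) noise, drift and blink artifacts;
real b-wave shape varies with energy; real OPs are not a fixed-frequency
Gabor.  Real OCT has speckle and segmentation ambiguity; real histology
has texture, lighting gradients and partial-volume colour mixing.  Passing
round-trip tests therefore demonstrates correctness of the analysis
algebra and estimator behaviour under the stated noise model — not
robustness to every artifact of real recordings.

## Default problem sizes

Tests and the acceptance script use the reference design's group sizes
(ERG 5xFAD 8/12/12 and WT 11/12/15 per age; OCT 5xFAD 8/12/14, WT
13/13/16), 10-flash ladders sampled at 4 kHz over −20…250 ms, 100 seeded
series for recovery studies, 200 replicates for null calibration and 50
full-cohort replicates for the qualitative-pattern study.  The pattern
check is strict — pSTR deficits at all ages, P3/P2/OP deficits at 17
months *and not before*, RNFL thinning at all ages, IPL thickening at
6 months, each with the programmed sign — so Bonferroni-level false
positives alone (six null comparisons per replicate at adjusted α) cap the
attainable full-pattern rate near 0.90; the observed rate at the frozen
configuration is ~0.85–0.90 against the ≥ 0.80 criterion.

## Known limitations

* The delayed-Gaussian is fitted only on leading edges; it does not model
  photoreceptor recovery, so the subtracted P3 is held at saturation late
  in the sweep (as the saturating model dictates).
* OP summary amplitude (sum of positive peaks above a floor) is monotone
  in burst energy but not strictly proportional to the envelope, so OP
  endpoints are compared as ratios/contrasts, not absolute truths.
* The Naka-Rushton exponent is fixed at 1 by default; steep
  intensity-response data need the free-exponent option.
* Detection-limit handling and assay curve forms are conventional defaults,
  configurable per run.
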