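# Methods

`venasl` implements the quantification chain of a multi-modal MRI study of
venous hyperintense ASL signal (VHS) and whole-brain oxygen extraction
fraction (OEF) in typically aging adults, together with the synthetic data
needed to verify every stage by parameter recovery.  This note documents the
models, the defaults and why they were chosen, the numerical choices, and
what the synthetic validation does and does not establish.

## ASL kinetic model

The label-control difference signal per unit equilibrium magnetization is
the standard continuous-labeling kinetic solution with a single exchange
time: labeled arterial water decays with the longitudinal relaxation time of
blood, T1b, during transit; arrives at the voxel after the arterial transit
time (ATT) as a boxcar bolus of the labeling duration LD; and thereafter
relaxes with the apparent tissue time T1app, where

    1/T1app = 1/T1_tissue + f / lambda,    f = CBF / 6000  [1/s]

(the second term is venous clearance of label at the perfusion rate).  With
t measured from labeling onset (t = LD + PLD at readout):

    dM(t) = 0                                                     t < ATT
    dM(t) = (2 alpha f / lambda) T1app e^(-ATT/T1b)
            (1 - e^-((t-ATT)/T1app))                    ATT <= t < ATT+LD
    dM(t) = dM(ATT+LD) e^-((t-ATT-LD)/T1app)                  t >= ATT+LD

The closed form is verified in the test suite against direct quadrature of
the underlying delivery–relaxation ODE (agreement ~1e-10 relative).  It is
isolated in `venasl.kinetics.kinetic_model_signal` so an alternative
two-compartment variant can be swapped in without touching the fitting
code.  Published multi-delay pipelines use two-compartment formulations
whose exact constants are not publicly specified; the single-exchange
solution is the standard closed-form, invertible choice.

Defaults (all configurable through `KineticConstants`): labeling efficiency
alpha = 0.85 (pCASL), partition coefficient lambda = 0.9 mL/g, T1_tissue =
1.3 s, blood relaxation rate 1/T1b = 0.52·Hct + 0.38 (1/s), assumed ATT for
single-delay quantification 1.5 s (an age-appropriate value for a 60–80
cohort; the literature gives no single number).

## Multi-delay quantification

ATT is estimated per voxel by two-stage normalized cross-correlation of the
measured per-delay curve against model templates: a coarse grid 0.2–2.5 s in
0.1 s steps, then a fine grid ±0.1 s in 0.01 s steps around the coarse
argmax.  Normalization makes the match invariant to positive scaling, so
template shape is computed at a nominal CBF of 60 mL/100g/min; ties resolve
to the smaller ATT (first argmax of an ascending grid).  Voxels whose curve
has non-positive mean are flagged invalid rather than fitted.

CBF then comes from per-voxel nonlinear least squares over all delays
(`scipy.optimize.least_squares`), initialized by linear projection onto the
unit-CBF curve, with optional continuous ATT refinement inside one
fine-grid step.  Absolute units come from dividing by the voxel's M0; voxels
with M0 at or below 10% of the robust (positive-median) M0 are excluded.

Single-delay maps are produced by inverting the kinetic model at the
assumed ATT via damped fixed-point iteration on the perfusion-dependent
scale factor (the CBF dependence of T1app is weak, so convergence to 1e-10
takes a handful of iterations).  The resulting map is *nominal*: values are
retained — including negative ones — in venous sinuses, CSF, and bone,
where the perfusion model is deliberately invalid, because the venous
readout of interest is exactly this nominal signal.

VHS is the mean nominal value over the venous-sinus mask restricted to a
mid-sagittal slab, 12 voxels wide by default, centered on the midline index
floor(n/2) (for even widths the slab spans [mid − w/2, mid + w/2)).
Adjacent gray-matter, CSF, and bone signals use the same slab and must be
disjoint from the sinus mask.

Framewise displacement uses the Power-style formulation: per-transition sum
of absolute translation differentials plus rotation differentials converted
to arc length on a 50 mm sphere (radius configurable; some motion tools
default to other radii).

Oxygen delivery: DO2 = phi · Ya · [Hb] · CBF / 100 with phi = 1.34 mL O2
per gram hemoglobin; the /100 reconciles [Hb] in g/dL with CBF in
mL/100g/min, giving mL O2/100 g/min.

## TRUST oxygenation

Venous blood signal isolated by label-control subtraction at effective echo
times 0/40/80/160 ms decays as S = S0 exp(−eTE · R_apparent).  The fit is
unweighted nonlinear least squares over all echo times jointly, initialized
log-linearly when all signals are positive (the acquisition's weighting
scheme is not standardized; unweighted NLLS is isolated so alternatives can
be substituted).  T2 of blood follows from 1/T2b = R_apparent − 1/T1b(Hct);
an apparent rate at or below the longitudinal rate is an error, not a
clipped value.  The calibration 1/T2b = A(Hct) + B(Hct)(1−Y) + C(Hct)(1−Y)²
is inverted on its monotone branch (unique root for B, C > 0).  The shipped
default coefficient set,

    A = −13.5 + 80.2 h − 75.9 h²,  B = −0.5 + 3.4 h,  C = 247.4 h²  [1/s]

follows the shape of established human-blood calibrations at a 10 ms
refocusing interval; coefficients are configuration, not constants, and the
validation relies exclusively on forward/inverse consistency, never on
absolute literature values.  OEF = (Ya − Yv)/Ya, reported as a fraction
internally and percent in reports; out-of-range values are flagged, not
clipped.

## Phase-contrast flow

Velocity is linear in phase up to the encoding limit (v = VENC·phase/pi);
phases beyond ±pi indicate aliasing and are rejected rather than unwrapped
(acquisitions choose VENC to avoid aliasing).  Vessel area comes from the
polygon geometry (shoelace, via shapely) scaled by the pixel area, while
mean velocity averages over the rasterized pixel set (pixel-center
inclusion, pixel (i,j) centered at (i+0.5, j+0.5)); both masks are
available because a drawn ROI conflates the two roles.  Flow = area ×
mean velocity × 60 (mL/min).  Bilateral carotid measures combine by summing
areas and flows; the combined velocity, flow/(area·60), is the
area-weighted mean of the side velocities.  Vertebral arteries are excluded
from the default analysis set.

## Cohort statistics

Group descriptives compare subjects with and without radiological VHS:
Welch's t-test when the pooled variable passes Shapiro-Wilk at alpha = 0.05,
otherwise Mann-Whitney U (the pooled-versus-per-group scope of the
normality gate is a genuine design choice; pooled is the default and
configurable).  Sex uses Fisher's exact test, race chi-square.  The
correlation matrix reports pairwise-complete Pearson r with two-sided
t-based p-values and a Bonferroni family of p(p−1)/2 tests — 78 for the 13
hemodynamic variables.  Pairwise-adjusted models put each predictor in a
two-covariate model of OEF; the diagonal holds univariate p-values,
presented unadjusted (optional correction available).

Stepwise selection emulates MATLAB `stepwiselm` defaults: starting from the
intercept, add the candidate with the smallest partial F-test p-value below
0.05; after each addition remove any term whose F-test p-value exceeds
0.10 (worst first); stop at a fixed point.  Ties break by candidate column
order; candidates collinear with the current model cannot enter; a
perfectly fitting model admits nothing further.  Missing data are listwise
for regressions, pairwise for correlations.  Rating agreement is Kendall
tau-b with tie correction; consensus ratings take the per-subject mode of
the four ratings and flag 2-2 splits for manual resolution.

## Synthetic data: what it emulates and what it does not

The digital phantom is a nested-ellipsoid head (bone shell, CSF, GM shell,
WM core, ventricles) with a straight mid-sagittal venous tube under the
inner skull and carotid stubs; CBF/ATT are smooth random fields around
tissue means (GM 68 / WM 25 mL/100g/min; ATT 1.35 / 1.6 s).  The ASL
simulator is the exact forward model of the quantifiers, with the venous
difference signal injected at a known nominal amplitude through the same
single-delay scaling the quantifier inverts, frame-wise rigid motion by
linear-interpolation resampling (rotations about the volume center), and
i.i.d. Gaussian noise.  It does not emulate realistic anatomy, distortion
or B0 artifacts, slice-timing effects, background suppression, partial
volume at tissue boundaries, or physiological noise — so passing recovery
tests establishes correctness of the implemented inversions, not robustness
to those real-data effects.

The cohort generator draws, per subject: CBF, Hb, Hct, Ya, CMRO2
independently (moments matching the study population: CBF 68.1 ± 11.0,
Hb 13.9 ± 1.3, Hct 0.417 ± 0.032, CMRO2 4.95 ± 0.55); ATT as a decreasing
function of CBF (central volume theorem) calibrated to r(ATT, CBF) ≈ −0.4;
DO2 through the delivery equation; and a latent lognormal(0, 0.5)
"capillary shunt severity" s that acts on both sides of the hypothesized
mechanism:

    OEF = clip(CMRO2/DO2 · (1 − 0.06 s), 0.05, 0.95) + noise(0.015)
    VHS = 1.0·CBF + 25·s + noise(8)

The shunt coefficients are free parameters — the study provides no
quantitative shunt-to-VHS mapping — chosen once so that VHS ≈ 96 ± 20
nominal units and OEF ≈ 0.37, near the published cohort moments, with an
extraction-efficiency penalty (~6% per unit severity) large enough to be a
detectable mechanism at n ≈ 200 yet small relative to delivery-driven OEF
variability.  Clipping beyond 10% of subjects emits a warning rather than
truncating silently.  With the shunt mechanism off, VHS carries no
information about OEF beyond oxygen delivery; a small (|r| < 0.03) linear
partial-correlation remnant survives because OEF depends on delivery
through 1/DO2 while partialling is linear.

## Problem sizes and numerical tolerances

The validation suite uses 32³ phantoms (64³ where the phantom's field
statistics are themselves under test), 500-voxel multi-delay recovery sets,
100-seed cohort replicates at n = 200, and 1000-replicate null
calibrations — sizes at which Monte-Carlo error is well below the asserted
margins while the whole suite runs in seconds.  Noise robustness is
evaluated at a temporal SNR of 5, defined on the label-control difference
series (per-pair difference noise SD equal to one fifth of the voxel's peak
difference signal) with per-delay averaging over the 43 acquired pairs
(9/9/9/8/8).  Solver tolerances: decay and perfusion fits run at
xtol/ftol = 1e-12 – 1e-15; the single-delay inversion iterates to 1e-10;
quadratic calibration inversion is closed-form.

## Known limitations

* The kinetic model is a single-exchange approximation; pipelines using
  full two-compartment water-exchange formulations will differ in absolute
  CBF by a model-dependent factor.
* Single-delay quantification is biased whenever the true transit time
  differs from the assumed 1.5 s; this mirrors the acquisition it models
  and is why its outputs are treated as nominal.
* Motion simulation resamples ideal volumes; it does not model
  intra-readout blurring, spin-history effects, or interpolation-induced
  partial voluming, so motion-related conclusions from the phantom are
  about the displacement metric, not about artifact generation.
* The statistics battery is (multi-)linear throughout, matching the
  analysis it reproduces; nonlinear delivery–extraction coupling is only
  partially captured by linear adjustment.
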