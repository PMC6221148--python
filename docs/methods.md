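# Methods

This note records the models implemented in `mimicvis`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that matter for reproducing
results.

## Spectra and the working grid

All spectra live on a closed, uniform wavelength grid; the default is
300–700 nm at 1 nm, chosen to cover both passbands of a UV photography
setup (UV-pass 320–380 nm, UV/IR-cut 400–680 nm) with margin. All
integrals are trapezoidal on this grid — exact for piecewise-linear
integrands, and at 1 nm spacing the discretization error of the
templates is far below every tolerance used in the tests. Resampling is
linear interpolation; extrapolation outside a spectrum's support
requires an explicit policy (`"zero"` or `"hold"`) and is an error
otherwise.

The CIE D65 relative spectral power distribution ships as a 10 nm table
(100 at 560 nm) and is interpolated to the working grid. A `"flat"`
equal-energy illuminant is available for analytic test cases.

## Receptor sensitivities

Receptor spectral sensitivities are reconstructed from peak wavelength
alone with the Govardovskii A1 nomogram (alpha band plus beta band),
peak-normalized to 1. The template constants live in
`PigmentTemplateParams`, so an A2 or refitted template can be injected
without touching calling code. Two consequences worth knowing:

- The beta band makes the summed template's argmax sit up to one grid
  step below the alpha-band $\lambda_{\max}$ for UV pigments (e.g. the
  355 nm UV1 template peaks at 354 nm on the 1 nm grid). The documented
  contract is argmax within ±1 grid step.
- Ocular media and oil-droplet filtering are not modeled. The
  red-shifted *H. erato* long-wavelength receptor is represented purely
  by its effective 600 nm peak (vs 555 nm unfiltered), which is how the
  filtering pigments' effect is conventionally summarized.

## Visual-system presets

Channel abundances ($\eta$) follow published retinal counts: blue tit
LW 1 / MW 0.99 / SW 0.71 / UV 0.37; peafowl MW 1 / LW 0.95 / SW 0.86 /
V 0.45; *H. erato* female LW 1 / B 0.17 / UV1 0.086 / UV2 0.076 and male
LW 1 / B 0.2 / UV2 0.13. Peak wavelengths without a published value for
these observers (bird UV/V/SW/MW/LW, butterfly B) are editable defaults
in `data/presets.yaml`, documented as defaults rather than claims. The
Weber fraction is 0.05 on the most abundant channel for every preset;
rarer channels get $e_i = \omega\sqrt{\eta_{\max}/\eta_i}$ (abundance-
scaled Weber noise; no intensity-dependent quantum-limited term). Bird
presets carry a double-cone achromatic channel with $e_D = 0.05$
(configurable); the butterfly presets carry none, and achromatic
operations reject them rather than guess.

Catches are normalized per channel to a flat 40% gray standard under the
scene illuminant (von Kries), mirroring the photographic gray standard;
normalized catches are therefore invariant to global illuminant
rescaling. Receptor signals are logarithmic ($f = \ln q$), the
bright-light Weber–Fechner regime appropriate for reflective targets in
daylight; this choice is an assumption, flagged here, since linear
signals are sometimes used for dim conditions.

## Discrimination model

The chromatic distance uses the general n-receptor form: project the
log-signal differences onto the subspace orthogonal to the achromatic
(equal-shift) direction under the inverse-noise-variance metric,

$$\Delta S^2 = \sum_i w_i (\Delta f_i - \bar f_w)^2,\quad w_i = 1/e_i^2 .$$

This is algebraically identical to the standard dichromat, trichromat
and tetrachromat closed forms; the tests verify the reduction to 1e-12
on random instances and against a second route that explicitly inverts
the noise covariance on the opponent subspace. The discrimination
threshold defaults to 3.00 JND with a strictly-greater convention
(exactly 3.00 counts as not discriminable), since values *below* 3 are
the ones described as hard to discriminate.

## Camera pipeline

The simulated camera has four Gaussian channels truncated to the filter
passbands (UV at 350 nm inside 320–380; blue/green/red at 460/540/600 nm
inside 400–680); real sensor curves are not published for this setup, so
synthetic channels with the correct passbands stand in. The forward
model applies a power-law (gamma) response to gray-normalized linear
responses, plus optional Gaussian read noise; `linearize_normalize`
inverts it exactly (round trip to 1e-12 without noise).

The camera-to-receptor mapping is per-receptor ordinary least squares
from normalized camera responses to gray-normalized catches, with an
intercept and optionally all pairwise channel products (the polynomial
degree used by existing toolboxes is not standardized, so both are
offered; linear is the default). The training library is a generic set
of smooth reflectances with a positive floor (baseline + broad Gaussians
+ optional long-pass edge, clipped to [0.02, 1.2]) — analogous to the
natural-spectra libraries used in practice. The floor matters: patches
that are essentially zero across a whole band (deep red in the UV) have
near-zero catches there, and *relative* prediction error on such catches
is unbounded for any mapping. With this library the held-out median
relative catch error is about 1% for the *H. erato* female target; the
UV2 (398 nm) receptor is the least well served because its peak falls in
the 380–400 nm gap between the two camera passbands.

Spatial image handling is deliberately reduced to per-patch mean
responses; there is no pixel-level segmentation, demosaicing, or
vignetting model.

## SWS1 classification

DNA fragments are translated with the standard code (frame chosen
automatically as the one without internal stops); the 11-residue tuning
window (sites 84–94, bovine rhodopsin numbering, 1-based) is taken at an
explicit offset, verbatim for exact-length inputs, or located by a
per-position consensus motif for longer proteins. The default call is
UVS ⇔ (C90 ∨ F86) — the minimal rule consistent with the packaged
reference windows and the spectral-tuning literature. Site 93 is carried
in the data model but unused by the default rule; whether additional
sites modulate calls in taxa beyond the packaged set is left open.
Non-standard residues at a key site produce an `unknown` call with a
warning rather than an error.

## Comimic-vs-conspecific statistics

Within each stratum (ring × patch color × wing side × visual system),
all cross-species pairs are comimic records and all within-species pairs
conspecific records; an optional species restriction limits conspecific
pairs to the clade with measured visual data (the butterfly-vision
case). Each individual's pairwise JNDs are averaged by pair type; the
square-root transform is applied *after* this averaging; and the
contrast is tested with the balanced two-level repeated-measures F
(individuals as random factor), which with one value per individual per
pair type equals the squared paired t on (1, n−1) degrees of freedom. A
within-individual label-flip permutation test is provided as a
robustness companion. Strata are tested independently with no
multiplicity correction — deliberately, matching common practice in this
literature; interpret families of strata accordingly.

One property of this design deserves emphasis: the per-individual means
share pair partners, so the paired differences are positively correlated
across individuals and the F test is anti-conservative under a true
null. In seeded simulations with zero species divergence the rejection
rate at α = 0.05 is roughly 13–17% rather than 5%, and grows with sample
size; an independent idealized simulation (scalar traits,
absolute-difference distance, same averaging) reproduces the same rates,
so this is a property of mean-pairwise-distance testing itself, not of
the implementation. The statistical engine is exactly calibrated when
its assumptions hold — on independent per-individual tables that are
normal on the transformed scale, the simulated type-I error is 0.05 —
so significant results from strongly divergent scenarios remain
meaningful, but p-values near the threshold should be read with this
inflation in mind.

## Mate-choice GLM

Trials are aggregated per male × treatment: successes are events toward
the comimic model, failures toward the conspecific, the weight their
sum; replicate observation periods are summed per male before fitting,
and zero-event rows are retained with weight 0 (they drop out of the
likelihood). The logit-link binomial GLM is fitted by IRLS (convergence
when the largest coefficient change is below 1e-10, cap 50 iterations);
complete separation is flagged as non-convergence with a warning rather
than an error. Wald z and two-sided normal p are reported per
coefficient. Designs are explicit and named: `intercept_only`,
`treatment`, and `treatment_x_behavior` (requires a table stacking the
approach and courtship aggregations); behaviors are fitted separately by
default. Aggregated and per-event Bernoulli data give identical fits,
and the implementation matches an independent reference GLM to ~1e-8
when both are run to tight convergence.

## Synthetic generators

Wing-patch reflectances are logistic long-pass curves (near zero in the
short wavelengths, rising at an inflection to a plateau) plus an
optional UV Gaussian lobe for the UV-reflecting yellow and white
pigments. Defaults per color class: yellow (inflection 500 nm, plateau
0.70, UV lobe at 350 nm), white (400 nm, 0.85, weak UV lobe), orange
(560 nm, 0.65), red (600 nm, 0.60). Individual variation has a
multiplicative lognormal factor (cv 0.05) and a normal jitter of the
inflection wavelength (1.5 nm; 4 nm for red, emulating age-related
fading of the red pigment). The spectral jitter is essential: a purely
multiplicative factor is removed by gray normalization and log signals,
so it produces exactly zero chromatic JND. Species divergence within a
ring is a controllable inflection shift (and optionally a UV-lobe
amplitude shift) applied to the second species.

`calibrate_ring_scenario` finds, by bisection against the generator
itself, the jitter and divergence whose simulated mean conspecific and
comimic JNDs hit requested targets (defaults 1 and 6 JND under the blue
tit model) — used by the end-to-end power checks. Choice trials are
binomial draws per male × treatment with known log odds returned as
ground truth; a preset scenario reproduces the aggregate scale of a
published experiment of this design (41 males, ~709 approaches, ~62
courtships) for smoke-testing the full pipeline.

What the generators do *not* emulate: iridescence, spatial pattern
geometry, pigment chemistry, specular effects, and measurement
covariance between wing sides. Passing tests on synthetic data therefore
validate the computational pipeline and its statistical behavior, not
the biological fidelity of any particular reflectance model.

Every generator is a pure function of the `numpy.random.Generator`
passed in; reruns with the same seed are bit-identical, and ground truth
is always returned alongside the data.

## Problem sizes and determinism

Simulation-based checks use 200-rep power/null studies with 10
individuals per species and one stratum, 2,000-rep calibration studies
for the test levels, and 500-rep recovery studies for the GLM — sizes at
which Monte-Carlo error is small relative to the asserted bands while a
full test run stays comfortably fast. The orchestrated run
(`run_full_analysis`) derives all stage seeds from one configured seed
and writes byte-identical outputs on rerun; TSV outputs use six
significant digits by default, full precision behind a flag.

## Known limitations

- No ocular-media or oil-droplet filtering; template-only sensitivities.
- Achromatic contrast is defined only for observers with a double cone.
- The F test's anti-conservatism on mean-pairwise-distance data (above)
  is inherited from the analysis design it implements.
- The camera model is synthetic; fitted mappings transfer to real
  cameras only after refitting with measured sensor curves.
- UVS/VS calls rest on two sites; taxa with unusual tuning chemistry
  would need an extended rule set.
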