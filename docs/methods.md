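# Methods

This note documents the models behind `emibrain`, the parameters that
matter, and what the synthetic study does and does not demonstrate.

## Forward model and coordinate conventions

All geometry is head-centered: x in meters toward the patient's left,
y toward anterior, the sagittal mirror line fixed as the y-axis.  The
default array places 16 antennas on a 110 mm × 130 mm ellipse at
angles 11.25° + k·22.5°, so no element sits on the mirror line and the
mirror pairing k ↔ (7 − k) mod 16 is a fixed-point-free involution.

The device's physics is replaced by a desk-scale linear surrogate: a
2-D scalar-Helmholtz Born (single-scattering) model in a homogeneous
lossy background representing the coupling medium (εr = 45,
σ = 0.15 S/m).  With the e^{−jωt} convention the complex permittivity
is ε_c = ε′ + jσ/(ωε0), the wavenumber k_b = ω√(μ0ε0ε_c) has positive
imaginary part, and the outgoing Green's function
G = (j/4)H0⁽¹⁾(k_b r) decays with range.  Scattering is

    S_ij(f) = G(r_i, r_j) + k_b² Σ_pixels G(r_i, r′) χ(r′) G(r′, r_j) ΔA

with χ the complex contrast against the background; the kernel is
symmetric, so reciprocity S_ij = S_ji holds exactly (enforced to the
bit by symmetrization).  The Born model is linear in contrast and has
no multiple scattering, no skull shadowing and no dispersion beyond
the σ/ω term — see *Limitations*.

Pixel pitch is 2 mm (λ_background/10 at 1.8 GHz ≈ 2.5 mm is the
validity bound, enforced); the grid spans ±120 mm × ±140 mm with pixel
centers at exact signed multiples of the pitch so that mirror
symmetry on the lattice is bitwise exact.  Antenna-to-pixel Green's
tensors are cached per (array, grid, sweep, background) combination.

## Phantoms and study conditions

A head phantom is a two-layer ellipse: coupling background outside,
homogeneous brain-average interior (εr = 42, σ = 0.75 S/m — between
white- and grey-matter values near 1 GHz; a package assumption), and
optionally one circular inclusion.  Hemorrhage raises the local
properties (+18 relative permittivity, +0.8 S/m by default), ischemia
lowers them (−12, −0.4); the signs are the physics, the magnitudes are
documented assumptions since measured stroke contrasts at these
frequencies are not standardized.  Inclusion centers are drawn
uniformly inside 80 % of the boundary, radii uniformly from
7.5–25 mm; per-patient head ellipses vary (semi-axes 70–92 mm ×
88–112 mm).

Cohort simulations use 41 frequency points across 0.7–1.8 GHz (the
core default sweep is 201 points; 41 is the package's study size and
leaves the band shape fully resolved at these aperture sizes).  Each
patient contributes 20 repeat scans at 30 dB per-channel SNR under one
session drift realization (per-port complex gains ~5 %, reciprocal
per-channel leakage offsets), with a 25 % chance of one
motion-corrupted (+20 dB) outlier scan.  The two homogeneous
calibration disks (εr = 38/0.55 S/m and 52/0.95 S/m, bracketing the
head average; exact clinical values are unpublished) are measured
under the same drift but averaged over the same number of repeats, so
their noise floor sits 10·log10(20) ≈ 13 dB lower.

## Calibration and preprocessing

Two-phantom calibration solves, per channel and frequency, the complex
affine map m(S) = gS + o carrying the measured reference responses
onto their model-predicted ("synthesized") responses, and applies it
to patient data.  This inverts any per-channel affine distortion —
in particular the per-port gain/offset drift model — exactly.
Channels whose two references are numerically indistinguishable, whose
solved gain is a wild outlier (reference separation below the noise),
or whose calibrated output violates the |S| sanity bound are flagged
uncalibratable and masked downstream.

Stability gating expresses each consecutive-scan RMS delta in dB
relative to the series' mean power and drops scans all of whose
adjacent deltas exceed the threshold; a single corrupted scan raises
both of its neighboring deltas and is removed exactly.  The function
default is −35 dB; the pipeline uses −20 dB because at the study's
30 dB SNR the scan-to-scan noise delta alone sits near −28.5 dB
(10·log10(2·10^{−3})), and a gate below the noise floor would reject
every scan.  Two consecutive corrupted scans can mask each other —
a known limitation of the neighbor rule.

The head contour (Algorithm I's clinical deep network, here a
desk-scale stand-in) is a per-parameter gradient-boosted regressor
from the 16 reflection-magnitude spectra (interpolated onto 21 fixed
frequencies) to the ellipse (cx, cy, a, b), trained on 400 seeded
phantoms with randomized geometry and classes at 30 dB SNR.
Validation mean semi-axis error is ~2 mm; predictions are clamped to
the anatomical range 60–120 mm and flagged when clamping occurs.

## Visibility graphs and the classifier ensemble

Calibrated spectra are windowed (Hamming), zero-padded (factor 4),
hermitian-extended and inverse-transformed to real time signals.  Each
channel's signal becomes a weighted horizontal visibility graph —
samples i < j are linked iff every intermediate sample is strictly
lower than both — built by a linear-time stack algorithm with edge
weights |x_i − x_j| (floored at 1e−12 so node strengths stay
positive).  Node degree, strength and incident-weight entropy
(−Σ p ln p in nats) are averaged per channel into three 16×16 metric
matrices M; the hemisphere differential D = M − PMPᵀ (P the mirror
permutation) isolates the asymmetry a unilateral stroke introduces.

The classifier feature vector has 48 entries:

* 13 summaries per differential matrix (Frobenius norm, max and mean
  of |entries|, a signed mean over the dominant hemisphere's channel
  block and a signed mean of that block's top-8 |D| entries, plus the
  8 left-hemisphere row norms).  The two signed statistics exist
  because the mirror involution maps D to −D entry-for-entry, so
  *every* permutation-invariant unsigned feature is blind to the sign
  of the dielectric contrast;
* 3 crossing-line signed differential means: channels whose
  transmit–receive segment passes within 10 mm of the beamography peak
  carry the contrast sign (on this forward model ischemia raises the
  crossing-line differential entropy, hemorrhage lowers it);
* 6 residual-signal summaries: mean HVG degree/strength/entropy over
  all channels and over the crossing channels, computed on the
  residual against a healthy forward-model synthesis on the estimated
  boundary.  The residual waveform flips nearly in sign between the
  two stroke classes and the visibility graph is sign-sensitive, which
  makes these features informative even for near-axis inclusions where
  every mirror-differential quantity degenerates.

Four probability classifiers (random forest, kNN, Gaussian naive
Bayes, RBF-SVM) are trained on a seeded cohort of 120 patients
(40/class).  The forest sees all features; the distance- and
density-based classifiers are fit on the top-8 forest-importance
features (selected on training data only).  At inference the four
probability vectors are fused by a certainty-weighted mean (weight =
each classifier's max probability), renormalized.

## Localization

Clutter — the dominant mirror-symmetric response of the head — is
removed by subtracting each channel's sagittal-mirror channel and then
the per-frequency channel mean.  The residual is back-propagated by
phase conjugation against the background Green's function; the default
steering vector is *phase-only* (unit-magnitude Green's factors)
because the lossy background otherwise biases extended-target peaks
toward their antenna-near edge (50-phantom median peak error 9.4 mm
with the amplitude-matched kernel vs 5.9 mm phase-only).  Channels
with both antennas on the healthy side duplicate affected-side
information and carry weight ½.

Mirror differencing leaves every unsigned image exactly
mirror-symmetric (a ghost target on the healthy side), so laterality
is decided once, by the Székely distance correlation between each
same-hemisphere channel's complex spectrum and the same channel of the
mirror-symmetric healthy model reference; the hemisphere with the
lower mean correlation is affected.  Comparing a channel against its
own mirror channel cannot decide the side — dCor is symmetric in its
arguments and the mirror map is an involution, so the two hemisphere
means coincide identically; that mode is retained as a fallback and
always reports its ambiguity.  Score differences under study
conditions are small (10⁻³–10⁻²) but their sign is reliable; the
0.01 ambiguity margin is therefore reported as a flag, not used as a
decision override.  Side calls are unreliable only for inclusions
straddling the midline, where "side" is ill-defined.

DMM maps each ordered antenna pair to a polar cell (sector = circular
midpoint angle, ring radius R(1 − sep/8) so diametric pairs probe the
center), filling cells with sensitivity-weighted frequency-aggregated
|ΔS| under the mirror reference; detection thresholds the total image
mass at 3σ of a healthy-cohort null.  Typing evaluates the phase of
the matched correlation Σ w ΔS conj(G_i G_j) — positive real part
means raised permittivity (ICH) — on the *background-reference*
residual at the matched-correlation maximum within 15 mm of the
beamography peak: the mirror reference cancels the stroke's own signal
for near-axis inclusions and plants an opposite-phase ghost, while the
background residual keeps the full contrast sign everywhere.  The
sign convention is verified on a noise-free hemorrhagic phantom at
training time and recorded in the model bundle.

EVSLA builds mirror-symmetric patch pairs by clipping the
quadrilateral through antennas (i, j, mirror(j), mirror(i)) — for
same-hemisphere pairs with circular separation 1–3 — to the head
boundary and each half-plane.  Each patch's statistic is the
bounding-channel HVG-entropy dissimilarity between patient and
calibration reference, differenced against the mirror patch, floored
at zero, and median-gated with an absolute activation floor of 1e−6
nats (float-level left/right residue must never activate a patch).
Pixel values are the mean statistic of the active patches covering
them.

## Fusion

The four modality images are resampled onto the common grid, min–max
normalized, and — once a stroke is called — masked to the affected
hemisphere, which resolves the mirror ambiguity every
symmetry-differenced modality shares.  Agreement voting (≥ K of 4
above τ = 0.5, K relaxed from 3 until non-empty) runs on the
*smoothed* normalized modalities so that the sharply peaked
back-propagation blob is not outvoted by the broad coarse maps; the
fused heatmap is a reliability-weighted mean (beamography 2, others 1)
of the Gaussian-smoothed modalities (σ = 2 px) inside the agreement
mask dilated by a 2 px disk.  The heatmap peak gives the quadrant
call (+y anterior, +x patient-left; on-axis peaks break toward
anterior, then left, and are flagged).  Decision fusion combines the
ensemble's probability vector with the DMM call mapped to a
pseudo-probability vector (detected type 0.8, others 0.1; no
detection → healthy 0.8) by the same certainty-weighted mean.

The pipeline is deterministic under fixed seeds; `report.json` is
byte-identical across reruns (stage timings go to a separate log so
they cannot break the determinism contract).

## Numerical choices

* Reciprocity enforced by explicit symmetrization (exact).
* Ellipse rim pixels: grid coordinates are signed pitch multiples so
  mirror membership tests are float-exact; disk radii used in
  equivariance tests avoid the lattice distance spectrum.
* Degenerate calibration channels: flagged when |high − low| falls
  under 1e−6 of the reference scale, when the solved gain exceeds
  50× its median, or when the output violates |S| ≤ 10.
* Entropy of degree-1 nodes is defined as 0; tiny negative rounding
  residue is clipped.
* Pixels within 3 mm of an antenna are excluded from back-propagated
  images (Green's-function singularity guard).

## Study sizes and runtimes (single CPU)

Model training: 400 boundary phantoms + 120 classifier patients,
~2 minutes.  Held-out evaluation cohorts: 60 patients (classification,
radii 7.5–25 mm) and 50 patients (localization, radii 10–25 mm),
~1.2 s/patient through the full pipeline.  The acceptance script runs
the complete study in about 3 minutes; the test suite in about 7.

## Limitations

The Born surrogate is linear: no multiple scattering, no skull/CSF
layering, no frequency-dispersive tissue models, and far weaker
lateral shadowing than a real head (a target's mirror image is
attenuated only by the lossy background, so mirror-differenced
magnitudes can approach twice the scattered-only signal).  Head
phantoms are mirror-symmetric ellipses, so the symmetry-based clutter
rejection is exact here but only approximate in vivo; the anatomical
asymmetry of real heads is represented solely by the average
subtraction stage.  Classifier and regressor training data come from
the same generative family as the evaluation cohorts — passing
accuracies demonstrate that the algorithms recover the information the
model encodes, not clinical performance.  Near-axis inclusions have no
well-defined affected side; typing remains reliable there only because
it uses the background-reference residual.
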