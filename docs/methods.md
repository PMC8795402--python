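# Methods

`ntcsim` is a desk-scale digital twin of a galvo–galvo two-photon scan
engine whose excitation path can be switched between a stock
diffraction-limited (DL) configuration and two non-telecentric (nTC)
configurations that illuminate the objective back aperture with a
diverging beam.  This note records the model, its assumptions, the
calibration of its free parameters, and the limits of what it can and
cannot predict.

## Paraxial model of the excitation path

The unfolded path is a sequence of ideal thin lenses along an optical
axis; the path coordinate (mm) runs from the scan-mirror pivot (0) toward
the sample.  The trains are built from the component values of the
hardware they emulate:

| element | DL | nTC1 | nTC2 |
|---|---|---|---|
| scan lens f=50 @ 56.6 mm | yes | — | — |
| L1 f=190, 190 mm before TL | — | yes | — |
| L2 f=175, 5–100 mm before TL | — | yes | — |
| L3 f=200, 5–100 mm before TL | — | — | yes |
| tube lens (TL) f=200 @ 306.6 mm | yes | yes | yes |
| objective, EFL 8.25 @ TL + 95 mm | yes | yes | yes |

The objective (a ×20/1.0 water-immersion lens) is an ideal thin lens of
effective focal length 8.25 mm (×20 on a 165 mm reference tube length)
whose plane coincides with its 16.5 mm back aperture.  Both galvos are
collapsed onto a single pivot; the inter-mirror separation is a
second-order effect at the angles involved.  The tunable lens (ETL) sits
200 mm upstream of the pivot and is a thin lens of power
`diopter_per_mA × current`.

Ray transport uses 2×2 ABCD matrices; beam transport uses the complex
beam parameter q of a Gaussian beam.  All axial sample coordinates are
air-equivalent millimetres; z is measured from the nominal focal plane
(the focus of the collimated DL beam) and is positive away from the
objective.  The immersion index (1.33) enters only the N.A. and PSF
closed forms, a simplification that reproduces the system's measured
axial differences without modelling the water column explicitly.

### Focus, N.A. and vignetting

`focus_solution` traces the chief ray (pivot, scan angle θ) for the
lateral focus position and transports q for the focal distance v below
the objective, the 1/e² beam radius at the aperture, and the effective
N.A. (Gaussian far-field divergence, clipped at the aperture-limited
cone and at the objective's nominal N.A.).  Vignetting is the power
fraction of the walking Gaussian footprint blocked by the circular back
aperture, evaluated by deterministic polar quadrature; a beam whose
transmission falls below 0.1 % is flagged fully vignetted rather than
raised as an error.

### Field curvature

The focal surface is modelled as a sphere centred on the back aperture
with radius equal to the on-axis focal distance v: as the scanned beam
tilts about the aperture its vergence is unchanged, so the focus forms at
a constant distance along the beam axis.  Hence
`z(θ) = sqrt(v² − r²) − f_obj` with r the lateral focus offset, and the
edge-to-centre sagitta is `v − sqrt(v² − r²) ≈ r²/2v` — quadratic in the
field radius, edges focusing shallower.  With v ≈ 9 mm for the nTC1
trains this reproduces the measured 20 µm (1.2 mm field) and 45 µm
(1.8 mm field) sagittas to better than 3 %; the four measured sagitta
values across both families are jointly consistent with a single ≈ 9 mm
focal sphere (quadratic fit R² > 0.999).

### Two-photon PSF closed forms

`psf_fwhm` uses the standard Gaussian-focus illumination closed forms
with the squared-intensity dependence of two-photon excitation: the 1/e
radii of the excitation profile are

    w_xy = 0.320 λ / (√2 NA)            NA ≤ 0.7
    w_xy = 0.325 λ / (√2 NA^0.91)       NA > 0.7
    w_z  = 0.532 λ / √2 · 1/(n − sqrt(n² − NA²))

and FWHM = 2 sqrt(ln 2) · w.  The lateral branches join with a ~2 %
step at NA 0.7, inherent to these published forms.  Both widths are
strictly decreasing in NA, axial exceeds lateral for NA < n, and the
low-NA limits scale as 1/NA (lateral) and 1/NA² (axial).

### Calibration of free parameters

Three quantities of the real instrument are not printed anywhere and are
therefore free parameters anchored to measured observables by
`calibrate` (deterministic least squares from fixed initial guesses):

| parameter | default | anchor |
|---|---|---|
| input 1/e² beam radius at the mirrors | 1.3933 mm | DL axial two-photon PSF FWHM 3.15 µm at λ = 927 nm, n = 1.33 |
| usable optical scan half-angle | 6.945° | DL square field side 0.5 mm |
| ETL gain (dpt/mA) | 0.06170 | 600 µm plane shift at 50 mA in nTC1 |

Duplicate, even contradictory, observables are legal and surface as
residuals; requesting a parameter the observables cannot constrain is an
error naming it.  A synthetic round trip (observables generated from
known parameters, then refit) recovers the truth to 10⁻⁶ relative.

The calibrated defaults give an effective DL excitation N.A. of 0.676 —
the under-resolution expected when a Gaussian beam fills a high-N.A.
aperture — and a DL lateral FWHM of 0.52 µm.

## Scan engine

Scan patterns are ordered rectangular regions, each with a per-line
z-profile (flat, mid-frame staircase jump, tilted plane with matched
y- and z-motion, sqrt-cosine "halfpipe" bend peaking at the centre line,
or a multiplane stack).  Timing is exact rational arithmetic: the line
period includes the turnaround, so an N-line frame at p ms/line runs at
exactly 1000/(N·p) Hz — which is why the activity-scan rates
(3.9062…, 7.8125, 5.8824…, 15.625 Hz) round to the familiar printed
values.  Multi-region (random-access) patterns additionally pay a
configurable number of blanked transition lines per jump (default 2);
rates are reported both with and without those lines, since the printed
rates for multi-region scans follow the active-lines convention.

`emit_waveforms` produces line-synchronised sample streams: the fast
mirror ramps over 1 − turnaround_fraction (default 10 %) of each line,
the slow mirror and the ETL command are constant within a line, and the
Pockels transmission is exactly zero on every turnaround, retrace and
transition sample and positive on every active-pixel sample.
`depth_power_compensation` maps each line's commanded depth through a
user law into per-line Pockels scales in (0, 1].

The ETL settling is a linear second-order system (natural frequency
450 Hz, damping ratio 0.5 by default), chosen so a 150 µm jump settles to
within 5 µm in ≈ 1.9 ms, inside the observed 2–3 ms decay; settling time
is the last threshold crossing of the closed-form step response and
matches an independent ODE integration to 0.05 ms.  The real lens's
nonlinearity and thermal drift are out of scope.

## Renderer

Phantoms are spheres with species-typical diameters — beads
0.175 ± 0.005 µm, fruit-fly larval somata 2–5 µm, zebrafish somata
5–10 µm, mouse cortical somata 15–25 µm — plus a dense uniform slab for
brightness profiling; generation is deterministic given the seed, which
is recorded in provenance.

A pixel's value is background plus, per emitter, brightness × the overlap
integral between the emitter sphere and the squared-intensity 3D Gaussian
excitation volume centred on that pixel's focus point, so PSF size, field
curvature, per-line z-profiles, stage z-steps and vignetting all shape
the image.  The overlap uses an analytic Gaussian-blob surrogate of the
uniform sphere (matched volume, per-axis variance R²/5), accurate to
~10 % against a brute-force Riemann integral over the tested radii and
exact in the point-emitter limit; the numeric integral (3 points per
FWHM by default) is available as a cross-check.  This reproduces the
size-selectivity of a large excitation volume: sub-volume objects dim
(signal ∝ volume) while PSF-sized objects remain bright.

The side-profile renderer projects the squared excitation along the slow
axis, orienting each Gaussian along the local chief ray so excitation
volumes tilt outward at the field edges; movies modulate emitter
brightness as base × (1 + kernel-convolved event train) with an
instantaneous-rise, exponential-decay calcium-like kernel, stimulus-
locked Bernoulli responses, Poisson spontaneous events and additive
Gaussian read noise under a recorded seed.  No shot noise, scattering,
photobleaching or collection-path physics is modelled.

## Analysis

FWHMs come from least-squares Gaussian + offset fits (failure is an
explicit result, never a silent number).  Bead-stack PSF estimation
detects beads as local 3D maxima above background + k·s.d. (k = 5 by
default; the detection rule is this package's choice), fits x/y/z
profiles through each maximum, excludes border-clipped beads, and
aggregates mean ± s.d. with the bead count.  Bead-size deconvolution is
not applied; estimates are reported as measured.  The activity map is
each pixel's mean Pearson correlation with its 8-connected neighbours
(4-connected optional; zero-variance pixels map to 0), bounded in
[−1, 1] and invariant to per-pixel affine intensity changes.  Traces are
z-scored against their own baseline window, and event-triggered averages
report the trial count.

## Reproducibility plumbing

Run configs are strict YAML/JSON documents (unknown keys rejected by
dotted path, defaults filled); a SHA-256 provenance hash and the global
seed are stamped into every output, and per-stage seeds are fanned out
deterministically via numpy's `SeedSequence.spawn`.  Reruns of the
deterministic stages are byte-identical.

## Validation and problem sizes

The test suite validates the engine against independent oracles: a
101-ray phase-space fan (brute-force minimal-RMS-spot search) agrees
with the Gaussian focus to ≤ 0.5 % across all presets and 11 movable-lens
positions; transfer-matrix determinants are 1 to 10⁻¹²; the Lagrange
invariant of a chief/marginal pair is conserved to 10⁻⁹ relative.
Render→measure round trips image 14 beads under the bead protocol
(30 × 30 µm, 256 × 256 px, 0.5 µm z-steps, 33 planes) and recover the
model PSF within 5 % with ≥ 10 usable beads; the five-configuration
ordering check uses 96 × 96 px stacks with pixel size and z-step scaled
to each configuration's predicted PSF, a sampling choice that keeps every
configuration's excitation volume equally well resolved.  Functional
checks use 64 × 64 px movies of ≤ 140 frames.

## Known limitations

* **nTC2 with the lens nearly touching the tube lens.**  At 5 mm
  separation the intermediate convergence point of the ideal-thin-lens
  train falls within ~4 mm of the back aperture, a region where the
  focal distance is hypersensitive to unprinted details (thick-lens
  principal planes, the movable objective head position, singlet
  dispersion at 927 nm).  The measured field curvature of this setting
  implies a ≈ 9 mm focal distance like every other configuration, while
  the thin-lens trace collapses to ≈ 2.7 mm; its predicted sagitta and
  focal shift are therefore unreliable, and the package reports them as
  the model computes them rather than forcing agreement.  A two-group
  thick objective could absorb this, but its parameters are not
  determinable from published component values, so the ideal-thin-lens
  objective is retained.
* **Field-of-view transfer between lens positions.**  The chief-ray
  magnification ratio between the far (100 mm) and near (5 mm) lens
  positions is fixed by the thin-lens geometry at 1.89 (nTC1) and 1.26
  (nTC2), whereas the measured usable-field endpoints imply 1.5 and 1.4.
  The discrepancy is the same unprinted thick-lens territory; anchoring
  the mirror range on one endpoint therefore over- or under-predicts the
  other by ~10–25 %.
* **Absolute PSF sizes of the nTC trains** depend on the unprinted beam
  parameters and on aberrations the paraxial model excludes; only the
  monotone ordering across configurations, the low-NA scaling laws and
  the render→measure consistency are treated as reliable.  (The measured
  lateral/axial pairs are themselves mutually inconsistent with a single
  ideal Gaussian focus, which bounds what any aberration-free model can
  reproduce.)
* Aberrations beyond field curvature (spherical, coma, astigmatism),
  pulse dispersion, collection optics and detector physics are out of
  scope; the side-view camera's instrumental blur is not emulated.
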