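# Methods

`dualsweep` models the computational core of a dual-foci axially swept
light-sheet microscope (ASLM) for cleared-tissue imaging: acquisition
timing, multi-immersion optical scaling, synthetic phantoms, PSF
quantification, informative-tile triage and acquisition planning.  This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not show.

## Optical model

**Gaussian sheet.**  The light sheet is a focused Gaussian beam with
waist radius `w0` (1/e² intensity radius) and Rayleigh range
`zR = π w0² n / λ`.  The radius profile is `w(z) = w0 √(1 + (z/zR)²)`;
the sheet *intensity* cross-section at axial offset z is Gaussian with
σ = w(z)/2, i.e. FWHM `√(2 ln 2) · w(z)`.  The instrument never states
an illumination NA, so the default `w0 = 0.4 µm` is an assumption
chosen to make the simulated system near-isotropic (see calibration
below); it is configurable (`optics.waist_radius_um`).

**Multi-immersion scaling.**  With a multi-immersion objective pair the
lateral magnification is modelled as linear in the immersion index:
`M(n) = M_ref · n / n_ref`, anchored at the single measured calibration
point `M(1.33) = 15.28`.  Pixel size is `p(n) = pitch / M(n)` with a
6.5 µm sensor pitch, giving 0.425 µm in water, and the field of view is
`2048 · p(n)` (871.2 µm in water; the instrument datasheet rounds this
to 870).  The identity `p(n)·M(n) = pitch` holds to machine precision
for every n.  Per-index measured magnifications, if available, can
override the linear model through the configuration.

**Dual remote focusing.**  Two stacked remote-focusing arms hold
mirrors at ±Δz around the nominal focus; a mirror displacement maps to
a sample-space focus displacement through an axial gain g, so the two
sheet foci sit `2 g |Δz|` apart — `round(2 g |Δz| / p(n))` camera rows,
ties rounded away from zero.  Neither g nor Δz is published for the
instrument, so the package calibrates their product so that the default
configuration yields exactly 1024 rows (half the 2048-row frame); both
are exposed in the configuration.

## Acquisition timing

**Rolling shutters.**  Row axis = sweep axis; row 0 = sweep start; the
readout direction is fixed (unidirectional chip).  In single mode one
band of `W` active rows sweeps all 2048 rows in the frame time T, so
each row is exposed for `W·T/2048`.  In dual mode two bands start at
rows 0 and 1024 and sweep 1024 rows each concurrently (the alternative
— one full-frame band trailing another by 1024 rows — is rejected
because the foci separation is fixed at half the frame while the frame
time stays T).  Per-row exposure becomes `W·T/1024`: exactly double at
equal T and W.  This is the signal side of the dual-foci trade; the
speed side is that each sheet travels only half the FOV, which is what
lets the validated minimum frame time drop from 100 ms (single, full
range) to 25 ms (dual, half range) — those two numbers are treated as
configuration facts of the instrument, not derived from the actuator
model.

**Drive waveform.**  A sawtooth: linear rise over T (the per-frame
acquisition time, pfAT), return over the flyback F, one camera TTL per
period, laser gated off during flyback.  The flyback default is
`F = 0.1·T` — the instrument literature discusses flyback only
qualitatively, so the 10% figure is a package default, configurable per
run.

**Actuator.**  The voice-coil focus actuator is modelled as a
second-order low-pass system with damping ζ = 0.8 and natural frequency
chosen so the 2% settling time `≈ 4/(ζ·ωn)` equals the catalogue 3 ms
response time.  `LagActuator` (pure transport delay) and
`IdealActuator` are available for controlled experiments.  The
synchronisation map samples the tracking error at each row's exposure
midpoint; with an ideal actuator it is identically zero by
construction, and in dual mode paired rows (r, r+1024) share one
window and hence one offset.

**Image formation.**  Expected photoelectrons at a voxel are emitter
brightness × per-row exposure × a separable Gaussian whose axial width
is the quadrature sum of the sheet cross-section at the row's
synchronisation offset, the detection blur and the emitter size
(Gaussian of FWHM = bead diameter), and whose lateral width is
detection blur ⊕ emitter size.  Detection blur is an isotropic Gaussian
with default FWHM 0.83 µm — a calibration chosen so the simulated
lateral system FWHM for a 0.5 µm bead in water is ≈ 0.97 µm, matching
the instrument's measured value *by construction, not as a claim*; the
axial default works out to ≈ 1.08 µm.  Counts are
`offset + gain·Poisson(e⁻) + N(0, σ_read)`, clipped to 16 bits with a
warning on saturation; all randomness flows from one seed per stack.

**SNR model.**  `SNR(e) = S·e / √(S·e + B·e + σ_r²)`.  For dual 25 ms
vs single 100 ms the per-row exposure ratio is 0.5, so the predicted
SNR ratio is bounded in [0.5, 1/√2 ≈ 0.707] across all noise regimes
(read-noise-limited to shot-limited).  The ~17% SNR decrease reported
for real tissue falls inside this bracket but is a tissue measurement
the simulator does not claim to reproduce.

## Phantoms

**Beads.**  Uniformly random positions by dart throwing with a minimum
pairwise separation (bounded rejections, then error), default diameter
0.5 µm, emulating sub-resolution beads in an agarose block.

**Tissue tiles.**  Low-resolution pre-scan tiles in two classes.  Empty
tiles are camera offset (100 counts) + Poisson background (20
photons) + Gaussian read noise (2 counts).  Informative tiles add
Gaussian blobs (default 5; σ 2–5 px laterally) and random-walk
filaments (default 2) with peak amplitude `contrast × σ_background`
(default contrast 10).  At contrast → 0 the classes are statistically
indistinguishable and triage AUC collapses to 0.5 — tested.  The real
pre-scan's pixel size and tile geometry are unpublished; the default
tile is 8 planes × 96 × 96 px, which comfortably exceeds the 40×40
triage kernel while keeping full-protocol dataset generation (2 × 2,080
tiles) to tens of seconds.  `make_dataset` stores axial MIPs by default
since both triage paths consume MIPs.

What the tiles do **not** emulate: realistic tissue texture,
vignetting, stitching seams, depth-dependent attenuation, or
class-ambiguous boundary tiles.  Passing triage tests therefore shows
the classifiers separate *cleanly separable* classes at the stated
contrast — not that they reach the same accuracy on real tissue.

## Triage

**Intensity recipe** (exact): axial MIP → box-mean with 20×20 kernel −
box-mean with 40×40 kernel → count pixels strictly above 2.5 → score =
percentage of pixels; tiles with score < 0.1% are non-informative
(informative iff score ≥ 0.1%).  Numerical choices: symmetric edge
padding; for even kernels the origin is offset toward the lower index
(window `[i−k/2, i+k/2−1]`); the difference image is float (the 2.5
threshold applies to float values); box sums use integral images on the
integer count image so they are exact in float64 and bit-for-bit
reproducible against a naive nested-loop reference.  The score is
invariant to adding a constant (unit-DC-gain filters cancel it) but not
to rescaling (absolute threshold) — both asserted.

**CNN**: blocks of (3×3 conv, ReLU, 2× max-pool), global average
pooling, one sigmoid output.  Defaults: 4 blocks, 8/16/32/64 filters,
64×64 input (tiles are MIP-projected, resized, and scaled by the 1st–
99th intensity percentiles of the training split), binary cross-entropy,
Adam at 1e-3.  Protocol: deterministic 80/20 split per seed, batch 32,
early stop after 10 epochs without validation-accuracy improvement
(cap 40 epochs), checkpoint saved at each improvement, CSV log with one
row per epoch.  The network is implemented directly in NumPy (im2col
convolutions with finite-difference-verified gradients) and sized so
the full protocol trains in a few minutes on one CPU core; width,
depth and input size are configurable.  Prediction probabilities are
clipped to (0, 1) so threshold 0 selects everything and threshold 1
nothing (label = informative iff p ≥ threshold).

## Planner

Tile grids use ceil-based minimal covering per axis with stride
`(1−overlap)·FOV` (lateral) or `(1−overlap)·depth` (axial) and the last
tile flush with the box edge; default overlap 10% (the protocol
specifies "a defined overlap" without a value).  Frames per stack =
`ceil(depth / p(n))` because the stage steps one pixel per frame.
pfAT totals are `n_stacks × frames × frame_time` and *exclude* flyback;
the total imaging time adds per-frame flyback and per-stack delays and
its components sum exactly.  Hours are reported to 2 decimal places,
round-half-even.  Worked-example note: the published time totals imply
≈ 425 frames/stack while the published byte totals imply ≈ 386; both
are carried as explicit inputs where used (425 for the 4.93 h pfAT
check, 386 for the 7.03 TB check) rather than silently reconciled.

## Known limitations

- The linear-in-n magnification model is a one-point calibration;
  real per-medium magnifications deviate at the percent level.
- The actuator model is an LTI stand-in; the real device's large-signal
  nonlinearity (which sets the 100 ms single-mode floor) is not
  modelled — the per-mode minimum sweep times are configuration facts.
- Instrument-measured quantities (0.97 µm bead FWHM, deconvolved
  0.80 µm, the tissue ~17% SNR drop, the 99.42% validation efficiency
  on real tiles) require the physical microscope or its images and are
  represented only by the property-based substitutes tested here:
  estimator bias < 1%, Richardson–Lucy monotone sharpening with ≤ 1%
  flux drift, SNR-ratio bracket [0.5, 1/√2], monotone axial-width
  degradation with synchronisation offset.
- Problem sizes in the test-suite simulations (64×64-row sensors,
  40-plane stacks, 200-tile triage batches) are the package's chosen
  desk-scale defaults; the classifier acceptance run uses the full
  2 × 2,080-tile protocol.
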