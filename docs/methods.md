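# Methods

This note documents the models, parameter choices and numerical conventions
behind `hpcsi`, and what the synthetic experiments do and do not establish
about real data.

## Scope and geometry

The device is an 8-well (4 × 2) PDMS plate read out by a dynamic 2D CSI
sequence: 8 × 8 matrix over a 40 × 40 mm field of view (5 × 5 mm voxels,
12 mm slice), 15° nominal flip, 64 excitations per image (one per
phase-encode step), repetition time 66.907 ms, 51.2 ms FID readout, one
image every 4 s, acquisition starting 25 s after dissolution.

Two geometric conventions deserve a note:

* **Layout pitch.** The physical plate has a 15 mm center-to-center pitch,
  which together with the 6 mm chamber diameter spans ~51 mm — more than
  the 40 mm field of view can hold. The default *imaging-frame* layout
  therefore uses a 10 mm pitch (centers at x ∈ {−15, −5, 5, 15} mm,
  y ∈ {−5, 5} mm), which keeps every chamber inside the imaged region and
  places each chamber center exactly on a corner shared by four voxels, so
  each well is quantified from exactly 4 voxels. `pitch_mm` and the centers
  are configurable for device-frame work.
* **Sequence timing.** 64 × 66.907 ms = 4.282 s slightly exceeds the
  nominal 4 s frame interval. The acquisition container tolerates up to
  0.35 s of overrun; per-pulse simulation compresses the pulse spacing to
  min(RT, Δt/n) so the train fits the frame.

Voxel–chamber assignment takes, per chamber, the k = 4 voxels with the
largest circle–voxel overlap area (computed with shapely's polygonal circle
at 1024 segments; agreement with midpoint-rule numerical integration is
tested), ties broken by row-major index, no voxel serving two chambers.

## Fluidic calibration

The volume model V_w = (V_t − V_d)/8 hard-codes the 8-way split, so the
least-squares dead volume has the closed form V_d = mean(V_t − 8 V_w); the
free-slope straight line is reported purely as a diagnostic of that split.
On the four bundled loading measurements the constrained fit gives
V_d = 576 μL with R² = 0.979. (A published R² of 0.96 for this experiment
was presumably computed on per-chamber raw data rather than the four means;
the package reports what it computes.)

## Kinetic model

All steps are first order or pseudo-first order in the excess peroxide
(~8 M; its consumption is negligible), so per chamber dc/dt = K c with a
constant generator K. Propagation uses `expm(K Δt)` per grid step — exact
for a linear network — and peroxide-dependent rates are zeroed in control
wells. Default rate constants (all configurable, units s⁻¹):

| step | default | rationale |
|---|---|---|
| pyruvate → intermediate | 0.012 | pyruvate's apparent decay during frames is nearly identical with and without peroxide, so its net kinetic loss is small |
| intermediate → CO₂ | 0.17 | the 181 ppm apparent decay (~0.50) exceeds the RF/T₁ baseline (~0.33) by this much |
| CO₂ ⇌ peroxymonocarbonate | 0.015 / 0.003 | slow net production keeps both product signals growing through the observation window |
| hydration ⇌ | 0.002 / 0.010 | a few percent hydrate at equilibrium |

A constant-rate model cannot simultaneously show the near-complete
pre-acquisition conversion of pyruvate *and* its near-zero conversion rate
during the frames; the fast initial burst (mixing during sample delivery)
is therefore expressed through the configurable chamber state at injection
(default reaction well: 26 mM pyruvate, 4 hydrate, 30 intermediate, 11
peroxymonocarbonate, 9 CO₂ — summing to the 80 mM delivered), with the
modest constant rates applying thereafter. The injection is placed at
t = 21 s, 4 s before the first frame; the transfer period before it only
scales the initial polarization (a global factor under uniform T₁).

## Spin physics

Hyperpolarized magnetization is treated as a per-species
polarization-weighted concentration vector M. Conversion carries the C1
nucleus — and its polarization, without loss — between pools, so M obeys
dM/dt = (K − diag(1/T₁)) M between pulses; every excitation multiplies M by
cos θ and the frame signal is sin θ · M sampled at the frame's first pulse.
Thermal-equilibrium recovery is neglected (hyperpolarized ≫ thermal).
T₁ is uniform at 60 s by default — the same assumption the concentration
correction makes — with per-species values supported.

Two integration modes exist: `per-pulse` (64 discrete cos θ events at the
effective repetition time) and `frame-lumped` (one cosⁿθ factor per frame).
For a non-reacting pool both give the exact per-frame survival factor
cosⁿθ·e^(−Δt/T₁); with kinetics slow against the repetition time they agree
within 5% (tested).

Because the effective flip angle on a given scanner depends on B₁
calibration, the generator can be configured to any *observed* apparent
decay rate r ≥ 1/T₁ via θ = arccos(exp(−(rΔt − Δt/T₁)/n)). This is how
measured apparent constants (e.g. ~3 s pyruvate decay dominated by RF
consumption) are emulated; the nominal 15° would predict a faster 1.75 s
constant.

## Spectral synthesis and reconstruction

Data are synthesized at the voxel level, post-reconstruction — k-space
encoding, B₀/B₁ maps and excitation profiles are out of scope. Each
species contributes exp(i2πΔf t − t/T₂*) with Δf from its ppm offset at
32.13 MHz (¹³C, 3 T) and T₂* = 1/(π·FWHM), default FWHM 53 Hz. (The
printed "1.8 ppm (53 Hz)" pair is internally inconsistent at this field —
1.8 ppm ≈ 58 Hz; the package standardizes on 53 Hz.) The spectral axis
spans 5 kHz (155.6 ppm) centered at 170 ppm so all five resonances fall in
band; out-of-band species raise an error rather than alias. Noise is
i.i.d. complex Gaussian per point, seeded; identical configuration + seed
reproduces the dataset bit-for-bit.

Reconstruction: optional exponential apodization, orthonormal FFT
(spectral energy equals FID energy), magnitude. Chamber spectra sum the
mapped voxels' *complex* FIDs in canonical (sorted) order before the
magnitude — synthetic phases are coherent, so signal adds linearly and
noise in quadrature. The analysis default zero-fills ×8 so that peak
heights are insensitive to where a resonance falls on the frequency grid.

Magnitude lineshapes have two consequences worth knowing:

* the magnitude of a Lorentzian is √3 wider at half maximum than its
  absorption part (≈92 vs 53 Hz here), and
* its tails fall off as 1/Δf (dispersive) with a floor of ~2/(2πΔf·T_acq)
  from the 51.2 ms readout, so a peak separated by Δf from a neighbor of
  relative amplitude ρ carries a height bias up to ~ρ·FWHM/(2Δf).

The 181/184 ppm pair (96 Hz apart) is below the readout's resolving power;
their windows are split at 182.5 ppm and no lineshape deconvolution is
attempted.

## Quantification

Peak height is the maximum magnitude in a per-species window (default
±1.5 ppm, with the explicit 181/184 split); the integral is the window sum
times the ppm step; SNR divides the height by the standard deviation of
the magnitude in a signal-free region (140–152 ppm by default), estimated
per spectrum. Detectability uses SNR > 5. Because the height is a maximum
statistic over ~5 independent points, pure noise exceeds that threshold in
a few percent of windows — decay fits therefore use the contiguous prefix
of frames above threshold (once a decaying signal enters the noise, later
crossings are flukes), extended to a minimum of 3 points.

Mono-exponential fits use a log-linear start refined by nonlinear least
squares; noiseless exponentials are recovered to machine precision.
Constant series return rate 0 with a warning; non-positive values are
excluded and flagged.

The concentration correction divides every species series by
D(t) = S_ref(t)/S_ref(t₀), the pyruvate signal of a peroxide-free well —
under uniform T₁ and a shared pulse schedule this is exactly the common
polarization decay — and then normalizes each species to its own first
frame. The output is the relative concentration change versus initial;
multiplying by a known initial concentration gives mM. Frames where the
reference falls below the SNR threshold terminate the series (no
extrapolation). Replicate wells of one condition can be pooled at the FID
level (`pooled_condition_peaks`), which raises SNR by √(replicates)
without the baseline bias that averaging magnitude heights would add.

## The recovery fixture

`noiseless-kinetics` is the fixture used to validate the correction round
trip: zero noise, uniform T₁, the full reaction network *without* the
hydrate, and a narrow 2 Hz linewidth. The two idealizations are
deliberate: the hydrate sits 96 Hz from the intermediate — inside the
magnitude-tail bias radius at any realistic linewidth — and at 53 Hz the
tail bias between the remaining peaks (≥161 Hz apart) would still reach
several percent times the amplitude ratio. The fixture isolates the
kinetic/polarization logic from that measurement bias, which is
characterized separately (see above) and documented as a limitation of
magnitude-mode quantification at the instrument linewidth. On this fixture
the corrected series match the generator's kinetics within 4% of each
species' initial concentration across all ten frames.

## What the synthetic data do not emulate

Chamber-to-chamber loading variation (the source of real replicate
dispersion at the ~20% level), B₀/B₁ inhomogeneity, lineshape distortions
and baseline roll, CO₂ bubbling (available only as a first-order escape
term, off by default), temperature/pH drift of rates, and thermal
detection of the urea reference wells (modeled as signal-free geometry
markers). Absolute SNR and mass sensitivity depend on coil and hardware
factors the generator does not model; passing tests establish correctness
of the *analysis*, not instrument-level sensitivity figures.

## Problem sizes

Default runs use 10 frames × 8 × 8 voxels × 256 complex points (×8
zero-fill in analysis), a 0.25 s kinetic grid, and 5-seed replicates for
noisy recovery checks — all chosen so the full test suite and the
reproduction script complete in well under a minute on one CPU while
leaving the statistical checks comfortable margins.
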