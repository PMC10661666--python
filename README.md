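# hpcsi

Analysis and simulation toolkit for **parallel hyperpolarized ¹³C chemical
shift imaging (CSI) in a multiwell microfluidic plate** — the experiment in
which a single dissolution-DNP shot of [1-¹³C]pyruvate is split across eight
6 mm chambers and all of them are monitored simultaneously by dynamic MRSI
while pyruvate is decarboxylated by hydrogen peroxide.

The package is aimed at people developing or validating quantification
pipelines for this kind of assay: it provides the complete forward model
(reaction kinetics coupled to hyperpolarized spin dynamics, rendered into
voxelized spectra) and the complete analysis chain (reconstruction,
per-chamber quantification, decay fitting, polarization-corrected
concentration recovery, fluidic calibration), so every analysis step can be
checked against known ground truth.

## The model

**Fluidics.** The injected volume V_t splits evenly over the 8 wells after
a dead volume V_d is retained in the tubing:

    V_w = (V_t − V_d) / 8

`fit_dead_volume` estimates V_d in closed form (mean of V_t − 8·V_w) with a
free-slope regression as a diagnostic of the 8-way split.

**Kinetics.** The decarboxylation network is linear (pseudo-first-order in
the excess peroxide): pyruvate (176 ppm) ⇌ hydrate (184 ppm); pyruvate →
2-hydroperoxy-2-hydroxypropanoate (181 ppm) → CO₂ (125 ppm) ⇌
peroxymonocarbonate (161 ppm). Concentrations obey dc/dt = K c per chamber
and are propagated with the matrix exponential (exact for a linear
network). The C1 label is conserved unless CO₂ escape is enabled.

**Spin physics.** Hyperpolarized longitudinal magnetization is
non-renewable. Between pulses the polarization-weighted concentration
vector M follows dM/dt = (K − diag(1/T₁)) M (polarization travels with the
nucleus through reactions); each of the n = 64 excitations per frame
multiplies M by cos θ and yields signal sin θ · M. The frame-lumped
survival factor is

    cosⁿθ · exp(−Δt/T₁)        (cos⁶⁴ 15° = 0.1087 per 4 s frame)

so the apparent decay constant of a non-reacting pool is
r = n(−ln cos θ)/Δt + 1/T₁, and `flip_angle_for_apparent_rate` inverts this
to emulate any observed apparent constant (the scanner's effective B₁ is
never known exactly).

**Rendering.** Each voxel's FID is the overlap-weighted sum of its
chambers' species signals, one decaying complex exponential per species
with T₂* = 1/(π·FWHM), plus seeded complex Gaussian noise. Reconstruction
is an orthonormal FFT; chamber spectra sum the 4 voxels overlapping each
well (complex first, magnitude after).

**Quantification.** Peak height (max magnitude in a per-species ppm
window), integral, and SNR against a signal-free region; mono-exponential
decay fits; division by the control-well pyruvate decay to remove the
shared polarization loss (uniform-T₁ assumption), giving per-species
relative concentration changes; time-normalized mass sensitivity
S_m = SNR/(m[μmol]·√t).

## Worked example

```bash
$ python examples/01_volume_calibration.py
dead volume V_d        : 576 uL
constrained-fit R^2    : 0.979
free-slope diagnostic  : slope 0.1105 (fluidic model: 1/8 = 0.1250), R^2 0.996
predicted delivery for 1.6 mL injected: 128 uL per chamber
```

576 μL of every injection is lost to the tubing; past that, each well
receives one eighth of the remainder, so 1.6 mL delivers ~128 μL per well.

```bash
$ python examples/05_apparent_decay_recovery.py
target tau 3.03 s -> effective flip 11.30 deg, recovered tau 3.0300 s
target tau 2.96 s -> effective flip 11.44 deg, recovered tau 2.9600 s
target tau 3.70 s -> effective flip 10.17 deg, recovered tau 3.7000 s
```

Each line configures the generator to a prescribed apparent pyruvate decay
constant, synthesizes the full CSI acquisition, reconstructs, measures and
fits — recovering the constant to numerical precision.

```bash
$ python examples/04_concentration_correction.py
...
    12     0.859 ( 0.866)     0.262 ( 0.229)     1.434 ( 1.427)     1.482 ( 1.483)
...
max deviation from the kinetic truth: 0.038 (fraction of each species' initial concentration)
```

After dividing out the control-well polarization decay, the corrected
series reproduce the simulated kinetics (plateauing pyruvate, decaying
intermediate, growing products) within a few percent, even though the raw
signal falls roughly tenfold per frame.

The other examples cover the kinetic integrator
(`02_reaction_kinetics.py`) and the full 8-well pipeline with dispersion
and mass-sensitivity outputs (`03_simulate_and_quantify.py`).

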