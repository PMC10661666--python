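"""Full forward + analysis chain on the default 8-well experiment.

Simulates the multiwell CSI acquisition (2 urea reference wells, 3 reaction
wells, 3 controls), reconstructs per-chamber spectra, and prints apparent
pyruvate decay constants, replicate dispersion and the mass sensitivity of
a single scan.
"""

from hpcsi import make_fixture, mass_sensitivity, replicate_dispersion, \
    run_pipeline

config = make_fixture("paper-default")
result = run_pipeline(config)

print("apparent pyruvate decay per chamber:")
fits = result.decay_fits
pyr = fits[fits.species == "pyruvate"]
for _, row in pyr.iterrows():
    print(f"  chamber {row.chamber} ({row.role:8s}): "
          f"tau = {row.time_constant_s:5.2f} s over {row.n_used} frames")

for role in ("reaction", "control"):
    chambers = config.layout.chambers_with_role(role)
    disp = replicate_dispersion(result.peaks, chambers, frame=0)
    print(f"pyruvate dispersion across {role} replicates at frame 0: "
          f"{disp:.1f}%")

# SNR of the reference-well pyruvate peak in the first 4 s scan, and the
# time-normalized mass sensitivity for the ~10 umol of pyruvate per well
ref = config.layout.chambers_with_role("control")[0]
snr = result.peaks.series(ref, "pyruvate", "snr")[0]
amount_mol = 125e-6 * 0.080  # 125 uL at 80 mM
sm = mass_sensitivity(snr, amount_mol, 4.0)
print(f"first-scan pyruvate SNR = {snr:.0f}; "
      f"S_m = {sm:.1f} umol^-1 s^-1/2")

# The decay is dominated by RF consumption (64 pulses of 15 deg per 4 s
# frame), so all wells show tau of a couple of seconds regardless of
# chemistry; dispersion percentages quantify well-to-well repeatability.
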