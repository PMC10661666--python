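"""Polarization-corrected reaction monitoring (the noiseless round trip).

Runs the zero-noise recovery fixture, divides every species series by the
control-well pyruvate decay (the shared hyperpolarization loss under a
uniform-T1 assumption), and compares the corrected relative concentrations
with the generator's kinetic ground truth.
"""

import numpy as np

from hpcsi import make_fixture, run_pipeline

config = make_fixture("noiseless-kinetics")
result = run_pipeline(config)

truth = result.trajectory.interpolated(result.signal.frame_times_s)
with np.errstate(invalid="ignore"):
    rel_true = truth / truth[0][None]

chamber = config.layout.chambers_with_role("reaction")[0]
times = result.signal.frame_times_s - result.signal.frame_times_s[0]
print(f"reaction chamber {chamber}: corrected (and true) concentration "
      "relative to the first frame")
names = result.concentration.species_names
header = "  ".join(f"{n[:12]:>19s}" for n in names)
print(f"  t(s)  {header}")
for f in range(0, len(times), 3):
    cells = []
    for s in range(len(names)):
        meas = result.concentration.relative[f, chamber, s]
        true = rel_true[f, chamber, s]
        cells.append(f"{meas:8.3f} ({true:6.3f})")
    print(f"  {times[f]:4.0f}  " + "  ".join(cells))

err = np.abs(result.concentration.relative[:, chamber, :]
             - rel_true[:, chamber, :]).max()
print(f"\nmax deviation from the kinetic truth: {err:.3f} "
      "(fraction of each species' initial concentration)")

# After the correction the pyruvate plateau, the decaying intermediate and
# the growing products are recovered to within a few percent, even though
# the raw signals all fall by ~an order of magnitude per frame.
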