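"""First-order reaction kinetics of the multiwell assay.

The network is linear (every step first order or pseudo-first order in the
excess peroxide), so concentrations follow dc/dt = K c per chamber and the
trajectory is computed with the matrix-exponential propagator, which is
exact for this system up to floating-point error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .errors import CoverageError, NumericalError, ValidationError
from .species import ReactionNetwork


@dataclass
class KineticTrajectory:
    """Per-chamber, per-species concentration (mM) on a time grid (s).

    `concentrations` has shape (n_times, n_chambers, n_species).  The
    network and per-chamber H2O2 flags are kept so downstream spin-physics
    simulation can follow the label fluxes.
    """

    times_s: np.ndarray
    concentrations_mM: np.ndarray
    species_names: list[str]
    h2o2_present: list[bool]
    network: ReactionNetwork

    @property
    def n_chambers(self) -> int:
        return self.concentrations_mM.shape[1]

    def initial_concentrations(self) -> np.ndarray:
        """(n_chambers, n_species) state at the first grid time."""
        return self.concentrations_mM[0]

    def chamber(self, index: int) -> np.ndarray:
        """(n_times, n_species) trajectory of one chamber."""
        return self.concentrations_mM[:, index, :]

    def interpolated(self, times_s: np.ndarray) -> np.ndarray:
        """Linear interpolation onto arbitrary times within the grid span."""
        t = np.asarray(times_s, float)
        if t.min() < self.times_s[0] - 1e-9 or t.max() > self.times_s[-1] + 1e-9:
            raise CoverageError("requested times outside the trajectory span")
        out = np.empty((len(t),) + self.concentrations_mM.shape[1:])
        for c in range(self.concentrations_mM.shape[1]):
            for s in range(self.concentrations_mM.shape[2]):
                out[:, c, s] = np.interp(t, self.times_s,
                                         self.concentrations_mM[:, c, s])
        return out


def simulate_kinetics(
    network: ReactionNetwork,
    initial_concentrations_mM: np.ndarray | Sequence[Sequence[float]],
    times_s: np.ndarray | Sequence[float],
    h2o2_present: Sequence[bool],
    species_order: list[str] | None = None,
) -> KineticTrajectory:
    """Integrate the reaction network for every chamber.

    Parameters
    ----------
    initial_concentrations_mM
        (n_chambers, n_species) initial state, species in `species_order`
        (defaults to the network's declared order).
    times_s
        Strictly increasing time grid; the first entry is the initial time.
    h2o2_present
        One flag per chamber; peroxide-dependent rates are zeroed where
        False (control chambers).
    """
    order = list(species_order or network.species_names)
    c0 = np.asarray(initial_concentrations_mM, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be a strictly increasing 1-D grid")
    if c0.ndim != 2 or c0.shape[1] != len(order):
        raise ValidationError(
            f"initial concentrations must be (n_chambers, {len(order)})")
    if np.any(c0 < 0) or not np.all(np.isfinite(c0)):
        raise ValidationError("initial concentrations must be finite and >= 0")
    if len(h2o2_present) != c0.shape[0]:
        raise ValidationError("one h2o2 flag per chamber is required")

    out = np.empty((len(t), c0.shape[0], c0.shape[1]))
    out[0] = c0
    # one propagator per (H2O2 flag, step length); grids are usually uniform
    props: dict[tuple[bool, float], np.ndarray] = {}
    ks = {flag: network.rate_matrix(order, flag) for flag in (True, False)}
    for ci, flag in enumerate(h2o2_present):
        state = c0[ci].copy()
        for k, dt in enumerate(np.diff(t)):
            key = (bool(flag), float(dt))
            if key not in props:
                props[key] = expm(ks[bool(flag)] * dt)
            state = props[key] @ state
            out[k + 1, ci] = state
    if not np.all(np.isfinite(out)):
        raise NumericalError("kinetic propagation produced non-finite values")
    # clip propagator round-off; genuine negativity cannot occur here
    np.clip(out, 0.0, None, out=out)
    return KineticTrajectory(
        times_s=t, concentrations_mM=out, species_names=order,
        h2o2_present=[bool(f) for f in h2o2_present], network=network)
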