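"""Hyperpolarized spin physics under repeated low-flip RF sampling.

Hyperpolarized longitudinal magnetization is a non-renewable resource: each
excitation pulse projects sin(theta) of it into the transverse plane (the
detected signal) and leaves cos(theta) behind, while T1 relaxation decays it
toward zero (the thermal floor is negligible at hyperpolarized levels).
Chemical conversion carries the polarized C1 nucleus between pools with no
polarization loss, so the polarization-weighted concentration vector M obeys
the same linear kinetics as the concentrations with an extra -M/T1 term,
punctuated by cos(theta) multiplications at every pulse.

With the imaging readout used here (64 pulses of 15 deg per 4 s frame) the
RF term dominates: cos(15 deg)^64 = 0.1087 per frame, i.e. an apparent decay
much faster than T1.  The effective flip angle on a given scanner depends on
the B1 calibration, so `flip_angle_for_apparent_rate` inverts the observed
apparent decay into the effective flip angle that reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .acquisition import AcquisitionParams
from .errors import CoverageError, ValidationError
from .kinetics import KineticTrajectory
from .species import SpeciesSet


def rf_depletion_factor(flip_angle_deg: float, n_pulses: int) -> float:
    """Longitudinal magnetization left after `n_pulses` pulses, cos(theta)^n."""
    if not (0.0 <= flip_angle_deg <= 90.0):
        raise ValidationError("flip angle must be in [0, 90] deg")
    if n_pulses < 0:
        raise ValidationError("pulse count must be >= 0")
    return float(np.cos(np.radians(flip_angle_deg)) ** n_pulses)


def apparent_decay_rate(
    flip_angle_deg: float, acq: AcquisitionParams, t1_s: float
) -> float:
    """Frame-lumped apparent signal decay rate (s^-1).

    The per-frame survival factor is cos(theta)^n * exp(-dt/T1); the
    apparent mono-exponential rate is its negative log over the frame
    interval.
    """
    if t1_s <= 0:
        raise ValidationError("T1 must be positive")
    n = acq.n_pulses_per_frame
    dt = acq.frame_interval_s
    return (n * -np.log(np.cos(np.radians(flip_angle_deg))) + dt / t1_s) / dt


def flip_angle_for_apparent_rate(
    rate_s: float, acq: AcquisitionParams, t1_s: float
) -> float:
    """Effective flip angle (deg) reproducing an observed apparent decay rate.

    Inverts `apparent_decay_rate`; requires rate >= 1/T1 (RF depletion can
    only speed the decay up).
    """
    if t1_s <= 0 or rate_s <= 0:
        raise ValidationError("rate and T1 must be positive")
    if rate_s < 1.0 / t1_s:
        raise ValidationError(
            f"apparent rate {rate_s} s^-1 is slower than 1/T1; no flip "
            "angle can produce it")
    dt = acq.frame_interval_s
    x = (rate_s * dt - dt / t1_s) / acq.n_pulses_per_frame
    return float(np.degrees(np.arccos(np.exp(-x))))


@dataclass
class SignalSeries:
    """Per-frame, per-chamber, per-species transverse signal amplitudes.

    Amplitudes are polarization-weighted concentrations times sin(theta),
    in mM-equivalent units; the absolute scale is arbitrary but consistent
    across chambers, species and frames.
    """

    frame_times_s: np.ndarray
    amplitudes: np.ndarray  # (n_frames, n_chambers, n_species)
    species_names: list[str]

    @property
    def n_frames(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_chambers(self) -> int:
        return self.amplitudes.shape[1]


def simulate_hp_signal(
    trajectory: KineticTrajectory,
    species: SpeciesSet,
    acq: AcquisitionParams,
    initial_polarization: float = 1.0,
    mode: str = "per-pulse",
) -> SignalSeries:
    """Evolve hyperpolarized magnetization through the acquisition schedule.

    Starting from the trajectory's initial concentrations uniformly
    polarized at `initial_polarization`, the magnetization vector of each
    chamber evolves by (i) T1 relaxation toward zero, (ii) label transfer
    along the kinetic fluxes, and (iii) cos(theta) depletion at each RF
    pulse.  The frame signal is sin(theta) times the magnetization sampled
    at the frame's first pulse.

    mode="per-pulse" applies the 64 pulses individually at the (effective)
    repetition time; mode="frame-lumped" applies cos(theta)^n once per frame
    after sampling.  The two agree when kinetics and T1 are slow relative to
    the pulse train.
    """
    if mode not in ("per-pulse", "frame-lumped"):
        raise ValidationError(f"unknown integration mode {mode!r}")
    if initial_polarization < 0:
        raise ValidationError("initial polarization must be >= 0")
    for name in trajectory.species_names:
        if name not in species:
            raise ValidationError(f"species {name!r} missing spectral params")

    frame_times = acq.frame_times_s
    t0 = trajectory.times_s[0]
    if t0 > acq.delay_to_first_frame_s + 1e-9 \
            or trajectory.times_s[-1] < frame_times[-1] - 1e-9:
        raise CoverageError(
            "trajectory does not cover the acquisition schedule "
            f"({t0:.1f}..{trajectory.times_s[-1]:.1f} s vs frames "
            f"{frame_times[0]:.1f}..{frame_times[-1]:.1f} s)")

    theta = np.radians(acq.flip_angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    n_pulse = acq.n_pulses_per_frame
    r1 = np.array([1.0 / species[name].t1_s
                   for name in trajectory.species_names])
    order = trajectory.species_names
    n_frames = acq.n_frames
    amps = np.zeros((n_frames, trajectory.n_chambers, len(order)))

    spacing = acq.effective_pulse_spacing_s
    tail = acq.frame_interval_s - n_pulse * spacing  # >= 0 by construction
    for flag in (True, False):
        rows = [i for i, f in enumerate(trajectory.h2o2_present) if f is flag]
        if not rows:
            continue
        A = trajectory.network.rate_matrix(order, flag) - np.diag(r1)
        # magnetization columns for all chambers sharing this H2O2 flag
        M = trajectory.initial_concentrations()[rows].T * initial_polarization
        M = expm(A * (acq.delay_to_first_frame_s - t0)) @ M
        if mode == "frame-lumped":
            p_frame = expm(A * acq.frame_interval_s)
            for f in range(n_frames):
                amps[f, rows, :] = (sin_t * M).T
                M = (cos_t ** n_pulse) * (p_frame @ M)
        else:
            p_pulse = expm(A * spacing)
            p_tail = expm(A * tail)
            for f in range(n_frames):
                amps[f, rows, :] = (sin_t * M).T
                for _ in range(n_pulse):
                    M = p_pulse @ (cos_t * M)
                M = p_tail @ M
    return SignalSeries(frame_times_s=frame_times, amplitudes=amps,
                        species_names=list(order))
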