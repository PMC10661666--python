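"""Rendering of chamber signal amplitudes into per-voxel complex FIDs.

Data are synthesized at the post-reconstruction, voxel-resolved level at
which the analysis operates: each voxel's FID is the overlap-weighted sum of
its chambers' species signals, each species contributing a decaying complex
exponential at its chemical-shift offset with T2* = 1/(pi * FWHM), plus
i.i.d. complex Gaussian noise.  k-space encoding, B0/B1 maps and excitation
profiles are deliberately not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .acquisition import AcquisitionParams
from .device import ChamberLayout, overlap_weights
from .errors import AliasingError, ValidationError
from .species import SpeciesSet
from .spin import SignalSeries

_HDF5_FORMAT_VERSION = 1


def dissolution_concentration(
    stock_concentration: float,
    stock_volume_ul: float,
    dissolution_volume_ml: float,
) -> float:
    """Concentration after dissolving a stock aliquot in buffer.

    The denominator is the dissolution volume alone (the few-uL stock is
    negligible against the ~mL buffer, matching how the nominal 80 mM
    pyruvate / 80 uM trityl concentrations are quoted).  Units of the
    returned concentration follow the stock concentration.
    """
    if stock_volume_ul <= 0 or dissolution_volume_ml <= 0:
        raise ValidationError("volumes must be positive")
    return stock_concentration * stock_volume_ul / (dissolution_volume_ml * 1e3)


@dataclass
class CSIDataset:
    """Complex FIDs indexed (frame, voxel_row, voxel_col, spectral_point)."""

    fid: np.ndarray
    acq: AcquisitionParams
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        expected = (self.acq.n_frames, *self.acq.matrix,
                    self.acq.n_spectral_points)
        if self.fid.shape != expected:
            raise ValidationError(
                f"FID shape {self.fid.shape} inconsistent with acquisition "
                f"{expected}")

    @property
    def n_frames(self) -> int:
        return self.fid.shape[0]

    # ---- persistence --------------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        """Write /fid (complex64) plus a JSON metadata attribute block."""
        meta = {
            "format_version": _HDF5_FORMAT_VERSION,
            "acq": self.acq.to_dict(),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with h5py.File(path, "w") as fh:
            fh.create_dataset("fid", data=self.fid.astype(np.complex64))
            fh.attrs["meta"] = json.dumps(meta, sort_keys=True)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "CSIDataset":
        with h5py.File(path, "r") as fh:
            meta = json.loads(fh.attrs["meta"])
            fid = fh["fid"][()]
        if meta.get("format_version") != _HDF5_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported dataset format {meta.get('format_version')}")
        return cls(fid=fid, acq=AcquisitionParams.from_dict(meta["acq"]),
                   noise_sd=meta["noise_sd"], seed=meta["seed"])


def species_basis(
    species: SpeciesSet, acq: AcquisitionParams, order: list[str]
) -> np.ndarray:
    """(n_species, n_points) complex FID basis, one Lorentzian line each."""
    t = np.arange(acq.n_spectral_points) * acq.dwell_time_s
    basis = np.empty((len(order), acq.n_spectral_points), dtype=complex)
    for i, name in enumerate(order):
        sp = species[name]
        df = (sp.shift_ppm - acq.center_ppm) * acq.spectrometer_freq_mhz
        if abs(df) > acq.spectral_width_hz / 2:
            lo, hi = acq.ppm_span()
            raise AliasingError(
                f"{name} at {sp.shift_ppm} ppm falls outside the acquired "
                f"band {lo:.1f}..{hi:.1f} ppm; refusing to alias")
        basis[i] = np.exp((2j * np.pi * df - 1.0 / sp.t2_star_s) * t)
    return basis


def synthesize_csi(
    layout: ChamberLayout,
    amplitudes: SignalSeries | np.ndarray,
    species: SpeciesSet,
    acq: AcquisitionParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
    species_order: list[str] | None = None,
) -> CSIDataset:
    """Render per-chamber species amplitudes into a voxelized CSI dataset.

    Each voxel receives every chamber's signal weighted by the fraction of
    the chamber circle it covers; complex white noise of standard deviation
    `noise_sd` (per real/imaginary component, per point) is added when
    requested.  Identical inputs and seed give a bit-identical dataset.
    """
    if isinstance(amplitudes, SignalSeries):
        order = amplitudes.species_names
        amp = amplitudes.amplitudes
    else:
        if species_order is None:
            raise ValidationError(
                "species_order is required with a bare amplitude array")
        order = list(species_order)
        amp = np.asarray(amplitudes, dtype=float)
    if amp.ndim != 3 or amp.shape[1] != len(layout.chamber_centers) \
            or amp.shape[2] != len(order):
        raise ValidationError(
            "amplitudes must be (n_frames, n_chambers, n_species)")
    if amp.shape[0] != acq.n_frames:
        raise ValidationError("amplitude frames disagree with acquisition")
    if not np.all(np.isfinite(amp)):
        raise ValidationError("amplitudes must be finite")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise ValidationError("a seed is required when noise_sd > 0")

    basis = species_basis(species, acq, order)      # (S, P)
    weights = overlap_weights(layout, acq)          # (C, R, Cc)
    # voxel amplitude per frame and species, then project onto the basis
    vox_amp = np.einsum("fcs,crk->frks", amp, weights)
    fid = np.einsum("frks,sp->frkp", vox_amp, basis)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fid = fid + (rng.normal(0.0, noise_sd, fid.shape)
                     + 1j * rng.normal(0.0, noise_sd, fid.shape))
    return CSIDataset(fid=fid, acq=acq, noise_sd=noise_sd, seed=seed)
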