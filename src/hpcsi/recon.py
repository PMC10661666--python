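"""Spectral reconstruction: FID -> magnitude spectra, voxel aggregation.

Complex voxel FIDs belonging to the same chamber are summed *before* the
Fourier transform (synthetic phases are coherent, so complex summation adds
signal linearly while noise adds in quadrature), then the magnitude is
taken.  The transform uses the orthonormal FFT convention so spectral energy
equals FID energy.  The ppm axis is returned in increasing order; NMR
display convention (ppm increasing right to left) is a plotting concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .errors import AggregationError, ValidationError
from .synth import CSIDataset


def _complex_spectrum(
    fid: np.ndarray, acq: AcquisitionParams,
    apodization_hz: float, zero_fill: int,
) -> tuple[np.ndarray, np.ndarray]:
    n = acq.n_spectral_points
    if fid.shape[-1] != n:
        raise ValidationError(
            f"FID length {fid.shape[-1]} != spectral points {n}")
    if apodization_hz < 0:
        raise ValidationError("apodization must be >= 0 Hz")
    if zero_fill < 1 or int(zero_fill) != zero_fill:
        raise ValidationError("zero_fill must be a positive integer factor")
    x = np.asarray(fid, dtype=complex)
    if apodization_hz > 0:
        t = np.arange(n) * acq.dwell_time_s
        x = x * np.exp(-np.pi * apodization_hz * t)
    n_out = n * int(zero_fill)
    spec = np.fft.fftshift(np.fft.fft(x, n=n_out, norm="ortho"), axes=-1)
    freqs = np.fft.fftshift(np.fft.fftfreq(n_out, acq.dwell_time_s))
    ppm = acq.center_ppm + freqs / acq.spectrometer_freq_mhz
    return ppm, spec


def fid_to_spectrum(
    fid: np.ndarray,
    acq: AcquisitionParams,
    apodization_hz: float = 0.0,
    zero_fill: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrum of one (or a stack of) FID(s).

    Optional exponential apodization (line broadening in Hz) and integer
    zero-filling, then an orthonormal DFT and magnitude.  Returns
    (ppm_axis, magnitude) with ppm strictly increasing; `fid` may have any
    leading shape with spectral points on the last axis.
    """
    ppm, spec = _complex_spectrum(fid, acq, apodization_hz, zero_fill)
    return ppm, np.abs(spec)


@dataclass
class ChamberSpectraSeries:
    """Per-frame, per-chamber magnitude spectra on a shared ppm axis."""

    ppm: np.ndarray
    magnitude: np.ndarray  # (n_frames, n_chambers, n_points)
    provenance: list[list[tuple[int, int]]]  # voxels summed per chamber
    frame_times_s: np.ndarray
    apodization_hz: float = 0.0
    zero_fill: int = 1

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def n_chambers(self) -> int:
        return self.magnitude.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (frame, chamber, ppm, magnitude) table."""
        f, c, p = self.magnitude.shape
        idx = pd.MultiIndex.from_product(
            [range(f), range(c), self.ppm], names=["frame", "chamber", "ppm"])
        return pd.DataFrame(
            {"magnitude": self.magnitude.reshape(-1)}, index=idx
        ).reset_index()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def aggregate_chamber(
    dataset: CSIDataset,
    mapping: list[list[tuple[int, int]]],
    apodization_hz: float = 0.0,
    zero_fill: int = 1,
) -> ChamberSpectraSeries:
    """Sum each chamber's voxel FIDs and reconstruct magnitude spectra.

    `mapping` lists, per chamber, the (row, col) voxels to sum (as produced
    by `voxel_chamber_map`).  Complex FIDs are summed first; the summation
    order within a chamber is irrelevant bit-for-bit.
    """
    nrow, ncol = dataset.acq.matrix
    chamber_fids = []
    for ci, voxels in enumerate(mapping):
        if not voxels:
            raise AggregationError(f"chamber {ci} has no mapped voxels")
        for r, c in voxels:
            if not (0 <= r < nrow and 0 <= c < ncol):
                raise AggregationError(
                    f"chamber {ci} voxel ({r}, {c}) outside the grid")
        # canonical summation order: bit-identical under voxel permutation
        ordered = sorted(voxels)
        rows = [v[0] for v in ordered]
        cols = [v[1] for v in ordered]
        chamber_fids.append(dataset.fid[:, rows, cols, :].sum(axis=1))
    fid = np.stack(chamber_fids, axis=1)  # (F, C, P)
    ppm, mag = fid_to_spectrum(fid, dataset.acq, apodization_hz, zero_fill)
    return ChamberSpectraSeries(
        ppm=ppm, magnitude=mag,
        provenance=[sorted(v) for v in mapping],
        frame_times_s=dataset.acq.frame_times_s,
        apodization_hz=apodization_hz, zero_fill=int(zero_fill))
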