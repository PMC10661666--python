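"""Quantification: peak metrics, decay fitting, concentration correction.

Turns chamber spectra into the assay's quantitative outputs: per-species
peak height/integral/SNR series, apparent mono-exponential decay constants,
polarization-corrected relative concentrations, time-normalized mass
sensitivity, and replicate dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import ConfigurationError, ValidationError
from .recon import ChamberSpectraSeries
from .species import HYDRATE, INTERMEDIATE, PYRUVATE, SpeciesSet

#: default integration half-width around each resonance (ppm)
DEFAULT_WINDOW_HALF_PPM = 1.5

#: explicit boundaries for the crowded downfield pair: the 181 ppm
#: intermediate and the 184 ppm hydrate are only ~3 ppm apart, so their
#: windows are split at 182.5 ppm instead of the default +-1.5 ppm
_CROWDED_WINDOWS_PPM = {
    INTERMEDIATE: (179.5, 182.4),
    HYDRATE: (182.6, 185.5),
}

#: signal-free region used for the per-spectrum noise estimate (ppm);
#: sits between the 161 ppm and 125 ppm resonances
DEFAULT_NOISE_REGION_PPM = (140.0, 152.0)

DEFAULT_SNR_THRESHOLD = 5.0


def default_windows_ppm(species: SpeciesSet) -> dict[str, tuple[float, float]]:
    """Per-species (lo, hi) ppm windows; crowded pairs get explicit splits."""
    windows = {}
    for sp in species:
        if sp.name in _CROWDED_WINDOWS_PPM:
            windows[sp.name] = _CROWDED_WINDOWS_PPM[sp.name]
        else:
            windows[sp.name] = (sp.shift_ppm - DEFAULT_WINDOW_HALF_PPM,
                                sp.shift_ppm + DEFAULT_WINDOW_HALF_PPM)
    return windows


@dataclass
class PeakSeries:
    """Per (frame, chamber, species) peak metrics from magnitude spectra."""

    frame_times_s: np.ndarray
    species_names: list[str]
    height: np.ndarray       # (F, C, S) max magnitude in window
    integral: np.ndarray     # (F, C, S) window sum x ppm step
    snr: np.ndarray          # (F, C, S) height / noise sd
    detectable: np.ndarray   # (F, C, S) bool, snr > threshold
    noise_sd: np.ndarray     # (F, C)
    snr_threshold: float
    windows_ppm: dict[str, tuple[float, float]]

    @property
    def n_chambers(self) -> int:
        return self.height.shape[1]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def series(self, chamber: int, species: str,
               statistic: str = "height") -> np.ndarray:
        """One (frame,) series of a chamber/species peak statistic."""
        arr = getattr(self, statistic)
        return arr[:, chamber, self.species_index(species)]

    def to_frame(self) -> pd.DataFrame:
        f, c, s = self.height.shape
        idx = pd.MultiIndex.from_product(
            [range(f), range(c), self.species_names],
            names=["frame", "chamber", "species"])
        df = pd.DataFrame({
            "time_s": np.repeat(self.frame_times_s, c * s),
            "height": self.height.reshape(-1),
            "integral": self.integral.reshape(-1),
            "snr": self.snr.reshape(-1),
            "detectable": self.detectable.reshape(-1),
        }, index=idx).reset_index()
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def measure_peaks(
    series: ChamberSpectraSeries,
    species: SpeciesSet,
    windows_ppm: dict[str, tuple[float, float]] | None = None,
    noise_region_ppm: tuple[float, float] = DEFAULT_NOISE_REGION_PPM,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
) -> PeakSeries:
    """Measure per-species peaks in every frame and chamber.

    Height is the maximum magnitude inside the species window, the integral
    is the window sum times the ppm step, and SNR divides the height by the
    standard deviation of the magnitude in a signal-free noise region of the
    same spectrum (estimated per frame and chamber).
    """
    windows = dict(windows_ppm or default_windows_ppm(species))
    for name in windows:
        if name not in species:
            raise ConfigurationError(f"window for unknown species {name!r}")
    items = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (na, wa), (nb, wb) in zip(items, items[1:]):
        if wb[0] < wa[1]:
            raise ConfigurationError(
                f"windows for {na!r} ({wa}) and {nb!r} ({wb}) overlap; "
                "set explicit boundaries")
    lo, hi = noise_region_ppm
    if lo >= hi:
        raise ConfigurationError("noise region must be (lo, hi) with lo < hi")
    for name, (wlo, whi) in windows.items():
        if wlo < hi and lo < whi:
            raise ConfigurationError(
                f"noise region {noise_region_ppm} overlaps the {name!r} "
                "window")

    ppm = series.ppm
    ppm_step = float(ppm[1] - ppm[0])
    noise_mask = (ppm >= lo) & (ppm <= hi)
    if noise_mask.sum() < 4:
        raise ConfigurationError("noise region covers too few points")
    noise_sd = series.magnitude[:, :, noise_mask].std(axis=2, ddof=1)

    names = species.names
    F, C = series.n_frames, series.n_chambers
    height = np.zeros((F, C, len(names)))
    integral = np.zeros_like(height)
    for si, name in enumerate(names):
        wlo, whi = windows[name]
        mask = (ppm >= wlo) & (ppm <= whi)
        if not mask.any():
            raise ConfigurationError(
                f"window for {name!r} contains no spectral points")
        sub = series.magnitude[:, :, mask]
        height[:, :, si] = sub.max(axis=2)
        integral[:, :, si] = sub.sum(axis=2) * ppm_step
    with np.errstate(divide="ignore", invalid="ignore"):
        # noiseless spectra: a positive peak has unbounded SNR, an exactly
        # zero spectrum has none
        snr = np.where(noise_sd[:, :, None] > 0,
                       height / noise_sd[:, :, None],
                       np.where(height > 0, np.inf, 0.0))
    return PeakSeries(
        frame_times_s=series.frame_times_s, species_names=list(names),
        height=height, integral=integral, snr=snr,
        detectable=snr > snr_threshold, noise_sd=noise_sd,
        snr_threshold=snr_threshold, windows_ppm=windows)


@dataclass
class DecayFit:
    """Mono-exponential fit A * exp(-r t) of a signal series."""

    amplitude: float
    rate_s: float
    window_s: tuple[float, float] | None
    residual_norm: float
    stderr_rate: float
    n_used: int
    flags: list[str] = field(default_factory=list)

    @property
    def time_constant_s(self) -> float:
        """Apparent decay time constant tau = 1/r."""
        return np.inf if self.rate_s == 0 else 1.0 / self.rate_s


def fit_monoexponential(
    times_s: np.ndarray,
    values: np.ndarray,
    window_s: tuple[float, float] | None = None,
) -> DecayFit:
    """Nonlinear least-squares fit of A * exp(-r t).

    Times are taken relative to the first frame of the fit window (the
    acquisition start is time zero for decay analysis).  Non-positive
    values are excluded (flagged); a constant series returns rate 0 with a
    warning.  On noiseless exponentials the fit recovers the generator rate
    to machine precision.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValidationError("times and values must be matching 1-D arrays")
    if window_s is not None:
        m = (t >= window_s[0]) & (t <= window_s[1])
        t, v = t[m], v[m]
    flags: list[str] = []
    pos = v > 0
    if not pos.all():
        flags.append("nonpositive_excluded")
        t, v = t[pos], v[pos]
    if len(v) < 3:
        raise ValidationError(
            f"need >= 3 positive points in the fit window, got {len(v)}")
    t = t - t[0]

    if np.allclose(v, v[0], rtol=1e-12, atol=0.0):
        warnings.warn("constant series; returning zero decay rate",
                      stacklevel=2)
        flags.append("degenerate_constant")
        return DecayFit(amplitude=float(v[0]), rate_s=0.0, window_s=window_s,
                        residual_norm=0.0, stderr_rate=0.0,
                        n_used=len(v), flags=flags)

    # log-linear start, then full nonlinear refinement
    slope, intercept = np.polyfit(t, np.log(v), 1)
    p0 = (float(np.exp(intercept)), float(max(-slope, 1e-12)))
    model = lambda tt, a, r: a * np.exp(-r * tt)
    try:
        with warnings.catch_warnings():
            # 3-point fits legitimately have a singular covariance
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(model, t, v, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise ValidationError(f"mono-exponential fit failed: {exc}") from exc
    resid = v - model(t, *popt)
    stderr = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    return DecayFit(amplitude=float(popt[0]), rate_s=float(popt[1]),
                    window_s=window_s,
                    residual_norm=float(np.linalg.norm(resid)),
                    stderr_rate=stderr, n_used=len(v), flags=flags)


@dataclass
class ConcentrationSeries:
    """Relative concentration change after polarization-decay correction.

    Every species series is divided framewise by the reference decay
    D(t) = S_ref(t)/S_ref(t0) (the pyruvate signal of a well without
    peroxide, a uniform-T1 proxy for the polarization decay of all pools),
    then self-normalized to its own first frame.  `relative[f, c, s]` is
    therefore c_s(t_f)/c_s(t_0); multiplying by a known initial
    concentration converts it to mM.  Frames after the reference drops
    below the SNR threshold are masked, not extrapolated.
    """

    frame_times_s: np.ndarray
    species_names: list[str]
    relative: np.ndarray        # (F, C, S)
    frame_valid: np.ndarray     # (F,) bool
    reference_chamber: int
    reference_species: str
    reference_decay: np.ndarray  # (F,) D(t)

    @property
    def change(self) -> np.ndarray:
        """Relative change vs initial, relative - 1."""
        return self.relative - 1.0

    def to_frame(self) -> pd.DataFrame:
        f, c, s = self.relative.shape
        idx = pd.MultiIndex.from_product(
            [range(f), range(c), self.species_names],
            names=["frame", "chamber", "species"])
        return pd.DataFrame({
            "time_s": np.repeat(self.frame_times_s, c * s),
            "relative": self.relative.reshape(-1),
            "frame_valid": np.repeat(self.frame_valid, c * s),
        }, index=idx).reset_index()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def correct_concentration(
    peaks: PeakSeries,
    reference_chamber: int,
    reference_species: str = PYRUVATE,
    snr_threshold: float | None = None,
) -> ConcentrationSeries:
    """Divide out the shared hyperpolarization decay.

    Assumes a uniform polarization decay across species (uniform T1 and
    shared RF schedule), measured as the reference species signal in the
    reference (no-reaction) chamber.  The correction terminates at the
    first frame where the reference falls below the SNR threshold.
    """
    thr = peaks.snr_threshold if snr_threshold is None else snr_threshold
    si = peaks.species_index(reference_species)
    ref = peaks.height[:, reference_chamber, si]
    ref_snr = peaks.snr[:, reference_chamber, si]
    if ref_snr[0] <= thr or ref[0] <= 0:
        raise ValidationError(
            "reference species is not detectable in the first frame")
    valid = ref_snr > thr
    if not valid.all():
        valid[int(np.argmin(valid)):] = False  # terminate, don't interpolate
    decay = np.where(valid, ref / ref[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = peaks.height / decay[:, None, None]
        relative = corrected / corrected[0][None, :, :]
    return ConcentrationSeries(
        frame_times_s=peaks.frame_times_s,
        species_names=list(peaks.species_names),
        relative=relative, frame_valid=valid,
        reference_chamber=reference_chamber,
        reference_species=reference_species,
        reference_decay=decay)


def mass_sensitivity(
    snr: float, amount_mol: float, measurement_time_s: float
) -> float:
    """Time-normalized mass sensitivity S_m = SNR / (m[umol] * sqrt(t)).

    `amount_mol` is the amount of substance in mol; the result is in
    umol^-1 s^-1/2.
    """
    if amount_mol <= 0 or measurement_time_s <= 0:
        raise ValidationError("amount and measurement time must be positive")
    return snr / (amount_mol * 1e6 * np.sqrt(measurement_time_s))


def replicate_dispersion(
    peaks: PeakSeries,
    chambers: list[int],
    frame: int,
    species: str = PYRUVATE,
    statistic: str = "height",
) -> float:
    """Percent dispersion (100 * sd/mean) across replicate chambers."""
    if len(chambers) < 2:
        raise ValidationError("need >= 2 replicate chambers")
    si = peaks.species_index(species)
    vals = getattr(peaks, statistic)[frame, chambers, si]
    mean = vals.mean()
    if mean == 0:
        raise ValidationError("replicate mean is zero")
    return float(100.0 * vals.std(ddof=1) / mean)
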