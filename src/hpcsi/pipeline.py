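"""End-to-end orchestration: configuration, simulate -> recon -> quantify.

A `RunConfig` bundles everything a run needs (layout, species, network,
acquisition, initial state, noise, seed, analysis options) and round-trips
losslessly through YAML.  `run_pipeline` executes the full chain and, when
given an output directory, writes the dataset (HDF5), tidy CSV tables, and
a JSON manifest (config hash, versions, seed) sufficient to reproduce every
output byte-exactly.

Timing model: the hyperpolarized solution leaves the polarizer at t = 0,
is transferred and injected, and reaches the peroxide-loaded chambers at
`injection_time_s`; the configured initial concentrations describe the
chamber contents at that moment.  Reaction kinetics then run continuously,
and frame acquisition starts at the acquisition delay.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import AcquisitionParams
from .device import ChamberLayout, voxel_chamber_map
from .errors import ValidationError
from .kinetics import KineticTrajectory, simulate_kinetics
from .quantify import (ConcentrationSeries, DecayFit, PeakSeries,
                       correct_concentration, fit_monoexponential,
                       measure_peaks, DEFAULT_NOISE_REGION_PPM,
                       DEFAULT_SNR_THRESHOLD)
from .recon import ChamberSpectraSeries, aggregate_chamber
from .species import PYRUVATE, ReactionNetwork, SpeciesSet
from .spin import SignalSeries, simulate_hp_signal
from .synth import CSIDataset, synthesize_csi


log = logging.getLogger("hpcsi.pipeline")


class _StageTimer:
    """Per-stage wall-clock logging; silent unless logging is configured."""

    def __init__(self) -> None:
        self._t = time.perf_counter()

    def __call__(self, name: str) -> None:
        now = time.perf_counter()
        log.info("%s: %.3f s", name, now - self._t)
        self._t = now


@dataclass
class AnalysisOptions:
    """Reconstruction and quantification settings."""

    apodization_hz: float = 0.0
    zero_fill: int = 8  # fine spectral grid keeps peak heights sampling-safe
    voxels_per_chamber: int = 4
    noise_region_ppm: tuple[float, float] = DEFAULT_NOISE_REGION_PPM
    snr_threshold: float = DEFAULT_SNR_THRESHOLD
    windows_ppm: dict | None = None
    reference_chamber: int | None = None  # default: first control chamber
    reference_species: str = PYRUVATE

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise_region_ppm"] = list(self.noise_region_ppm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisOptions":
        d = dict(d)
        d["noise_region_ppm"] = tuple(d["noise_region_ppm"])
        if d.get("windows_ppm"):
            d["windows_ppm"] = {k: tuple(v)
                                for k, v in d["windows_ppm"].items()}
        return cls(**d)


@dataclass
class RunConfig:
    """Full description of one synthetic acquisition + analysis run."""

    layout: ChamberLayout
    species: SpeciesSet
    network: ReactionNetwork
    acq: AcquisitionParams
    #: chamber contents (mM) at injection, keyed by chamber role
    initial_concentrations_mM: dict[str, dict[str, float]]
    injection_time_s: float = 21.0
    initial_polarization: float = 1.0
    mode: str = "per-pulse"
    noise_sd: float = 0.0
    seed: int | None = None
    kinetic_step_s: float = 0.25
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def validate(self) -> None:
        """Raise a validation report naming each offending field."""
        problems: list[str] = []
        if self.noise_sd < 0:
            problems.append("noise_sd: must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            problems.append("seed: mandatory when noise_sd > 0")
        if self.mode not in ("per-pulse", "frame-lumped"):
            problems.append(f"mode: unknown mode {self.mode!r}")
        if not (0 <= self.injection_time_s
                <= self.acq.delay_to_first_frame_s):
            problems.append(
                "injection_time_s: must lie in [0, delay_to_first_frame]")
        if self.kinetic_step_s <= 0:
            problems.append("kinetic_step_s: must be positive")
        if self.initial_polarization < 0:
            problems.append("initial_polarization: must be >= 0")
        for role, conc in self.initial_concentrations_mM.items():
            if role not in ("reference", "reaction", "control"):
                problems.append(
                    f"initial_concentrations_mM: unknown role {role!r}")
                continue
            for name, val in conc.items():
                if name not in self.species:
                    problems.append(
                        f"initial_concentrations_mM[{role}]: unknown "
                        f"species {name!r}")
                elif val < 0 or not np.isfinite(val):
                    problems.append(
                        f"initial_concentrations_mM[{role}][{name}]: "
                        "must be finite and >= 0")
        for name in self.network.species_names:
            if name not in self.species:
                problems.append(f"network: species {name!r} has no "
                                "spectral parameters")
        if self.analysis.reference_chamber is None:
            if not self.layout.chambers_with_role("control"):
                problems.append(
                    "analysis.reference_chamber: no control chamber to "
                    "default to")
        if problems:
            raise ValidationError("invalid config:\n  " +
                                  "\n  ".join(problems))

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "layout": self.layout.to_dict(),
            "species": self.species.to_dict(),
            "network": self.network.to_dict(),
            "acq": self.acq.to_dict(),
            "initial_concentrations_mM": self.initial_concentrations_mM,
            "injection_time_s": self.injection_time_s,
            "initial_polarization": self.initial_polarization,
            "mode": self.mode,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "kinetic_step_s": self.kinetic_step_s,
            "analysis": self.analysis.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            layout=ChamberLayout.from_dict(d["layout"]),
            species=SpeciesSet.from_dict(d["species"]),
            network=ReactionNetwork.from_dict(d["network"]),
            acq=AcquisitionParams.from_dict(d["acq"]),
            initial_concentrations_mM=d["initial_concentrations_mM"],
            injection_time_s=d["injection_time_s"],
            initial_polarization=d["initial_polarization"],
            mode=d["mode"],
            noise_sd=d["noise_sd"],
            seed=d["seed"],
            kinetic_step_s=d["kinetic_step_s"],
            analysis=AnalysisOptions.from_dict(d["analysis"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    """All artifacts of one run, including the generator's ground truth."""

    config: RunConfig
    trajectory: KineticTrajectory
    signal: SignalSeries
    dataset: CSIDataset
    mapping: list[list[tuple[int, int]]]
    spectra: ChamberSpectraSeries
    peaks: PeakSeries
    decay_fits: pd.DataFrame
    concentration: ConcentrationSeries
    manifest: dict


def _initial_matrix(config: RunConfig) -> np.ndarray:
    order = config.network.species_names
    c0 = np.zeros((len(config.layout.chamber_centers), len(order)))
    for ci, role in enumerate(config.layout.roles):
        conc = config.initial_concentrations_mM.get(role, {})
        for si, name in enumerate(order):
            c0[ci, si] = conc.get(name, 0.0)
    return c0


def fit_peak_decay(
    peaks: PeakSeries, chamber: int, species: str,
    min_snr: float | None = None,
) -> DecayFit:
    """Fit the apparent mono-exponential decay of one peak series.

    Uses the contiguous prefix of frames above the SNR threshold (once the
    decaying signal drops into the noise, later above-threshold frames are
    maximum-statistic flukes); times are relabeled so the first used frame
    is t = 0 (decay analysis starts at the acquisition start).
    """
    thr = peaks.snr_threshold if min_snr is None else min_snr
    si = peaks.species_index(species)
    above = peaks.snr[:, chamber, si] > thr
    prefix = len(above) if above.all() else int(np.argmin(above))
    n = max(prefix, 3)  # the fit needs 3 points even when SNR fades early
    t = peaks.frame_times_s[:n] - peaks.frame_times_s[0]
    return fit_monoexponential(t, peaks.height[:n, chamber, si])


def pooled_condition_peaks(
    result: PipelineResult, chambers: list[int]
) -> PeakSeries:
    """Peak series of several replicate chambers pooled at the FID level.

    The voxels of all listed chambers are summed into one virtual chamber
    before reconstruction, so replicate signal adds coherently while noise
    adds in quadrature — the analog of averaging replicate wells of the
    same condition.  Returns a single-chamber PeakSeries.
    """
    if not chambers:
        raise ValidationError("need at least one chamber to pool")
    merged = [v for ci in chambers for v in result.mapping[ci]]
    opts = result.config.analysis
    spectra = aggregate_chamber(result.dataset, [merged],
                                apodization_hz=opts.apodization_hz,
                                zero_fill=opts.zero_fill)
    return measure_peaks(
        spectra, result.config.species, windows_ppm=opts.windows_ppm,
        noise_region_ppm=opts.noise_region_ppm,
        snr_threshold=opts.snr_threshold)


def run_pipeline(config: RunConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute simulate -> reconstruct -> quantify.

    Returns everything in memory; when `outdir` is given also writes
    dataset.h5, spectra.csv, peaks.csv, fits.csv, concentration.csv,
    config.yaml and manifest.json.
    """
    config.validate()
    acq = config.acq
    order = config.network.species_names
    stage = _StageTimer()

    # kinetics from injection through the last frame
    t_end = float(acq.frame_times_s[-1])
    n_steps = int(np.ceil((t_end - config.injection_time_s)
                          / config.kinetic_step_s))
    times = np.linspace(config.injection_time_s, t_end, n_steps + 1)
    h2o2 = [role == "reaction" for role in config.layout.roles]
    trajectory = simulate_kinetics(
        config.network, _initial_matrix(config), times, h2o2)
    stage("kinetics")

    signal = simulate_hp_signal(
        trajectory, config.species, acq,
        initial_polarization=config.initial_polarization, mode=config.mode)
    stage("spin dynamics")
    dataset = synthesize_csi(
        config.layout, signal, config.species, acq,
        noise_sd=config.noise_sd, seed=config.seed)
    stage("synthesis")

    opts = config.analysis
    mapping = voxel_chamber_map(config.layout, acq,
                                k=opts.voxels_per_chamber)
    spectra = aggregate_chamber(dataset, mapping,
                                apodization_hz=opts.apodization_hz,
                                zero_fill=opts.zero_fill)
    stage("reconstruction")
    peaks = measure_peaks(
        spectra, config.species,
        windows_ppm=opts.windows_ppm,
        noise_region_ppm=opts.noise_region_ppm,
        snr_threshold=opts.snr_threshold)
    stage("quantification")

    rows = []
    for ci, role in enumerate(config.layout.roles):
        for name in order:
            si = peaks.species_index(name)
            usable = ((peaks.snr[:, ci, si] > peaks.snr_threshold)
                      & (peaks.height[:, ci, si] > 0))
            if usable.sum() < 3:
                continue
            try:
                fit = fit_peak_decay(peaks, ci, name)
            except ValidationError:
                # above-threshold frames were non-contiguous noise flukes
                continue
            rows.append({
                "chamber": ci, "role": role, "species": name,
                "amplitude": fit.amplitude, "rate_s": fit.rate_s,
                "time_constant_s": fit.time_constant_s,
                "stderr_rate": fit.stderr_rate, "n_used": fit.n_used,
                "flags": ";".join(fit.flags),
            })
    decay_fits = pd.DataFrame(rows)

    ref = opts.reference_chamber
    if ref is None:
        ref = config.layout.chambers_with_role("control")[0]
    concentration = correct_concentration(
        peaks, reference_chamber=ref,
        reference_species=opts.reference_species)

    manifest = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "versions": {
            "hpcsi": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
        "n_frames": acq.n_frames,
        "n_chambers": len(config.layout.chamber_centers),
        "reference_chamber": ref,
    }

    result = PipelineResult(
        config=config, trajectory=trajectory, signal=signal,
        dataset=dataset, mapping=mapping, spectra=spectra, peaks=peaks,
        decay_fits=decay_fits, concentration=concentration,
        manifest=manifest)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        dataset.to_hdf5(out / "dataset.h5")
        spectra.to_csv(out / "spectra.csv")
        peaks.to_csv(out / "peaks.csv")
        decay_fits.to_csv(out / "fits.csv", index=False)
        concentration.to_csv(out / "concentration.csv")
        config.to_yaml(out / "config.yaml")
        manifest["outputs"] = ["dataset.h5", "spectra.csv", "peaks.csv",
                               "fits.csv", "concentration.csv",
                               "config.yaml"]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
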