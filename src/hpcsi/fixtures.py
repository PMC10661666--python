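"""Deterministic fixture configurations used by tests and examples.

Each registry entry returns a complete `RunConfig`; run it with
`run_pipeline` to obtain the corresponding dataset and analysis.  All
fixtures are generated programmatically and are small (a few MB in memory).
"""

from __future__ import annotations

from dataclasses import replace

from .device import ChamberLayout
from .errors import RegistryError
from .pipeline import AnalysisOptions, RunConfig
from .acquisition import AcquisitionParams
from .species import (CO2, INTERMEDIATE, PEROXYMONOCARBONATE, PYRUVATE,
                      HYDRATE, Edge, ReactionNetwork, Species, SpeciesSet,
                      DEFAULT_SHIFTS_PPM)

#: reaction-chamber contents (mM) at injection for the default assay: the
#: rapid initial burst of the peroxide reaction during sample delivery is
#: expressed through this partly-converted state, after which the modest
#: constant pseudo-first-order rates apply (see docs/methods.md).
REACTION_INITIAL_MM = {
    PYRUVATE: 26.0, HYDRATE: 4.0, INTERMEDIATE: 30.0,
    PEROXYMONOCARBONATE: 11.0, CO2: 9.0,
}

CONTROL_INITIAL_MM = {PYRUVATE: 78.0, HYDRATE: 2.0}


def _paper_default() -> RunConfig:
    """8 chambers (2 reference / 3 reaction / 3 control), 5 species,
    10 frames of the default CSI readout, light noise."""
    species = SpeciesSet.pyruvate_decarboxylation()
    return RunConfig(
        layout=ChamberLayout(),
        species=species,
        network=ReactionNetwork.pyruvate_decarboxylation(),
        acq=AcquisitionParams(),
        initial_concentrations_mM={
            "reaction": dict(REACTION_INITIAL_MM),
            "control": dict(CONTROL_INITIAL_MM),
            "reference": {},
        },
        noise_sd=0.02,
        seed=20231019,
        analysis=AnalysisOptions(),
    )


def _noiseless_kinetics() -> RunConfig:
    """Zero-noise recovery fixture with uniform T1.

    Designed to validate the polarization-decay correction round trip:
    the hydrate is omitted (its 96 Hz spacing from the intermediate is
    below the readout's resolving power) and a narrow 2 Hz linewidth keeps
    magnitude-spectrum tail overlap from confounding the kinetic
    comparison.  Lineshape-overlap bias at the instrument linewidth is a
    documented limitation, not something this fixture measures.
    """
    species = SpeciesSet.pyruvate_decarboxylation(
        linewidth_fwhm_hz=2.0, include_hydrate=False)
    initial = {k: v for k, v in REACTION_INITIAL_MM.items() if k != HYDRATE}
    initial[PYRUVATE] += REACTION_INITIAL_MM[HYDRATE]  # keep 80 mM total
    return RunConfig(
        layout=ChamberLayout(),
        species=species,
        network=ReactionNetwork.pyruvate_decarboxylation(
            include_hydrate=False),
        acq=AcquisitionParams(),
        initial_concentrations_mM={
            "reaction": initial,
            "control": {PYRUVATE: 80.0},
            "reference": {},
        },
        noise_sd=0.0,
        seed=None,
        analysis=AnalysisOptions(zero_fill=8),
    )


def _two_chamber_minimal() -> RunConfig:
    """Smallest useful run: two occupied wells (one reaction, one control),
    two species, five frames.

    The plate always has 8 wells; "two-chamber" means only two contain
    sample (the six others are empty reference wells).
    """
    species = SpeciesSet([
        Species(PYRUVATE, DEFAULT_SHIFTS_PPM[PYRUVATE]),
        Species(CO2, DEFAULT_SHIFTS_PPM[CO2]),
    ])
    network = ReactionNetwork(
        [PYRUVATE, CO2],
        [Edge(PYRUVATE, CO2, 0.05, requires_h2o2=True)],
    )
    layout = ChamberLayout(roles=("reaction", "control") + ("reference",) * 6)
    return RunConfig(
        layout=layout,
        species=species,
        network=network,
        acq=AcquisitionParams(n_frames=5),
        initial_concentrations_mM={
            "reaction": {PYRUVATE: 80.0},
            "control": {PYRUVATE: 80.0},
            "reference": {},
        },
        noise_sd=0.0,
        seed=None,
        analysis=AnalysisOptions(zero_fill=4),
    )


def apparent_decay_config(
    rate_s: float,
    shift_ppm: float = DEFAULT_SHIFTS_PPM[PYRUVATE],
    t1_s: float = 60.0,
    n_frames: int = 10,
    noise_sd: float = 0.0,
    seed: int | None = None,
    linewidth_fwhm_hz: float = 53.0,
) -> RunConfig:
    """Single-species run whose signal decays at a prescribed apparent rate.

    A non-reacting probe species is placed in one well and the effective
    flip angle is solved so that RF depletion plus T1 relaxation produce
    exactly the requested frame-to-frame mono-exponential rate — the
    configuration used to emulate a measured apparent decay constant (the
    scanner's true B1 calibration being unknown).
    """
    from .spin import flip_angle_for_apparent_rate

    acq = AcquisitionParams(n_frames=n_frames)
    flip = flip_angle_for_apparent_rate(rate_s, acq, t1_s)
    acq = replace(acq, flip_angle_deg=flip)
    species = SpeciesSet([Species("probe", shift_ppm, t1_s,
                                  linewidth_fwhm_hz)])
    return RunConfig(
        layout=ChamberLayout(roles=("control",) + ("reference",) * 7),
        species=species,
        network=ReactionNetwork(["probe"], []),
        acq=acq,
        initial_concentrations_mM={"control": {"probe": 80.0},
                                   "reference": {}},
        noise_sd=noise_sd,
        seed=seed,
        analysis=AnalysisOptions(reference_chamber=0,
                                 reference_species="probe"),
    )


_REGISTRY = {
    "paper-default": _paper_default,
    "noiseless-kinetics": _noiseless_kinetics,
    "two-chamber-minimal": _two_chamber_minimal,
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def make_fixture(name: str) -> RunConfig:
    """Return the registered fixture configuration by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise RegistryError(
            f"unknown fixture {name!r}; known: {fixture_names()}") from None
    return factory()
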