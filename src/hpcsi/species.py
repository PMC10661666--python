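"""Chemical species and the first-order reaction network.

The default chemistry is the decarboxylation of [1-13C]pyruvate by hydrogen
peroxide: pyruvate (176 ppm) reacts to the 2-hydroperoxy-2-hydroxypropanoate
intermediate (181 ppm), which decomposes releasing the C1 label as 13CO2
(125 ppm); CO2 exchanges with peroxymonocarbonate (161 ppm) in the
peroxide-rich wells.  Pyruvate also equilibrates with its hydrate (184 ppm).
Every edge moves the C1 label from exactly one source species to exactly one
target species, so the label is conserved unless CO2 escape is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ValidationError

PYRUVATE = "pyruvate"
HYDRATE = "pyruvate_hydrate"
INTERMEDIATE = "hydroperoxy_hydroxypropanoate"
PEROXYMONOCARBONATE = "peroxymonocarbonate"
CO2 = "co2"

#: 13C chemical shifts (ppm) of the C1 label in each pool
DEFAULT_SHIFTS_PPM = {
    PYRUVATE: 176.0,
    HYDRATE: 184.0,
    INTERMEDIATE: 181.0,
    PEROXYMONOCARBONATE: 161.0,
    CO2: 125.0,
}

DEFAULT_LINEWIDTH_HZ = 53.0  # measured shim-limited FWHM of the pyruvate peak
DEFAULT_T1_S = 60.0          # [1-13C]pyruvate in solution at 3 T


@dataclass(frozen=True)
class Species:
    name: str
    shift_ppm: float
    t1_s: float = DEFAULT_T1_S
    linewidth_fwhm_hz: float = DEFAULT_LINEWIDTH_HZ

    def __post_init__(self) -> None:
        if self.t1_s <= 0:
            raise ValidationError(f"{self.name}: T1 must be positive")
        if self.linewidth_fwhm_hz <= 0:
            raise ValidationError(f"{self.name}: linewidth must be positive")

    @property
    def t2_star_s(self) -> float:
        """Effective transverse decay, 1/(pi * FWHM)."""
        return 1.0 / (np.pi * self.linewidth_fwhm_hz)


class SpeciesSet:
    """Ordered collection of species with distinct chemical shifts."""

    def __init__(self, species: list[Species]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValidationError("species names must be unique")
        shifts = [s.shift_ppm for s in species]
        if len(set(shifts)) != len(shifts):
            raise ValidationError("chemical shifts must be distinct")
        self._species = list(species)
        self._by_name = {s.name: s for s in species}

    def __len__(self) -> int:
        return len(self._species)

    def __iter__(self):
        return iter(self._species)

    def __getitem__(self, key: int | str) -> Species:
        if isinstance(key, str):
            return self._by_name[key]
        return self._species[key]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._species]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def pyruvate_decarboxylation(
        cls,
        t1_s: float = DEFAULT_T1_S,
        linewidth_fwhm_hz: float = DEFAULT_LINEWIDTH_HZ,
        include_hydrate: bool = True,
    ) -> "SpeciesSet":
        """The five (or four, without the hydrate) observed 13C pools.

        A single uniform T1 is the default, matching the quantification
        assumption used downstream; per-species values can be set by
        constructing the set manually.
        """
        names = [PYRUVATE, HYDRATE, INTERMEDIATE, PEROXYMONOCARBONATE, CO2]
        if not include_hydrate:
            names.remove(HYDRATE)
        return cls([
            Species(n, DEFAULT_SHIFTS_PPM[n], t1_s, linewidth_fwhm_hz)
            for n in names
        ])

    def to_dict(self) -> list[dict]:
        return [asdict(s) for s in self._species]

    @classmethod
    def from_dict(cls, d: list[dict]) -> "SpeciesSet":
        return cls([Species(**s) for s in d])


@dataclass(frozen=True)
class Edge:
    """First-order conversion moving the C1 label source -> target.

    `requires_h2o2` marks pseudo-first-order steps whose rate constant
    already folds in the (large-excess) peroxide concentration; these rates
    are zeroed in chambers without H2O2.
    """
    source: str
    target: str
    rate_s: float
    requires_h2o2: bool = False

    def __post_init__(self) -> None:
        if self.rate_s < 0:
            raise ValidationError(
                f"rate {self.source}->{self.target} must be >= 0")


class ReactionNetwork:
    """First-order reaction scheme over a set of named species."""

    def __init__(
        self,
        species_names: list[str],
        edges: list[Edge],
        co2_escape_rate_s: float = 0.0,
    ):
        if co2_escape_rate_s < 0:
            raise ValidationError("CO2 escape rate must be >= 0")
        declared = set(species_names)
        for e in edges:
            if e.source not in declared or e.target not in declared:
                raise ValidationError(
                    f"edge {e.source}->{e.target} uses undeclared species")
        if co2_escape_rate_s > 0 and CO2 not in declared:
            raise ValidationError("CO2 escape requires a co2 species")
        self.species_names = list(species_names)
        self.edges = list(edges)
        self.co2_escape_rate_s = co2_escape_rate_s

    @classmethod
    def pyruvate_decarboxylation(
        cls,
        k_conversion_s: float = 0.012,
        k_decomposition_s: float = 0.17,
        k_co2_to_pmc_s: float = 0.015,
        k_pmc_to_co2_s: float = 0.003,
        k_hydration_s: float = 0.002,
        k_dehydration_s: float = 0.010,
        include_hydrate: bool = True,
        co2_escape_rate_s: float = 0.0,
    ) -> "ReactionNetwork":
        """Default decarboxylation scheme.

        Rates are configuration, not constants: the conversion and
        decomposition steps are pseudo-first-order in the excess peroxide,
        and the defaults are chosen so that, on top of the RF/T1 signal
        decay, the intermediate decays faster than the products grow, giving
        the observed plateau/decrease/increase pattern.
        """
        edges = [
            Edge(PYRUVATE, INTERMEDIATE, k_conversion_s, requires_h2o2=True),
            Edge(INTERMEDIATE, CO2, k_decomposition_s, requires_h2o2=True),
            Edge(CO2, PEROXYMONOCARBONATE, k_co2_to_pmc_s, requires_h2o2=True),
            Edge(PEROXYMONOCARBONATE, CO2, k_pmc_to_co2_s, requires_h2o2=True),
        ]
        names = [PYRUVATE, INTERMEDIATE, PEROXYMONOCARBONATE, CO2]
        if include_hydrate:
            names.insert(1, HYDRATE)
            edges += [
                Edge(PYRUVATE, HYDRATE, k_hydration_s),
                Edge(HYDRATE, PYRUVATE, k_dehydration_s),
            ]
        return cls(names, edges, co2_escape_rate_s)

    def rate_matrix(
        self, species_order: list[str], h2o2_present: bool
    ) -> np.ndarray:
        """Generator K of the linear kinetics dc/dt = K c (units s^-1).

        Off-diagonal K[j, i] is the rate of i -> j; diagonal entries collect
        the total loss of each pool.  Peroxide-dependent edges contribute
        zero when `h2o2_present` is False.
        """
        for n in self.species_names:
            if n not in species_order:
                raise ValidationError(f"species {n!r} missing from order")
        n = len(species_order)
        idx = {name: i for i, name in enumerate(species_order)}
        K = np.zeros((n, n))
        for e in self.edges:
            rate = e.rate_s if (h2o2_present or not e.requires_h2o2) else 0.0
            i, j = idx[e.source], idx[e.target]
            K[i, i] -= rate
            K[j, i] += rate
        if self.co2_escape_rate_s > 0 and CO2 in idx:
            K[idx[CO2], idx[CO2]] -= self.co2_escape_rate_s
        return K

    def to_dict(self) -> dict:
        return {
            "species_names": self.species_names,
            "edges": [asdict(e) for e in self.edges],
            "co2_escape_rate_s": self.co2_escape_rate_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        return cls(d["species_names"], [Edge(**e) for e in d["edges"]],
                   d.get("co2_escape_rate_s", 0.0))
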