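"""Multiwell microfluidic device model.

Geometry of the 8-well (4 x 2) PDMS plate in the imaging frame, the fluidic
volume-distribution model with its dead volume, and the mapping from CSI
voxels to chambers.

Conventions (stated once, used everywhere): coordinates are continuous mm in
the device frame with the origin at the field-of-view center; voxel indices
are 0-based row-major, with row 0 at y = -FOV/2 (y increases with row index)
and column 0 at x = -FOV/2.

The default layout places the eight 6 mm chambers on a symmetric 4 x 2 grid
at x in {-15, -5, 5, 15} mm, y in {-5, 5} mm, so every chamber center sits
on a corner shared by four 5 mm voxels and each chamber is quantified from
exactly 4 voxels.  The physical plate has a wider (15 mm) pitch than the
40 mm field of view can hold; `pitch_mm` is configurable for device-frame
work, while the default keeps every chamber inside the imaged region.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Point, box

from .acquisition import AcquisitionParams
from .errors import CalibrationError, MappingError, ValidationError

N_WELLS = 8

VALID_ROLES = ("reference", "reaction", "control")


def _default_centers(pitch_mm: float = 10.0) -> list[tuple[float, float]]:
    xs = [pitch_mm * (i - 1.5) for i in range(4)]
    ys = [-pitch_mm / 2, pitch_mm / 2]
    return [(x, y) for y in ys for x in xs]


#: chamber roles in the proof-of-concept assay: two [13C]urea reference
#: wells in opposite corners, three H2O2 reaction wells, three NaOH controls.
DEFAULT_ROLES = ("reference", "reaction", "control", "reaction",
                 "control", "reaction", "control", "reference")


@dataclass
class ChamberLayout:
    """Geometry and role of the 8 wells on the imaging grid."""

    chamber_centers: list[tuple[float, float]] = field(
        default_factory=_default_centers)
    chamber_diameter_mm: float = 6.0
    pitch_mm: float = 10.0
    roles: tuple[str, ...] = DEFAULT_ROLES
    sample_volume_ul: float = 125.0
    fov_mm: tuple[float, float] = (40.0, 40.0)

    def __post_init__(self) -> None:
        if len(self.chamber_centers) != N_WELLS:
            raise ValidationError(
                f"layout must have exactly {N_WELLS} chambers, "
                f"got {len(self.chamber_centers)}")
        if len(self.roles) != N_WELLS:
            raise ValidationError("one role per chamber is required")
        for r in self.roles:
            if r not in VALID_ROLES:
                raise ValidationError(f"unknown chamber role {r!r}")
        c = np.asarray(self.chamber_centers, dtype=float)
        if not np.all(np.isfinite(c)):
            raise ValidationError("chamber centers must be finite")
        d = self.chamber_diameter_mm
        # pairwise non-overlap
        for i in range(N_WELLS):
            for j in range(i + 1, N_WELLS):
                if np.hypot(*(c[i] - c[j])) <= d:
                    raise ValidationError(
                        f"chambers {i} and {j} overlap (center distance "
                        f"<= diameter {d} mm)")
        # every circle inside the field of view
        half = np.asarray(self.fov_mm, dtype=float) / 2
        r = d / 2
        if np.any(np.abs(c) + r > half + 1e-9):
            raise ValidationError(
                "a chamber circle extends outside the field of view")

    @property
    def radius_mm(self) -> float:
        return self.chamber_diameter_mm / 2

    def chambers_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    def translated(self, dx: float, dy: float) -> "ChamberLayout":
        return ChamberLayout(
            chamber_centers=[(x + dx, y + dy) for x, y in self.chamber_centers],
            chamber_diameter_mm=self.chamber_diameter_mm,
            pitch_mm=self.pitch_mm, roles=self.roles,
            sample_volume_ul=self.sample_volume_ul, fov_mm=self.fov_mm)

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chamber_centers"] = [list(p) for p in self.chamber_centers]
        d["roles"] = list(self.roles)
        d["fov_mm"] = list(self.fov_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChamberLayout":
        d = dict(d)
        d["chamber_centers"] = [tuple(p) for p in d["chamber_centers"]]
        d["roles"] = tuple(d["roles"])
        d["fov_mm"] = tuple(d["fov_mm"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChamberLayout":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class VolumeCalibration:
    """Result of fitting V_w = (V_t - V_d)/8 to injected/recovered volumes.

    `dead_volume_ul` and `r_squared` describe the constrained fit (slope
    fixed at 1/8, one chamber volume per eighth of the net injection); the
    `free_*` fields report an unconstrained straight-line fit kept as a
    diagnostic of the 8-way-split assumption.
    """

    dead_volume_ul: float
    slope: float
    r_squared: float
    residuals_ul: np.ndarray
    free_slope: float
    free_intercept_ul: float
    free_r_squared: float
    negative_dead_volume: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["residuals_ul"] = np.asarray(self.residuals_ul).tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def fit_dead_volume(
    pairs: Sequence[tuple[float, float]],
) -> VolumeCalibration:
    """Fit the dead volume of the fluidic network.

    Each pair is (total injected volume, mean volume recovered per chamber),
    both in uL.  The constrained model splits the net injection equally over
    the 8 wells, V_w = (V_t - V_d)/8, whose least-squares dead volume has
    the closed form V_d = mean(V_t - 8 V_w).
    """
    if len(pairs) < 2:
        raise CalibrationError(
            f"calibration needs at least 2 (V_t, V_w) pairs, got {len(pairs)}")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be (total, per-chamber) 2-tuples")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("volumes must be finite")
    if np.any(arr <= 0):
        raise ValidationError("volumes must be positive")
    vt, vw = arr[:, 0], arr[:, 1]

    dead = float(np.mean(vt - N_WELLS * vw))
    negative = dead < 0
    if negative:
        warnings.warn(f"fitted dead volume is negative ({dead:.1f} uL)",
                      stacklevel=2)
    pred = (vt - dead) / N_WELLS
    resid = vw - pred
    ss_tot = float(np.sum((vw - vw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0

    # free-slope diagnostic
    slope_f, intercept_f = np.polyfit(vt, vw, 1)
    pred_f = slope_f * vt + intercept_f
    ss_res_f = float(np.sum((vw - pred_f) ** 2))
    r2_f = 1.0 - ss_res_f / ss_tot if ss_tot > 0 else 1.0

    return VolumeCalibration(
        dead_volume_ul=dead,
        slope=1.0 / N_WELLS,
        r_squared=r2,
        residuals_ul=resid,
        free_slope=float(slope_f),
        free_intercept_ul=float(intercept_f),
        free_r_squared=r2_f,
        negative_dead_volume=negative,
    )


def predict_chamber_volume(
    total_injected_ul: float, calibration: VolumeCalibration
) -> float:
    """Volume delivered per chamber (uL) for a given total injection.

    Returns (V_t - V_d)/8, clipped at zero (with a warning) when the
    injection does not exceed the dead volume.
    """
    if not np.isfinite(total_injected_ul):
        raise ValidationError("total injected volume must be finite")
    vw = (total_injected_ul - calibration.dead_volume_ul) / N_WELLS
    if vw < 0:
        warnings.warn(
            f"injected volume {total_injected_ul} uL is below the dead "
            f"volume {calibration.dead_volume_ul:.0f} uL; predicting 0",
            stacklevel=2)
        return 0.0
    return float(vw)


def read_volume_pairs_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read (total_injected_uL, chamber_volume_uL) pairs from a 2-column CSV."""
    pairs = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#"):
                continue
            try:
                pairs.append((float(row[0]), float(row[1])))
            except ValueError:
                continue  # header line
    return pairs


# ---- voxel geometry ---------------------------------------------------------

def voxel_bounds_mm(
    acq: AcquisitionParams, row: int, col: int
) -> tuple[float, float, float, float]:
    """(xmin, ymin, xmax, ymax) of a voxel in the device frame (mm)."""
    wx, wy = acq.voxel_size_mm
    x0 = -acq.fov_mm[0] / 2 + col * wx
    y0 = -acq.fov_mm[1] / 2 + row * wy
    return (x0, y0, x0 + wx, y0 + wy)


def circle_voxel_overlap_mm2(
    center: tuple[float, float], radius_mm: float,
    bounds: tuple[float, float, float, float],
    quad_segs: int = 256,
) -> float:
    """Area (mm^2) of the intersection between a chamber circle and a voxel."""
    circle = Point(*center).buffer(radius_mm, quad_segs=quad_segs)
    return float(circle.intersection(box(*bounds)).area)


def voxel_chamber_map(
    layout: ChamberLayout,
    acq: AcquisitionParams,
    k: int = 4,
) -> list[list[tuple[int, int]]]:
    """Assign to each chamber its top-k voxels by circle-voxel overlap area.

    Ties are broken by row-major voxel index; no voxel is assigned to two
    chambers (chambers are processed in order and claim voxels greedily).
    Returns, per chamber, a list of (row, col) indices.
    """
    nrow, ncol = acq.matrix
    half = (acq.fov_mm[0] / 2, acq.fov_mm[1] / 2)
    r = layout.radius_mm
    for i, (cx, cy) in enumerate(layout.chamber_centers):
        if abs(cx) + r > half[0] + 1e-9 or abs(cy) + r > half[1] + 1e-9:
            raise MappingError(f"chamber {i} extends outside the voxel grid")

    taken: set[int] = set()
    mapping: list[list[tuple[int, int]]] = []
    for ci, center in enumerate(layout.chamber_centers):
        scores = []
        for row in range(nrow):
            for col in range(ncol):
                idx = row * ncol + col
                if idx in taken:
                    continue
                area = circle_voxel_overlap_mm2(
                    center, r, voxel_bounds_mm(acq, row, col))
                if area > 0:
                    scores.append((-area, idx, row, col))
        scores.sort()  # largest overlap first, then row-major index
        if len(scores) < k:
            raise MappingError(
                f"chamber {ci} overlaps only {len(scores)} voxels, need {k}")
        chosen = scores[:k]
        taken.update(s[1] for s in chosen)
        mapping.append(sorted((row, col) for _, _, row, col in chosen))
    return mapping


def overlap_weights(
    layout: ChamberLayout, acq: AcquisitionParams
) -> np.ndarray:
    """Fraction of each chamber's circle area falling in each voxel.

    Returns an array of shape (n_chambers, nrow, ncol) whose entries sum to
    1 per chamber when the circle lies fully inside the field of view.
    """
    nrow, ncol = acq.matrix
    r = layout.radius_mm
    w = np.zeros((len(layout.chamber_centers), nrow, ncol))
    for ci, (cx, cy) in enumerate(layout.chamber_centers):
        circle = Point(cx, cy).buffer(r, quad_segs=256)
        for row in range(nrow):
            for col in range(ncol):
                bounds = voxel_bounds_mm(acq, row, col)
                # cheap reject: voxel farther than radius from center
                if (bounds[0] - cx > r or cx - bounds[2] > r
                        or bounds[1] - cy > r or cy - bounds[3] > r):
                    continue
                w[ci, row, col] = circle.intersection(box(*bounds)).area
        # normalize by the discretized circle's own area so fully covered
        # chambers have weights summing to exactly 1
        w[ci] /= circle.area
    return w
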