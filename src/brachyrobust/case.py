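"""Core in-memory model of an HDR prostate brachytherapy case.

All geometry lives in the DICOM patient coordinate system (x: patient
left +, y: posterior +, z: superior +), in millimetres; dwell times are
in seconds.  A case couples the delivery side (needles carrying dwell
positions and times) with the anatomy side (slice-wise closed contours
for prostate, urethra and rectum), the prescription dose and the
clinical dose-volume constraints against which every scenario is
scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: canonical structure names every case must provide
STRUCTURE_NAMES = ("prostate", "urethra", "rectum")

#: tolerance on uniform slice spacing, mm (float round-trip noise)
SLICE_SPACING_TOL = 0.01


class CaseValidationError(ValueError):
    """Raised when a case violates a structural invariant."""


@dataclass
class DwellSet:
    """Per-needle dwell positions, dwell times and needle-tip control points.

    ``positions[i]`` is an ``(n_i, 3)`` array ordered from the needle tip
    (superior) toward the insertion end (inferior); ``times[i]`` the
    matching dwell durations in seconds; ``tips[i]`` the needle end
    control point used for path fitting.
    """

    positions: list[np.ndarray]
    times: list[np.ndarray]
    tips: list[np.ndarray]

    def __post_init__(self) -> None:
        self.positions = [np.asarray(p, dtype=float).reshape(-1, 3) for p in self.positions]
        self.times = [np.asarray(t, dtype=float).reshape(-1) for t in self.times]
        self.tips = [np.asarray(t, dtype=float).reshape(3) for t in self.tips]

    @property
    def n_needles(self) -> int:
        return len(self.positions)

    @property
    def n_dwells(self) -> int:
        return sum(len(p) for p in self.positions)

    def all_positions(self) -> np.ndarray:
        """All dwell positions stacked into an ``(n_dwells, 3)`` array."""
        return np.concatenate(self.positions, axis=0)

    def all_times(self) -> np.ndarray:
        return np.concatenate(self.times)

    def copy(self) -> "DwellSet":
        return DwellSet(
            [p.copy() for p in self.positions],
            [t.copy() for t in self.times],
            [t.copy() for t in self.tips],
        )

    def validate(self) -> None:
        if self.n_needles == 0:
            raise CaseValidationError("case contains zero needles")
        if not (len(self.times) == len(self.tips) == self.n_needles):
            raise CaseValidationError("needle-wise field lengths disagree")
        for i, (pos, t) in enumerate(zip(self.positions, self.times)):
            if len(pos) == 0:
                raise CaseValidationError(f"needle {i} has zero dwells")
            if len(pos) != len(t):
                raise CaseValidationError(
                    f"needle {i}: {len(pos)} positions but {len(t)} times"
                )
            if np.any(t < 0):
                raise CaseValidationError(f"needle {i} has negative dwell times")


@dataclass
class Structure:
    """A contoured structure: ordered transverse slices of closed polygons.

    Each slice is an ``(L, 3)`` vertex array with constant z; slices are
    ordered inferior to superior at uniform spacing ``slice_width``.
    Polygons are stored open (first vertex not repeated).
    """

    slices: list[np.ndarray]
    slice_width: float

    def __post_init__(self) -> None:
        self.slices = [np.asarray(s, dtype=float).reshape(-1, 3) for s in self.slices]
        self.slice_width = float(self.slice_width)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def slice_z(self) -> np.ndarray:
        return np.array([s[0, 2] for s in self.slices])

    def all_points(self) -> np.ndarray:
        return np.concatenate(self.slices, axis=0)

    def centroid(self) -> np.ndarray:
        """Geometric mean of all contour vertices."""
        return self.all_points().mean(axis=0)

    def copy(self) -> "Structure":
        return Structure([s.copy() for s in self.slices], self.slice_width)

    def validate(self, name: str = "structure") -> None:
        if self.n_slices < 1:
            raise CaseValidationError(f"{name}: no slices")
        for k, s in enumerate(self.slices):
            if len(s) < 3:
                raise CaseValidationError(f"{name} slice {k}: fewer than 3 vertices")
            if np.ptp(s[:, 2]) > 1e-6:
                raise CaseValidationError(f"{name} slice {k}: z not constant")
        z = self.slice_z()
        if self.n_slices > 1:
            dz = np.diff(z)
            if np.any(dz <= 0):
                raise CaseValidationError(f"{name}: slices not ordered inferior→superior")
            if np.any(np.abs(dz - self.slice_width) > SLICE_SPACING_TOL):
                raise CaseValidationError(
                    f"{name}: non-uniform slice spacing {np.round(dz, 4).tolist()} "
                    f"(expected {self.slice_width} ± {SLICE_SPACING_TOL} mm)"
                )

    def resample_vertices(self, n_vertices: int) -> "Structure":
        """Resample every slice to ``n_vertices`` points at uniform angles.

        Vertices are placed on rays at uniform polar angles from the
        slice centroid (valid for star-shaped contours), giving every
        slice the same vertex count with index-aligned angular
        positions — a prerequisite for the superior–inferior curve
        resampling used by the prostate boundary operator.
        """
        out = []
        for s in self.slices:
            c = s[:, :2].mean(axis=0)
            d = s[:, :2] - c
            ang = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
            r = np.hypot(d[:, 0], d[:, 1])
            order = np.argsort(ang)
            ang_s, r_s = ang[order], r[order]
            # periodic extension for interpolation across the wrap
            ang_ext = np.concatenate([ang_s - 2 * np.pi, ang_s, ang_s + 2 * np.pi])
            r_ext = np.concatenate([r_s, r_s, r_s])
            target = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
            r_new = np.interp(target, ang_ext, r_ext)
            xy = c + np.column_stack([r_new * np.cos(target), r_new * np.sin(target)])
            out.append(np.column_stack([xy, np.full(n_vertices, s[0, 2])]))
        return Structure(out, self.slice_width)


@dataclass
class ContourSet:
    """The three named structures of a case."""

    structures: dict[str, Structure]

    def __getitem__(self, name: str) -> Structure:
        return self.structures[name]

    def copy(self) -> "ContourSet":
        return ContourSet({k: v.copy() for k, v in self.structures.items()})

    def validate(self) -> None:
        missing = [n for n in STRUCTURE_NAMES if n not in self.structures]
        if missing:
            raise CaseValidationError(
                f"missing structures {missing}; available: {sorted(self.structures)}"
            )
        for name, s in self.structures.items():
            s.validate(name)


@dataclass(frozen=True)
class MetricConstraint:
    """One clinical dose-volume objective, e.g. prostate D90 ≥ 16 Gy.

    ``kind`` is ``"D"`` (dose to hottest volume ``spec``) or ``"V"``
    (volume at dose level ``spec``); ``spec_unit`` gives the unit of
    ``spec`` (``%`` of volume / prescription, or ``cc`` / ``Gy``);
    ``direction`` is ``"ge"`` or ``"le"`` against ``limit``.
    """

    structure: str
    kind: str
    spec: float
    spec_unit: str
    limit: float
    limit_unit: str
    direction: str

    @property
    def name(self) -> str:
        if self.kind == "D" and self.spec_unit == "cc":
            return f"{self.structure}_D{self.spec:g}cc"
        return f"{self.structure}_{self.kind}{self.spec:g}"

    def passes(self, value: float) -> bool:
        # boundary equality counts as a pass
        return value >= self.limit if self.direction == "ge" else value <= self.limit


def default_constraints() -> list[MetricConstraint]:
    """The eight clinical objectives for a 16 Gy single-fraction boost."""
    return [
        MetricConstraint("prostate", "D", 90, "%", 16.0, "Gy", "ge"),
        MetricConstraint("prostate", "V", 100, "%", 90.0, "%", "ge"),
        MetricConstraint("prostate", "V", 150, "%", 40.0, "%", "le"),
        MetricConstraint("prostate", "V", 200, "%", 10.0, "%", "le"),
        MetricConstraint("urethra", "D", 10, "%", 18.4, "Gy", "le"),
        MetricConstraint("urethra", "D", 0.01, "cc", 18.4, "Gy", "le"),
        MetricConstraint("rectum", "V", 75, "%", 1.0, "cc", "le"),
        MetricConstraint("rectum", "D", 0.1, "cc", 13.0, "Gy", "le"),
    ]


@dataclass
class CaseModel:
    """A complete case: dwells, contours, prescription and constraints."""

    dwells: DwellSet
    contours: ContourSet
    prescription: float = 16.0
    constraints: list[MetricConstraint] = field(default_factory=default_constraints)

    def copy(self) -> "CaseModel":
        return CaseModel(
            self.dwells.copy(),
            self.contours.copy(),
            self.prescription,
            list(self.constraints),
        )

    def validate(self) -> None:
        if not (self.prescription > 0 and math.isfinite(self.prescription)):
            raise CaseValidationError("prescription must be positive and finite")
        self.dwells.validate()
        self.contours.validate()
        for c in self.constraints:
            if c.structure not in self.contours.structures:
                raise CaseValidationError(
                    f"constraint {c.name} references undefined structure {c.structure!r}"
                )

    def content_hash(self) -> int:
        """Hash of all numeric content; used to check operator purity."""
        h = []
        for p, t, tip in zip(self.dwells.positions, self.dwells.times, self.dwells.tips):
            h.extend([p.tobytes(), t.tobytes(), tip.tobytes()])
        for name in sorted(self.contours.structures):
            s = self.contours.structures[name]
            h.append(np.float64(s.slice_width).tobytes())
            h.extend(sl.tobytes() for sl in s.slices)
        h.append(np.float64(self.prescription).tobytes())
        return hash(b"".join(h))
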