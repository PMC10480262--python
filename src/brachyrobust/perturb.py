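"""The six variable-parameter operators that turn a nominal plan into a scenario.

Each operator simulates one family of treatment uncertainties:

1. dwells slide along their needle (needle-tip reconstruction, rigid SI
   needle motion, source positioning),
2. the prostate boundary expands/contracts radially from its geometric
   centre, with the contour resampled back to the original slice width,
3. urethra and rectum contours expand/contract slice-wise in 2D,
4. whole needles translate in the transverse plane,
5. dwell times scale by a percentage and gain a constant offset,
6. the prostate (with urethra and dwells) moves rigidly while the
   rectum stays put.

All operators are pure: they return new objects and never mutate their
inputs.  Applied in parameter order 1→6 by :func:`apply_scenario`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .case import CaseModel, ContourSet, DwellSet, Structure
from .needles import NeedlePath

log = logging.getLogger(__name__)


@dataclass
class ScenarioParams:
    """One realization of the six variable parameters.

    Signs follow the patient coordinate system (x left +, y posterior +,
    z superior +); ``p1_shift`` is positive toward the needle tip
    (superior).  ``p3_*`` are radial magnitudes applied to contour
    vertices.  ``p4_transverse`` holds one ``[X, Y]`` mm vector per
    needle (``None`` = no movement).
    """

    p1_shift: float = 0.0
    p2_prostate: float = 0.0
    p3_urethra: float = 0.0
    p3_rectum: float = 0.0
    p4_transverse: np.ndarray | None = None
    p5_scale: float = 1.0
    p5_offset: float = 0.0
    p6_rigid: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.p4_transverse is not None:
            self.p4_transverse = np.asarray(self.p4_transverse, float).reshape(-1, 2)
        self.p6_rigid = np.asarray(self.p6_rigid, float).reshape(3)
        if not self.p5_scale > 0:
            raise ValueError("p5_scale must be > 0")

    def geometry_key(self) -> tuple:
        """Hashable key of everything except the dwell-time parameter."""
        p4 = None if self.p4_transverse is None else self.p4_transverse.tobytes()
        return (self.p1_shift, self.p2_prostate, self.p3_urethra,
                self.p3_rectum, p4, self.p6_rigid.tobytes())


# ---------------------------------------------------------------------------
# parameter 1: dwells move along the needle
# ---------------------------------------------------------------------------


def shift_dwells_along_needle(
    dwells: DwellSet, paths: list[NeedlePath], x: float
) -> DwellSet:
    """Slide every dwell a distance ``x`` along its needle path.

    Positive ``x`` moves dwells toward the needle tip (superior), i.e.
    each dwell's arc-length coordinate decreases by ``x``.  Shifts past
    a path end clamp to the end point with a warning.
    """
    out = dwells.copy()
    clamped = 0
    for i, path in enumerate(paths):
        pos = dwells.positions[i]
        d2 = (
            np.sum(path.points**2, axis=1)[None, :]
            - 2.0 * pos @ path.points.T
            + np.sum(pos**2, axis=1)[:, None]
        )
        k_min = np.argmin(d2, axis=1)
        target = path.arclengths[k_min] - x
        lo, hi = path.arclengths[0], path.arclengths[-1]
        clamped += int(np.sum((target < lo) | (target > hi)))
        target_c = np.clip(target, lo, hi)
        # nearest arc-length entry; ties resolve to the lower index
        idx = np.searchsorted(path.arclengths, target_c)
        idx = np.clip(idx, 1, len(path.arclengths) - 1)
        left = path.arclengths[idx - 1]
        right = path.arclengths[idx]
        use_left = (target_c - left) <= (right - target_c)
        k_x = np.where(use_left, idx - 1, idx)
        out.positions[i] = path.points[k_x].copy()
    if clamped:
        warnings.warn(
            f"{clamped} dwell shift(s) exceeded the needle path and were clamped",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# parameter 2: prostate boundary expansion/contraction
# ---------------------------------------------------------------------------


class ContourCollapseError(ValueError):
    """A contraction pulled a vertex through the structure centre."""


def _radial_move(points: np.ndarray, centre: np.ndarray, x: float, label: str) -> np.ndarray:
    d = points - centre
    r = np.linalg.norm(d, axis=1)
    if np.any(r + x <= 0):
        raise ContourCollapseError(
            f"{label}: contraction {x} mm collapses a vertex through the centre "
            f"(min radius {r.min():.3f} mm)"
        )
    return points + (d / r[:, None]) * x


def scale_prostate(structure: Structure, x: float, q_factor: int = 10) -> Structure:
    """Expand/contract the prostate by ``x`` mm from its geometric centre.

    Every vertex moves ``x`` mm along the line joining it to the mean of
    all contour points, which perturbs slice z-planes; the structure is
    then resampled back to the original slice width.  Each
    superior–inferior vertex curve is refit with an interpolating cubic
    B-spline evaluated at ``q_factor`` × the slice count, the crossing
    parameter for each target z-level refined by inverse interpolation,
    and the new slices placed on the original slice lattice (so the
    identity perturbation reproduces the input slices).
    """
    n = structure.n_slices
    if n < 3:
        raise ValueError("prostate needs at least 3 slices")
    counts = {len(s) for s in structure.slices}
    struct = structure if len(counts) == 1 else structure.resample_vertices(max(counts))
    centre = struct.centroid()
    moved = [_radial_move(s, centre, x, "prostate") for s in struct.slices]

    z_orig = struct.slice_z()
    width = (z_orig.max() - z_orig.min()) / (n - 1) if n > 1 else struct.slice_width

    # dimension swap: l-th vertex of each slice forms a curve along z
    curves = np.stack(moved, axis=0)          # (n_slices, L, 3)
    L = curves.shape[1]
    t = np.arange(n, dtype=float)
    q = max(q_factor * n, 2 * n)
    t_dense = np.linspace(0.0, n - 1.0, q)
    k = min(3, n - 1)

    splines = [make_interp_spline(t, curves[:, l, :], k=k) for l in range(L)]
    dense = [s(t_dense) for s in splines]     # each (q, 3)

    zmin = max(d[:, 2].min() for d in dense)
    zmax = min(d[:, 2].max() for d in dense)
    # new slices stay on the original slice lattice (spacing `width`,
    # symmetric about the original mean z), growing or shrinking at the
    # ends to cover the moved structure
    z_anchor = z_orig[0]
    k_lo = int(np.ceil((zmin - z_anchor) / width - 1e-9))
    k_hi = int(np.floor((zmax - z_anchor) / width + 1e-9))
    if k_hi < k_lo:
        raise ContourCollapseError("prostate: contraction leaves no resampled slices")
    levels = z_anchor + width * np.arange(k_lo, k_hi + 1)

    new_slices = []
    for z_level in levels:
        verts = np.empty((L, 3))
        for l, (s, d) in enumerate(zip(splines, dense)):
            # z is monotone along the curve: invert z(t) on the dense grid
            t_star = np.interp(z_level, d[:, 2], t_dense)
            p = s(t_star)
            verts[l, :2] = p[:2]
            verts[l, 2] = z_level
        new_slices.append(verts)
    return Structure(new_slices, width)


# ---------------------------------------------------------------------------
# parameter 3: urethra/rectum slice-wise expansion
# ---------------------------------------------------------------------------


def scale_structure_slicewise(structure: Structure, x: float, name: str = "structure") -> Structure:
    """Move every vertex ``x`` mm along the line from its slice centroid.

    Purely in-plane (z untouched), no resampling; the OARs extend beyond
    their contoured superior–inferior region, so per-slice 2D scaling is
    the appropriate uncertainty model.
    """
    out = []
    for idx, s in enumerate(structure.slices):
        centre = s.mean(axis=0)  # z-component of (v - centre) is 0
        out.append(_radial_move(s, centre, x, f"{name} slice {idx}"))
    return Structure(out, structure.slice_width)


# ---------------------------------------------------------------------------
# parameter 4: needle transverse translation
# ---------------------------------------------------------------------------


def translate_needles_transverse(dwells: DwellSet, vectors: np.ndarray) -> DwellSet:
    """Translate each needle by its own ``[X, Y]`` vector in the transverse plane."""
    vectors = np.asarray(vectors, float).reshape(-1, 2)
    if len(vectors) != dwells.n_needles:
        raise ValueError(
            f"{len(vectors)} vectors for {dwells.n_needles} needles"
        )
    out = dwells.copy()
    for i, v in enumerate(vectors):
        shift = np.array([v[0], v[1], 0.0])
        out.positions[i] = out.positions[i] + shift
        out.tips[i] = out.tips[i] + shift
    return out


# ---------------------------------------------------------------------------
# parameter 5: dwell-time adjustment
# ---------------------------------------------------------------------------


def adjust_dwell_times(
    times: list[np.ndarray], scale: float, offset: float
) -> tuple[list[np.ndarray], int]:
    """Apply ``t ← t × scale + offset`` per dwell, clipping at zero.

    Returns the new times and the number of clipped (negative) entries.
    Dwell times are physically non-negative, hence the clip.
    """
    if not scale > 0:
        raise ValueError("scale must be > 0")
    out, clipped = [], 0
    for t in times:
        new = t * scale + offset
        clipped += int(np.sum(new < 0))
        out.append(np.clip(new, 0.0, None))
    if clipped:
        log.warning("%d dwell time(s) clipped at 0 s", clipped)
    return out, clipped


# ---------------------------------------------------------------------------
# parameter 6: prostate rigid movement
# ---------------------------------------------------------------------------


def rigid_move(case: CaseModel, vector: np.ndarray) -> CaseModel:
    """Translate prostate, urethra and all dwells by ``vector``; rectum fixed.

    Relative prostate–rectum motion is simulated by moving only the
    prostate side of the geometry.
    """
    vector = np.asarray(vector, float).reshape(3)
    out = case.copy()
    for name in ("prostate", "urethra"):
        s = out.contours.structures[name]
        out.contours.structures[name] = Structure(
            [sl + vector for sl in s.slices], s.slice_width
        )
    for i in range(out.dwells.n_needles):
        out.dwells.positions[i] = out.dwells.positions[i] + vector
        out.dwells.tips[i] = out.dwells.tips[i] + vector
    return out


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------


def apply_scenario(
    case: CaseModel, paths: list[NeedlePath], params: ScenarioParams
) -> CaseModel:
    """Apply all six operators in parameter order 1→6; the input is untouched."""
    out = case.copy()
    if params.p1_shift != 0.0:
        out.dwells = shift_dwells_along_needle(out.dwells, paths, params.p1_shift)
    if params.p2_prostate != 0.0:
        out.contours.structures["prostate"] = scale_prostate(
            out.contours.structures["prostate"], params.p2_prostate
        )
    if params.p3_urethra != 0.0:
        out.contours.structures["urethra"] = scale_structure_slicewise(
            out.contours.structures["urethra"], params.p3_urethra, "urethra"
        )
    if params.p3_rectum != 0.0:
        out.contours.structures["rectum"] = scale_structure_slicewise(
            out.contours.structures["rectum"], params.p3_rectum, "rectum"
        )
    if params.p4_transverse is not None and np.any(params.p4_transverse != 0):
        out.dwells = translate_needles_transverse(out.dwells, params.p4_transverse)
    if params.p5_scale != 1.0 or params.p5_offset != 0.0:
        out.dwells.times, _ = adjust_dwell_times(
            out.dwells.times, params.p5_scale, params.p5_offset
        )
    if np.any(params.p6_rigid != 0):
        out = rigid_move(out, params.p6_rigid)
    return out
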