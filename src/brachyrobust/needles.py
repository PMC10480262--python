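"""Dense interpolated needle paths with arc-length maps.

Each needle is represented by a dense polyline (~6000 points by
default) obtained from an interpolating spline through the needle-tip
control point and the dwell positions, so the fitted curve passes
through every dwell exactly and zero-magnitude perturbations stay
exact.  The cumulative arc length from the tip provides a direct map
between a path index and its distance along the needle, which is what
the dwell-shift operator moves along.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .case import DwellSet

#: default number of interpolated points per needle
DEFAULT_N_POINTS = 6000

#: default straight extension past the most inferior dwell, mm; the
#: default path spans tip → last dwell (shifts beyond it clamp)
DEFAULT_INFERIOR_EXTENSION = 0.0

#: free length used to extend single-dwell needles, mm, so the dwell
#: has room to shift in both directions
SINGLE_DWELL_FREE_LENGTH = 20.0


class NeedleFitError(ValueError):
    """Raised when a needle's control points cannot define a curve."""


@dataclass
class NeedlePath:
    """Dense polyline for one needle, indexed from the tip.

    ``arclengths[k]`` is the cumulative distance of ``points[k]`` from
    the needle tip (``arclengths[0] == 0``).
    """

    points: np.ndarray
    arclengths: np.ndarray

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tangents(self) -> np.ndarray:
        """Unit tangent vectors at every path point (central differences)."""
        if not hasattr(self, "_tangents"):
            d = np.gradient(self.points, axis=0)
            norm = np.linalg.norm(d, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._tangents = d / norm
        return self._tangents


def _dedupe(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > tol:
            keep.append(i)
    return points[keep]


def build_needle_path(
    tip: np.ndarray,
    dwell_positions: np.ndarray,
    n_points: int = DEFAULT_N_POINTS,
    inferior_extension: float = DEFAULT_INFERIOR_EXTENSION,
    needle_index: int | None = None,
) -> NeedlePath:
    """Fit one needle path through ``tip`` followed by the dwell positions."""
    ctrl = _dedupe(np.vstack([np.asarray(tip, float).reshape(1, 3),
                              np.asarray(dwell_positions, float).reshape(-1, 3)]))
    label = f"needle {needle_index}" if needle_index is not None else "needle"
    if len(ctrl) < 2:
        raise NeedleFitError(
            f"{label}: control points are coincident; cannot orient the curve"
        )
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))])
    total_chord = chord[-1]
    if total_chord <= 0:
        raise NeedleFitError(f"{label}: zero-length control polygon")
    k = min(3, len(ctrl) - 1)
    spline = make_interp_spline(chord, ctrl, k=k)
    ext = max(float(inferior_extension), 0.0)
    if len(ctrl) == 2:
        # single dwell: straight segment tip→dwell, extended inferiorly
        # by the needle's free length so shifts have room
        ext = max(ext, SINGLE_DWELL_FREE_LENGTH)
    n_main = max(int(round(n_points * total_chord / (total_chord + ext))), 2)
    n_ext = max(n_points - n_main, 0)
    t = np.linspace(0.0, total_chord, n_main)
    pts = spline(t)
    if n_ext > 0:
        tang = pts[-1] - pts[-2]
        tang = tang / np.linalg.norm(tang)
        step = ext / n_ext
        pts = np.vstack([pts, pts[-1] + tang * step * np.arange(1, n_ext + 1)[:, None]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclengths = np.concatenate([[0.0], np.cumsum(seg)])
    path = NeedlePath(pts, arclengths)
    # the interpolating fit must pass through every dwell
    for j, d in enumerate(np.atleast_2d(dwell_positions)):
        dist = np.linalg.norm(path.points - d, axis=1).min()
        if dist > 0.5:
            raise NeedleFitError(
                f"{label}: dwell {j} lies {dist:.2f} mm from the fitted path"
            )
    return path


def build_needle_paths(
    dwells: DwellSet,
    n_points: int = DEFAULT_N_POINTS,
    inferior_extension: float = DEFAULT_INFERIOR_EXTENSION,
) -> list[NeedlePath]:
    """One dense path per needle, starting at the needle tip."""
    return [
        build_needle_path(
            dwells.tips[i], dwells.positions[i], n_points, inferior_extension, i
        )
        for i in range(dwells.n_needles)
    ]


def nearest_path_index(path: NeedlePath, point: np.ndarray) -> int:
    """Index of the path point closest to ``point`` (lowest-index tie-break)."""
    d2 = np.einsum("ij,ij->i", path.points - point, path.points - point)
    return int(np.argmin(d2))
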