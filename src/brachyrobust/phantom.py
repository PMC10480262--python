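"""Reproducible synthetic phantom cases for testing and demonstration.

The default phantom emulates the study geometry the evaluation method
is demonstrated on: an ellipsoidal prostate contoured at ≈38 cc in
uniform transverse slices, a central urethra tube extending 9 mm more
inferiorly and 6 mm more superiorly than the prostate, a posterior
rectum tube extending 15 mm more inferiorly and 6 mm more superiorly,
and 16 needles on a 5 mm template grid running inferior→superior
through the gland with dwells at a fixed step size.  Dwell times are
uniform until :func:`normalize_dwell_times` scales them so the nominal
prostate D90 equals the prescription.

Everything is deterministic given the spec (the seed is reserved for
future stochastic anatomy variants; the default construction is
entirely geometric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .case import CaseModel, ContourSet, DwellSet, Structure
from .dvh import dose_at_volume, sample_structure_points
from .needles import build_needle_paths
from .tg43 import SourceModel, accumulate_dose, synthetic_ir192


@dataclass
class PhantomSpec:
    """Parameters of the synthetic case."""

    prostate_volume_cc: float = 38.1
    axis_ratios: tuple[float, float, float] = (1.25, 0.95, 1.0)  # LR, AP, SI
    prostate_slice_width: float = 2.5
    n_prostate_vertices: int = 48
    urethra_radius: float = 3.0
    urethra_inferior_ext: float = 9.0
    urethra_superior_ext: float = 6.0
    rectum_radius: float = 10.0
    rectum_gap: float = 2.0           # prostate surface → anterior rectal wall
    rectum_inferior_ext: float = 15.0
    rectum_superior_ext: float = 6.0
    n_oar_vertices: int = 24
    n_needles: int = 16
    needle_grid: float = 5.0          # template hole spacing, mm
    needle_max_radial_fraction: float = 0.8   # holes within this elliptical fraction
    urethra_clearance: float = 8.0    # min hole distance from the urethra axis, mm
    dwell_margin_fraction: float = 0.95       # dwells inside this gland fraction
    dwell_spacing: float = 5.0        # source step size, mm
    prescription: float = 16.0
    seed: int = 0

    def semi_axes(self) -> tuple[float, float, float]:
        ra, rb, rc = self.axis_ratios
        c = (3.0 * self.prostate_volume_cc * 1000.0 / (4.0 * np.pi * ra * rb * rc)) ** (1 / 3)
        return ra * c, rb * c, rc * c

    def validate(self) -> None:
        if self.prostate_volume_cc <= 0:
            raise ValueError("prostate volume must be > 0")
        if self.n_needles < 1:
            raise ValueError("need at least one needle")
        a, b, _ = self.semi_axes()
        if self.urethra_radius >= min(a, b):
            raise ValueError("urethra radius exceeds the prostate minor axis")


def _circle_slice(cx, cy, z, radius, n_vertices):
    ang = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [cx + radius * np.cos(ang), cy + radius * np.sin(ang), np.full(n_vertices, z)]
    )


def _polygon_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def generate_phantom(spec: PhantomSpec | None = None) -> CaseModel:
    """Build the synthetic case; fully deterministic for a given spec."""
    spec = spec or PhantomSpec()
    spec.validate()
    a, b, c = spec.semi_axes()
    w = spec.prostate_slice_width

    # prostate: uniform slices of the ellipsoid, symmetric about z = 0
    n_slices = int(np.floor(2.0 * c / w + 1.0 - 1e-9))
    z_levels = (np.arange(n_slices) - (n_slices - 1) / 2.0) * w
    slices = []
    for z in z_levels:
        s = np.sqrt(max(1.0 - (z / c) ** 2, 1e-6))
        ang = np.linspace(0.0, 2 * np.pi, spec.n_prostate_vertices, endpoint=False)
        slices.append(
            np.column_stack(
                [a * s * np.cos(ang), b * s * np.sin(ang), np.full_like(ang, z)]
            )
        )
    # calibrate the contoured (stacked-polygon) volume to the target exactly
    stacked = sum(_polygon_area(sl[:, :2]) for sl in slices) * w
    scale = np.sqrt(spec.prostate_volume_cc * 1000.0 / stacked)
    for sl in slices:
        sl[:, :2] *= scale
    a_eff, b_eff = a * scale, b * scale
    prostate = Structure(slices, w)
    pz_min, pz_max = z_levels[0], z_levels[-1]

    # urethra: central tube spanning [pz_min - 9, pz_max + 6] mm
    u_lo = pz_min - spec.urethra_inferior_ext
    u_hi = pz_max + spec.urethra_superior_ext
    n_u = int(round((u_hi - u_lo) / w)) + 1
    wu = (u_hi - u_lo) / (n_u - 1)
    urethra = Structure(
        [_circle_slice(0.0, 0.0, z, spec.urethra_radius, spec.n_oar_vertices)
         for z in np.linspace(u_lo, u_hi, n_u)],
        wu,
    )

    # rectum: posterior tube spanning [pz_min - 15, pz_max + 6] mm
    r_lo = pz_min - spec.rectum_inferior_ext
    r_hi = pz_max + spec.rectum_superior_ext
    n_r = int(round((r_hi - r_lo) / w)) + 1
    wr = (r_hi - r_lo) / (n_r - 1)
    cy = b_eff + spec.rectum_gap + spec.rectum_radius
    rectum = Structure(
        [_circle_slice(0.0, cy, z, spec.rectum_radius, spec.n_oar_vertices)
         for z in np.linspace(r_lo, r_hi, n_r)],
        wr,
    )

    # needles: template-grid holes, most peripheral first (peripheral
    # loading), clear of the urethra
    g = spec.needle_grid
    cand = []
    for x in np.arange(-np.ceil(a_eff / g) * g, np.ceil(a_eff / g) * g + g / 2, g):
        for y in np.arange(-np.ceil(b_eff / g) * g, np.ceil(b_eff / g) * g + g / 2, g):
            re = np.hypot(x / a_eff, y / b_eff)
            if re > spec.needle_max_radial_fraction:
                continue
            if np.hypot(x, y) < spec.urethra_clearance:
                continue
            cand.append((x, y, re))
    if len(cand) < spec.n_needles:
        raise ValueError(
            f"template admits only {len(cand)} needle positions for "
            f"{spec.n_needles} requested"
        )
    cand.sort(key=lambda t: (-round(t[2], 6), np.arctan2(t[1], t[0])))
    holes = cand[: spec.n_needles]

    positions, times, tips = [], [], []
    for x, y, re in holes:
        z_half = c * np.sqrt(max(spec.dwell_margin_fraction**2 - re**2, 0.0))
        dz = spec.dwell_spacing
        k_max = int(np.floor(z_half / dz))
        zs = np.arange(-k_max, k_max + 1) * dz if k_max >= 0 else np.array([0.0])
        if len(zs) == 0:
            zs = np.array([0.0])
        zs = np.sort(zs)[::-1]  # tip-ward (superior) first
        positions.append(np.column_stack([np.full_like(zs, x), np.full_like(zs, y), zs]))
        # heuristic peripheral loading: longer dwells toward the capsule
        # and at the base/apex ends, in lieu of inverse optimization
        t = np.full(len(zs), 0.3 + 0.7 * re**2)
        if len(t) > 1:
            t[0] *= 1.5
            t[-1] *= 1.5
        times.append(t)
        tips.append(np.array([x, y, zs[0] + 3.0]))
    dwells = DwellSet(positions, times, tips)

    case = CaseModel(
        dwells,
        ContourSet({"prostate": prostate, "urethra": urethra, "rectum": rectum}),
        spec.prescription,
    )
    case.validate()
    return case


def normalize_dwell_times(
    case: CaseModel,
    source: SourceModel | None = None,
    target: float | None = None,
    tol: float = 0.005,
    max_iter: int = 30,
    grid_spacing: float = 1.0,
) -> CaseModel:
    """Scale all dwell times uniformly so prostate D90 hits the target dose.

    D90 is exactly linear in a global time scale, so the ratio update
    converges immediately; the loop guards the stated 0.5% tolerance.
    Returns a new case; the input is untouched.
    """
    source = source or synthetic_ir192()
    target = case.prescription if target is None else target
    out = case.copy()
    paths = build_needle_paths(out.dwells)
    pts, wts = sample_structure_points(out.contours["prostate"], grid_spacing)
    for _ in range(max_iter):
        dose = accumulate_dose(out.dwells, paths, source, pts, wts).dose
        d90 = dose_at_volume(dose, wts, volume_pct=90)
        if abs(d90 - target) <= tol * target:
            return out
        if d90 <= 0:
            raise RuntimeError("prostate receives no dose; cannot normalize")
        factor = target / d90
        out.dwells.times = [t * factor for t in out.dwells.times]
    raise RuntimeError(
        f"dwell-time normalization did not converge (achieved D90 = {d90:.3f} Gy)"
    )
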