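"""TG-43 dose calculation for a stepping HDR source.

Implements the AAPM TG-43 formalism: dose rate at a point is

    D(r, θ) = S_K · Λ · [G_L(r, θ) / G_L(r₀, θ₀)] · g(r) · F(r, θ)

with air-kerma strength S_K (U), dose-rate constant Λ (cGy·h⁻¹·U⁻¹),
line-source geometry function G_L, radial dose function g(r) and 2D
anisotropy function F(r, θ), all referenced to r₀ = 1 cm, θ₀ = 90°.
Dose is computed in a homogeneous water medium — the standard TG-43
limitation (no heterogeneity, shielding or scatter corrections).

Internal units are SI (Gy, s, mm); distances convert to cm at the
kernel boundary.  The default source is a *synthetic* generic HDR
Ir-192 line source whose g(r)/F(r,θ) tables are generated from a
simplified attenuation/anisotropy model; users supply measured
consensus tables via :func:`load_source_tables` for clinical use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .case import DwellSet
from .needles import NeedlePath, nearest_path_index

log = logging.getLogger(__name__)

#: cGy/h → Gy/s
_RATE_CONV = 0.01 / 3600.0


@dataclass
class SourceModel:
    """An HDR source: strength, dose-rate constant and TG-43 tables."""

    dose_rate_constant: float        # Λ, cGy·h⁻¹·U⁻¹
    air_kerma_strength: float        # S_K, U
    active_length: float             # L, mm
    radial_r: np.ndarray             # cm, strictly increasing
    radial_g: np.ndarray             # g(r), g(1 cm) = 1
    aniso_r: np.ndarray              # cm
    aniso_theta: np.ndarray          # deg, 0..180
    aniso_f: np.ndarray              # F(r, θ), F(r, 90°) = 1
    mode: str = "line"               # {"line", "point"}

    def __post_init__(self) -> None:
        self.radial_r = np.asarray(self.radial_r, float)
        self.radial_g = np.asarray(self.radial_g, float)
        self.aniso_r = np.asarray(self.aniso_r, float)
        self.aniso_theta = np.asarray(self.aniso_theta, float)
        self.aniso_f = np.asarray(self.aniso_f, float)
        if np.any(np.diff(self.radial_r) <= 0) or np.any(np.diff(self.aniso_r) <= 0):
            raise ValueError("radius tables must be strictly increasing")
        g1 = np.interp(1.0, self.radial_r, self.radial_g)
        if abs(g1 - 1.0) > 1e-3:
            raise ValueError(f"g(r0=1 cm) = {g1:.4f}, must be 1")
        if np.max(np.abs(self._f_at_90() - 1.0)) > 1e-3:
            raise ValueError("F(r, 90°) must be 1")
        if self.mode not in ("line", "point"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def _f_at_90(self) -> np.ndarray:
        col = np.empty(len(self.aniso_r))
        for i in range(len(self.aniso_r)):
            col[i] = np.interp(90.0, self.aniso_theta, self.aniso_f[i])
        return col


def synthetic_ir192(
    air_kerma_strength: float = 40820.0, mode: str = "line"
) -> SourceModel:
    """A synthetic generic HDR Ir-192 line source (stand-in tables).

    The radial dose function follows a cubic tissue
    attenuation/build-up polynomial normalised at 1 cm and the
    anisotropy a smooth axial-depression model — representative of an
    Ir-192 HDR source but *not* a measured consensus dataset.  Default
    strength corresponds to a ≈10 Ci source; Λ = 1.109 cGy·h⁻¹·U⁻¹;
    active length 3.5 mm.
    """
    r = np.array([0.1, 0.15, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0,
                  4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 14.0])
    poly = np.array([1.0128, 5.019e-3, -1.178e-3, -2.008e-5])  # 1, r, r², r³

    def m(x):
        return poly[0] + poly[1] * x + poly[2] * x**2 + poly[3] * x**3

    g = m(r) / m(1.0)
    theta = np.arange(0.0, 181.0, 10.0)
    ar = np.array([0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0])
    amp = 0.32 * np.exp(-ar / 3.0) + 0.12
    f = 1.0 - amp[:, None] * np.abs(np.cos(np.radians(theta)))[None, :] ** 2.5
    return SourceModel(
        dose_rate_constant=1.109,
        air_kerma_strength=air_kerma_strength,
        active_length=3.5,
        radial_r=r,
        radial_g=g,
        aniso_r=ar,
        aniso_theta=theta,
        aniso_f=f,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# plain-text table I/O (columnar: "r g" and "r theta F" rows)
# ---------------------------------------------------------------------------


def write_source_tables(source: SourceModel, g_path: str, f_path: str) -> None:
    """Write g(r) and F(r,θ) as whitespace-separated columnar text."""
    with open(g_path, "w") as fh:
        fh.write("# r_cm g\n")
        for r, g in zip(source.radial_r, source.radial_g):
            fh.write(f"{float(r)!r} {float(g)!r}\n")
    with open(f_path, "w") as fh:
        fh.write("# r_cm theta_deg F\n")
        for i, r in enumerate(source.aniso_r):
            for j, th in enumerate(source.aniso_theta):
                fh.write(f"{float(r)!r} {float(th)!r} {float(source.aniso_f[i, j])!r}\n")


def load_source_tables(
    g_path: str,
    f_path: str,
    dose_rate_constant: float = 1.109,
    air_kerma_strength: float = 40820.0,
    active_length: float = 3.5,
    mode: str = "line",
) -> SourceModel:
    """Load a source from columnar g(r) and F(r,θ) text tables."""
    gr = np.loadtxt(g_path)
    fr = np.loadtxt(f_path)
    r_vals = np.unique(fr[:, 0])
    th_vals = np.unique(fr[:, 1])
    f = np.full((len(r_vals), len(th_vals)), np.nan)
    ri = np.searchsorted(r_vals, fr[:, 0])
    ti = np.searchsorted(th_vals, fr[:, 1])
    f[ri, ti] = fr[:, 2]
    if np.any(np.isnan(f)):
        raise ValueError(f"{f_path}: anisotropy grid is not complete")
    return SourceModel(
        dose_rate_constant, air_kerma_strength, active_length,
        gr[:, 0], gr[:, 1], r_vals, th_vals, f, mode,
    )


# ---------------------------------------------------------------------------
# geometry function
# ---------------------------------------------------------------------------


def line_geometry_factor(r, theta, L):
    """Normalised line-source geometry function G_L(r,θ) / G_L(1 cm, 90°).

    ``r`` in cm, ``theta`` in degrees, ``L`` (active length) in cm.
    On-axis values use the limit 1/(r² − L²/4).  Reduces to (1 cm / r)²
    as L → 0.
    """
    r = np.asarray(r, float)
    theta = np.asarray(theta, float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0 (geometry function singular at the source)")
    if L <= 0:
        return np.asarray(1.0 / r**2)
    g0 = 2.0 * np.arctan(L / 2.0) / L  # G_L(1, 90°)
    th = np.radians(theta)
    z = r * np.cos(th)
    rho = r * np.sin(th)
    on_axis = rho < 1e-9
    rho_safe = np.where(on_axis, 1.0, rho)
    beta = np.arctan((z + L / 2.0) / rho_safe) - np.arctan((z - L / 2.0) / rho_safe)
    g = beta / (L * rho_safe)
    axis_val = 1.0 / np.maximum(r**2 - L**2 / 4.0, 1e-12)
    g = np.where(on_axis, axis_val, g)
    return g / g0


# ---------------------------------------------------------------------------
# interpolation helpers (log-linear in r for g; bilinear for F)
# ---------------------------------------------------------------------------


def _radial_dose(source: SourceModel, r: np.ndarray) -> np.ndarray:
    rt, gt = source.radial_r, source.radial_g
    logr = np.log(np.maximum(r, rt[0]))
    g = np.interp(logr, np.log(rt), gt)
    over = r > rt[-1]
    if np.any(over):
        log.warning("radii beyond g(r) table; extrapolating log-linearly")
        slope = (gt[-1] - gt[-2]) / (np.log(rt[-1]) - np.log(rt[-2]))
        g = np.where(over, gt[-1] + slope * (logr - np.log(rt[-1])), g)
    return g


def _anisotropy(source: SourceModel, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    if source.mode == "point":
        return np.ones_like(r)
    rt, tt, f = source.aniso_r, source.aniso_theta, source.aniso_f
    rc = np.clip(r, rt[0], rt[-1])
    thc = np.clip(theta, tt[0], tt[-1])
    i = np.clip(np.searchsorted(rt, rc) - 1, 0, len(rt) - 2)
    j = np.clip(np.searchsorted(tt, thc) - 1, 0, len(tt) - 2)
    fr = (rc - rt[i]) / (rt[i + 1] - rt[i])
    ft = (thc - tt[j]) / (tt[j + 1] - tt[j])
    return (
        f[i, j] * (1 - fr) * (1 - ft)
        + f[i + 1, j] * fr * (1 - ft)
        + f[i, j + 1] * (1 - fr) * ft
        + f[i + 1, j + 1] * fr * ft
    )


def _rate_matrix(
    source: SourceModel,
    dwell_pos: np.ndarray,
    dwell_dir: np.ndarray,
    points: np.ndarray,
) -> np.ndarray:
    """Dose rate (Gy/s) from each dwell at each point: shape (P, D)."""
    dwell_pos = np.atleast_2d(dwell_pos)
    dwell_dir = np.atleast_2d(dwell_dir)
    points = np.atleast_2d(points)
    diff = points[:, None, :] - dwell_pos[None, :, :]      # mm
    r_mm = np.sqrt(np.einsum("pdi,pdi->pd", diff, diff))
    r = r_mm / 10.0                                        # cm
    r_min = min(source.radial_r[0], source.aniso_r[0])
    near = r < r_min
    if np.any(near):
        log.debug(
            "%d point–dwell distance(s) below the minimum table radius; "
            "contribution capped at the minimum-r table value", int(near.sum())
        )
        r = np.maximum(r, r_min)
    cos_t = np.einsum("pdi,di->pd", diff, dwell_dir) / np.maximum(r_mm, 1e-12)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_t))
    if source.mode == "line":
        geo = line_geometry_factor(r, theta, source.active_length / 10.0)
    else:
        geo = 1.0 / r**2
    rate = (
        source.air_kerma_strength
        * source.dose_rate_constant
        * geo
        * _radial_dose(source, r)
        * _anisotropy(source, r, theta)
        * _RATE_CONV
    )
    return rate


def dose_rate_at(
    source: SourceModel,
    dwell_pos: np.ndarray,
    dwell_dir: np.ndarray,
    point: np.ndarray,
) -> float:
    """Dose rate (Gy/s) at one point from one dwell.

    ``dwell_dir`` is the unit source axis; point mode ignores anisotropy.
    """
    dwell_dir = np.asarray(dwell_dir, float)
    n = np.linalg.norm(dwell_dir)
    if abs(n - 1.0) > 1e-6:
        raise ValueError("dwell_dir must be a unit vector")
    point = np.asarray(point, float)
    if np.allclose(point, dwell_pos):
        raise ValueError("point coincides with the dwell position")
    return float(_rate_matrix(source, dwell_pos, dwell_dir, point)[0, 0])


@dataclass
class DoseSample:
    """Dose evaluated at weighted sample points.

    ``rate_sum`` (Gy/s, per point, summed over dwells) is retained so a
    pure dwell-time change ``t → t·s + y`` maps dose linearly to
    ``s·dose + y·rate_sum`` without re-evaluating the kernel.
    """

    points: np.ndarray       # (N, 3) mm
    dose: np.ndarray         # Gy
    weight: np.ndarray       # mm³ per point
    rate_sum: np.ndarray | None = None


def dwell_directions(dwells: DwellSet, paths: list[NeedlePath]) -> np.ndarray:
    """Unit source axis per dwell: the needle-path tangent at the nearest path point."""
    dirs = []
    for i in range(dwells.n_needles):
        tang = paths[i].tangents
        for p in dwells.positions[i]:
            dirs.append(tang[nearest_path_index(paths[i], p)])
    return np.asarray(dirs)


def accumulate_dose(
    dwells: DwellSet,
    paths: list[NeedlePath],
    source: SourceModel,
    points: np.ndarray,
    weights: np.ndarray | None = None,
    chunk: int = 8192,
) -> DoseSample:
    """Total dose at ``points`` from all dwells: Σ rate(dwell, p) · t_dwell.

    Linear in every dwell time and additive over any partition of the
    dwell set.  Uses a compiled point×dwell loop when numba is
    available (identical formulas, float64); otherwise evaluates the
    vectorized rate matrix in point chunks to bound memory.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if weights is None:
        weights = np.ones(len(points))
    pos = dwells.all_positions()
    times = dwells.all_times()
    dirs = dwell_directions(dwells, paths)
    fast = _fast_kernel()
    if fast is not None:
        dose, rate_sum = fast(
            points, pos, dirs, times,
            source.active_length / 10.0,
            source.air_kerma_strength * source.dose_rate_constant * _RATE_CONV,
            np.log(source.radial_r), source.radial_g,
            source.aniso_r, source.aniso_theta, source.aniso_f,
            source.mode == "line",
            min(source.radial_r[0], source.aniso_r[0]),
            source.radial_r[-1],
        )
        return DoseSample(points, dose, np.asarray(weights, float), rate_sum)
    dose = np.empty(len(points))
    rate_sum = np.empty(len(points))
    for start in range(0, len(points), chunk):
        sl = slice(start, start + chunk)
        rates = _rate_matrix(source, pos, dirs, points[sl])
        dose[sl] = rates @ times
        rate_sum[sl] = rates.sum(axis=1)
    return DoseSample(points, dose, np.asarray(weights, float), rate_sum)


_FAST_KERNEL = None


def _fast_kernel():
    """Compile (once) the numba point×dwell kernel; None if numba is absent."""
    global _FAST_KERNEL
    if _FAST_KERNEL is not None:
        return _FAST_KERNEL if _FAST_KERNEL is not False else None
    try:
        import numba
    except ImportError:  # pragma: no cover - numba is an optional speed-up
        _FAST_KERNEL = False
        return None

    @numba.njit(cache=True, fastmath=False)
    def kernel(points, pos, dirs, times, L, sk_lambda, log_rt, gt,
               ar, at, f, line_mode, r_min, r_max):
        P = points.shape[0]
        D = pos.shape[0]
        dose = np.zeros(P)
        rate_sum = np.zeros(P)
        g0 = 2.0 * np.arctan(L / 2.0) / L if L > 0 else 1.0
        n_g = log_rt.shape[0]
        n_ar = ar.shape[0]
        n_at = at.shape[0]
        g_slope = (gt[n_g - 1] - gt[n_g - 2]) / (log_rt[n_g - 1] - log_rt[n_g - 2])
        for p in range(P):
            px, py, pz = points[p, 0], points[p, 1], points[p, 2]
            for d in range(D):
                dx = px - pos[d, 0]
                dy = py - pos[d, 1]
                dz = pz - pos[d, 2]
                r_mm = np.sqrt(dx * dx + dy * dy + dz * dz)
                r = r_mm / 10.0
                if r < r_min:
                    r = r_min
                ct = 0.0
                if r_mm > 1e-12:
                    ct = (dx * dirs[d, 0] + dy * dirs[d, 1] + dz * dirs[d, 2]) / r_mm
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
                theta = np.degrees(np.arccos(ct))
                # geometry function ratio
                if line_mode and L > 0:
                    st = np.sqrt(max(1.0 - ct * ct, 0.0))
                    z = r * ct
                    rho = r * st
                    if rho < 1e-9:
                        geo = 1.0 / max(r * r - L * L / 4.0, 1e-12)
                    else:
                        beta = np.arctan((z + L / 2.0) / rho) - np.arctan((z - L / 2.0) / rho)
                        geo = beta / (L * rho)
                    geo /= g0
                else:
                    geo = 1.0 / (r * r)
                # radial dose function: linear in log r, log-linear extrapolation
                lr = np.log(r)
                if r >= r_max:
                    g = gt[n_g - 1] + g_slope * (lr - log_rt[n_g - 1])
                else:
                    i = np.searchsorted(log_rt, lr)
                    if i <= 0:
                        g = gt[0]
                    else:
                        frac = (lr - log_rt[i - 1]) / (log_rt[i] - log_rt[i - 1])
                        g = gt[i - 1] + frac * (gt[i] - gt[i - 1])
                # anisotropy: bilinear in (r, theta), nearest beyond the grid
                if line_mode:
                    rc = min(max(r, ar[0]), ar[n_ar - 1])
                    tc = min(max(theta, at[0]), at[n_at - 1])
                    i = np.searchsorted(ar, rc) - 1
                    if i < 0:
                        i = 0
                    elif i > n_ar - 2:
                        i = n_ar - 2
                    j = np.searchsorted(at, tc) - 1
                    if j < 0:
                        j = 0
                    elif j > n_at - 2:
                        j = n_at - 2
                    fr = (rc - ar[i]) / (ar[i + 1] - ar[i])
                    ft = (tc - at[j]) / (at[j + 1] - at[j])
                    fv = (f[i, j] * (1 - fr) * (1 - ft)
                          + f[i + 1, j] * fr * (1 - ft)
                          + f[i, j + 1] * (1 - fr) * ft
                          + f[i + 1, j + 1] * fr * ft)
                else:
                    fv = 1.0
                rate = sk_lambda * geo * g * fv
                dose[p] += rate * times[d]
                rate_sum[p] += rate
        return dose, rate_sum

    _FAST_KERNEL = kernel
    return kernel
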