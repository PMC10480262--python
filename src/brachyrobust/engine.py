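"""Scenario engine: draw, enumerate and evaluate uncertainty scenarios.

Orchestrates the robust-evaluation loop: build the uncertainty budget,
sample probabilistic scenarios (truncated-normal draws within the 90%
CI) and/or enumerate worst-case scenarios (combinations of the ±1.65 SD
limits), apply the six operators to the nominal plan, recompute dose
and DVH metrics for every scenario, and aggregate the ensemble into a
robustness summary.

Scenarios are independent; aggregation is commutative, so results do
not depend on evaluation order.  Dose is linear in dwell time, which
the worst-case loop exploits: scenarios sharing all geometry parameters
reuse the dose field and fold the time parameter analytically (falling
back to full recomputation if time clipping occurs).
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import stats as rstats
from .budget import UncertaintyBudget
from .case import CaseModel, Structure
from .dvh import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_GRID_SPACING,
    compute_dvh,
    compute_metrics,
    evaluate_constraints,
    sample_structure_points,
)
from .needles import NeedlePath, build_needle_paths
from .perturb import (
    ScenarioParams,
    apply_scenario,
    scale_prostate,
    scale_structure_slicewise,
    shift_dwells_along_needle,
    translate_needles_transverse,
)
from .tg43 import SourceModel, accumulate_dose, synthetic_ir192

log = logging.getLogger(__name__)

#: default coordinated worst-case direction modes for needle transverse moves
DEFAULT_WC_MODES = ("out", "in", "posterior")


# ---------------------------------------------------------------------------
# scenario generation
# ---------------------------------------------------------------------------


def _trunc_draw(rng, sd: float, limit_mult: float, size=None):
    """Zero-mean normal draw hard-truncated at ±limit_mult·sd."""
    if sd == 0:
        return 0.0 if size is None else np.zeros(size)
    return truncnorm.rvs(-limit_mult, limit_mult, scale=sd, size=size, random_state=rng)


def sample_probabilistic(
    budget: UncertaintyBudget,
    n_needles: int,
    seed=None,
) -> ScenarioParams:
    """Draw one probabilistic scenario from the budget's distributions.

    Every scalar comes from a zero-mean normal with the budget SD,
    truncated at ±1.65·SD (the 90% CI); needle transverse moves are
    drawn independently per needle and per axis.  ``seed`` may be an
    int or a ``numpy.random.Generator``; draws are deterministic given it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = budget.ci_multiplier
    pct = _trunc_draw(rng, budget.p5_percent_sd, m)
    p6 = np.array([_trunc_draw(rng, sd, m) for sd in budget.p6_sd])
    return ScenarioParams(
        p1_shift=float(_trunc_draw(rng, budget.p1_sd, m)),
        p2_prostate=float(_trunc_draw(rng, budget.p2_sd, m)),
        p3_urethra=float(_trunc_draw(rng, budget.p3_urethra_sd, m)),
        p3_rectum=float(_trunc_draw(rng, budget.p3_rectum_sd, m)),
        p4_transverse=np.asarray(_trunc_draw(rng, budget.p4_sd, m, size=(n_needles, 2))).reshape(n_needles, 2),
        p5_scale=1.0 + float(pct) / 100.0,
        p5_offset=float(_trunc_draw(rng, budget.p5_offset_sd_s, m)),
        p6_rigid=p6,
    )


def _needle_transverse_dirs(case: CaseModel) -> np.ndarray:
    """Unit 2D direction from the prostate transverse centre line to each needle."""
    centre = case.contours["prostate"].centroid()[:2]
    dirs = []
    for pos in case.dwells.positions:
        d = pos[:, :2].mean(axis=0) - centre
        n = np.linalg.norm(d)
        dirs.append(d / n if n > 1e-9 else np.array([1.0, 0.0]))
    return np.asarray(dirs)


def p4_mode_vectors(case: CaseModel, mode: str, magnitude: float) -> np.ndarray | None:
    """Per-needle transverse vectors for a coordinated worst-case mode.

    ``out``/``in``: all needles move radially away from / toward the
    prostate transverse centre line; ``posterior``: all needles move
    posteriorly (+y); ``none``: no movement.
    """
    n = case.dwells.n_needles
    if mode == "none" or magnitude == 0:
        return None
    if mode in ("out", "in"):
        dirs = _needle_transverse_dirs(case)
        return dirs * magnitude * (1.0 if mode == "out" else -1.0)
    if mode == "posterior":
        return np.tile([0.0, magnitude], (n, 1))
    if mode == "anterior":
        return np.tile([0.0, -magnitude], (n, 1))
    raise ValueError(f"unknown worst-case mode {mode!r}")


def enumerate_worst_case(
    budget: UncertaintyBudget,
    case: CaseModel,
    modes: tuple[str, ...] = DEFAULT_WC_MODES,
) -> list[ScenarioParams]:
    """All combinations of the 90% CI limits of the six parameters.

    Scalar parameters (p1, p2, p3-urethra, p3-rectum, p5) take levels
    {−1.65 SD, 0, +1.65 SD}; the dwell-time percentage and offset move
    jointly with the same sign.  The rigid-motion parameter takes
    one-axis-at-a-time levels (±LR, ±AP, and zero).  Needle transverse
    moves use the coordinated direction ``modes`` at the 1.65 SD
    magnitude.  Zero-SD parameters collapse to a single zero level, so
    an all-zero budget yields exactly one (nominal) scenario.  The
    emission order is deterministic, with structure-geometry parameters
    outermost and the time parameter innermost.
    """

    def levels(sd):
        lim = budget.limit(sd)
        return [-lim, 0.0, lim] if lim > 0 else [0.0]

    p5_levels = []
    for s in sorted({-1.0, 0.0, 1.0} if budget.p5_percent_sd or budget.p5_offset_sd_s else {0.0}):
        p5_levels.append(
            (1.0 + s * budget.limit(budget.p5_percent_sd) / 100.0,
             s * budget.limit(budget.p5_offset_sd_s))
        )
    p6_levels: list[np.ndarray] = [np.zeros(3)]
    for axis in range(3):
        lim = budget.limit(budget.p6_sd[axis])
        if lim > 0:
            for sgn in (-1.0, 1.0):
                v = np.zeros(3)
                v[axis] = sgn * lim
                p6_levels.append(v)
    p4_mag = budget.limit(budget.p4_sd)
    mode_list = list(dict.fromkeys(modes)) if p4_mag > 0 else ["none"]

    out = []
    for p2, p3u, p3r, p6, p1, mode, (p5s, p5o) in itertools.product(
        levels(budget.p2_sd),
        levels(budget.p3_urethra_sd),
        levels(budget.p3_rectum_sd),
        p6_levels,
        levels(budget.p1_sd),
        mode_list,
        p5_levels,
    ):
        out.append(
            ScenarioParams(
                p1_shift=p1,
                p2_prostate=p2,
                p3_urethra=p3u,
                p3_rectum=p3r,
                p4_transverse=p4_mode_vectors(case, mode, p4_mag),
                p5_scale=p5s,
                p5_offset=p5o,
                p6_rigid=p6,
            )
        )
    log.info("worst-case enumeration: %d scenarios", len(out))
    return out


# ---------------------------------------------------------------------------
# single-scenario evaluation
# ---------------------------------------------------------------------------


def _geometry_params(params: ScenarioParams) -> ScenarioParams:
    return ScenarioParams(
        p1_shift=params.p1_shift,
        p2_prostate=params.p2_prostate,
        p3_urethra=params.p3_urethra,
        p3_rectum=params.p3_rectum,
        p4_transverse=params.p4_transverse,
        p5_scale=1.0,
        p5_offset=0.0,
        p6_rigid=params.p6_rigid,
    )


class _Evaluator:
    """Shared machinery for nominal and scenario evaluation, with caches.

    Worst-case enumeration revisits the same structure geometries and
    dwell configurations many times, so dose fields are cached per
    structure keyed by exactly the parameters that affect them (the
    rectum, e.g., is untouched by the prostate-contour and rigid-motion
    parameters on the anatomy side).  Caching is enabled per call so
    probabilistic scenarios (whose continuous parameters never repeat)
    do not fill the caches.
    """

    _DOSE_CACHE_MAX = 512
    _POINT_CACHE_MAX = 256

    def __init__(self, case, paths, source, grid_spacing, bin_width, max_dose,
                 v200_waiver=False):
        self.case = case
        self.paths = paths
        self.source = source
        self.spacing = grid_spacing
        self.bin_width = bin_width
        self.max_dose = max_dose
        self.v200_waiver = v200_waiver
        self.structures = sorted({c.structure for c in case.constraints})
        self._point_cache: dict = {}
        self._dose_cache: dict = {}
        self._dwell_cache: dict = {}

    # -- keys ---------------------------------------------------------------

    @staticmethod
    def _p4_key(params):
        p4 = params.p4_transverse
        return None if p4 is None else p4.tobytes()

    def _dwell_key(self, params) -> tuple:
        return (params.p1_shift, self._p4_key(params), params.p6_rigid.tobytes())

    def _struct_key(self, name: str, params: ScenarioParams) -> tuple:
        if name == "prostate":
            return (name, params.p2_prostate, params.p6_rigid.tobytes())
        if name == "urethra":
            return (name, params.p3_urethra, params.p6_rigid.tobytes())
        return (name, params.p3_rectum)

    # -- geometry construction (operator order 1→6 preserved) ---------------

    def _transformed_dwells(self, params: ScenarioParams, cache: bool):
        key = self._dwell_key(params)
        if cache and key in self._dwell_cache:
            return self._dwell_cache[key]
        dwells = self.case.dwells
        if params.p1_shift != 0.0:
            dwells = shift_dwells_along_needle(dwells, self.paths, params.p1_shift)
        if params.p4_transverse is not None and np.any(params.p4_transverse != 0):
            dwells = translate_needles_transverse(dwells, params.p4_transverse)
        if np.any(params.p6_rigid != 0):
            out = dwells.copy()
            for i in range(out.n_needles):
                out.positions[i] = out.positions[i] + params.p6_rigid
                out.tips[i] = out.tips[i] + params.p6_rigid
            dwells = out
        if cache and len(self._dwell_cache) < self._DOSE_CACHE_MAX:
            self._dwell_cache[key] = dwells
        return dwells

    def _transformed_structure(self, name: str, params: ScenarioParams):
        s = self.case.contours[name]
        if name == "prostate" and params.p2_prostate != 0.0:
            s = scale_prostate(s, params.p2_prostate)
        elif name == "urethra" and params.p3_urethra != 0.0:
            s = scale_structure_slicewise(s, params.p3_urethra, "urethra")
        elif name == "rectum" and params.p3_rectum != 0.0:
            s = scale_structure_slicewise(s, params.p3_rectum, "rectum")
        if name in ("prostate", "urethra") and np.any(params.p6_rigid != 0):
            s = Structure([sl + params.p6_rigid for sl in s.slices], s.slice_width)
        return s

    def _sample_points(self, name, params, cache: bool):
        key = self._struct_key(name, params)
        if key in self._point_cache:
            return self._point_cache[key]
        pts = sample_structure_points(self._transformed_structure(name, params), self.spacing)
        if cache and len(self._point_cache) < self._POINT_CACHE_MAX:
            self._point_cache[key] = pts
        return pts

    def geometry_dose(self, params: ScenarioParams, cache: bool = True):
        """Per-structure dose at unperturbed times, and per-point rate sums."""
        data = {}
        dwells = None
        for name in self.structures:
            dose_key = (self._dwell_key(params), self._struct_key(name, params))
            if cache and dose_key in self._dose_cache:
                data[name] = self._dose_cache[dose_key]
                continue
            if dwells is None:
                dwells = self._transformed_dwells(params, cache)
            pts, w = self._sample_points(name, params, cache)
            sample = accumulate_dose(dwells, self.paths, self.source, pts, w)
            entry = (sample.dose, sample.rate_sum, w)
            if cache and len(self._dose_cache) < self._DOSE_CACHE_MAX:
                self._dose_cache[dose_key] = entry
            data[name] = entry
        return data

    def evaluate(self, params: ScenarioParams, cache: bool = True):
        """Metrics, pass flags and DVH curves for one scenario."""
        nominal_times = self.case.dwells.all_times()
        new_times = nominal_times * params.p5_scale + params.p5_offset
        if np.any(new_times < 0):
            # clipping breaks dose linearity in the time parameter
            geo = apply_scenario(self.case, self.paths, params)
            dose_by, w_by = {}, {}
            for name in self.structures:
                pts, w = self._sample_points(name, params, cache)
                sample = accumulate_dose(geo.dwells, self.paths, self.source, pts, w)
                dose_by[name], w_by[name] = sample.dose, w
        else:
            data = self.geometry_dose(params, cache)
            dose_by, w_by = {}, {}
            for name in self.structures:
                dose0, rate_sum, w = data[name]
                dose_by[name] = dose0 * params.p5_scale + rate_sum * params.p5_offset
                w_by[name] = w
        metrics = compute_metrics(self.case, dose_by, w_by)
        flags, n_pass = evaluate_constraints(
            metrics, self.case.constraints, self.v200_waiver
        )
        curves = {
            name: compute_dvh(dose_by[name], w_by[name], self.bin_width, self.max_dose)
            for name in self.structures
        }
        return metrics, flags, curves


def run_scenario(
    case: CaseModel,
    paths: list[NeedlePath],
    source: SourceModel,
    params: ScenarioParams,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_dose: float | None = None,
):
    """Evaluate one scenario: apply operators, compute dose, DVH and metrics.

    Returns ``(metrics, flags, curves)``; the nominal case is untouched.
    """
    if max_dose is None:
        max_dose = 4.0 * case.prescription
    ev = _Evaluator(case, paths, source, grid_spacing, bin_width, max_dose)
    return ev.evaluate(params)


# ---------------------------------------------------------------------------
# full evaluation
# ---------------------------------------------------------------------------


@dataclass
class RobustSummary:
    """Ensemble summary: the per-metric table and whole-curve measures."""

    table: pd.DataFrame                  # one row per metric
    pass_rate_all: float
    pass_rate_excl_v200: float
    sd_areas: dict[str, float]           # Gy, per structure
    n_probabilistic: int
    n_worst_case: int
    n_failed: int


@dataclass
class EvaluationResult:
    """Everything produced by :func:`run_evaluation`."""

    summary: RobustSummary
    scenario_table: pd.DataFrame
    nominal_metrics: dict[str, float]
    nominal_flags: dict[str, bool]
    dose_bins: np.ndarray
    nominal_curves: dict[str, np.ndarray]
    prob_curves: dict[str, np.ndarray]            # (n_prob, n_bins) per structure
    wc_envelope: dict[str, tuple[np.ndarray, np.ndarray]]  # (min, max) per structure
    failures: list = field(default_factory=list)
    config: dict = field(default_factory=dict)


def _params_record(kind: str, idx: int, params: ScenarioParams) -> dict:
    p4 = params.p4_transverse
    return {
        "kind": kind,
        "scenario": idx,
        "p1_shift_mm": params.p1_shift,
        "p2_prostate_mm": params.p2_prostate,
        "p3_urethra_mm": params.p3_urethra,
        "p3_rectum_mm": params.p3_rectum,
        "p4_mean_mm": 0.0 if p4 is None else float(np.linalg.norm(p4, axis=1).mean()),
        "p5_scale": params.p5_scale,
        "p5_offset_s": params.p5_offset,
        "p6_x_mm": params.p6_rigid[0],
        "p6_y_mm": params.p6_rigid[1],
        "p6_z_mm": params.p6_rigid[2],
    }


def run_evaluation(
    case: CaseModel,
    source: SourceModel | None = None,
    n_probabilistic: int = 1000,
    seed: int | None = None,
    worst_case: bool = True,
    budget: UncertaintyBudget | None = None,
    wc_modes: tuple[str, ...] = DEFAULT_WC_MODES,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    bin_width: float = DEFAULT_BIN_WIDTH,
    v200_waiver: bool = False,
    progress: bool = False,
) -> EvaluationResult:
    """Full robust evaluation of a case.

    Runs ``n_probabilistic`` sampled scenarios (each drawn from a
    substream derived deterministically from ``(seed, scenario index)``)
    and, when ``worst_case`` is set, the enumerated worst-case set.
    Scenarios that raise are recorded in ``failures`` and excluded from
    the summary.  The whole run is bit-for-bit reproducible in metric
    values for a given seed.
    """
    if n_probabilistic < 1:
        raise ValueError("n_probabilistic must be ≥ 1")
    case.validate()
    source = source or synthetic_ir192()
    budget = budget or UncertaintyBudget()
    budget.validate()
    paths = build_needle_paths(case.dwells)
    max_dose = 4.0 * case.prescription
    ev = _Evaluator(case, paths, source, grid_spacing, bin_width, max_dose, v200_waiver)

    nominal_metrics, nominal_flags, nominal_curves = ev.evaluate(ScenarioParams())
    dose_bins = next(iter(nominal_curves.values())).dose_bins

    scenarios: list[tuple[str, int, ScenarioParams]] = []
    if worst_case:
        for i, p in enumerate(enumerate_worst_case(budget, case, wc_modes)):
            scenarios.append(("worst_case", i, p))
    n_needles = case.dwells.n_needles
    for i in range(n_probabilistic):
        rng = np.random.default_rng([0 if seed is None else seed, i])
        scenarios.append(("probabilistic", i, sample_probabilistic(budget, n_needles, rng)))

    structures = ev.structures
    records, metric_rows, failures = [], [], []
    prob_curves = {s: [] for s in structures}
    wc_min = {s: None for s in structures}
    wc_max = {s: None for s in structures}
    wc_metrics: dict[str, list] = {}
    t_start = time.perf_counter()
    for kind, idx, params in scenarios:
        t0 = time.perf_counter()
        try:
            metrics, flags, curves = ev.evaluate(params, cache=(kind == "worst_case"))
        except Exception as exc:  # noqa: BLE001 — partial failures are data
            failures.append({"kind": kind, "scenario": idx, "error": str(exc)})
            log.warning("scenario %s/%d failed: %s", kind, idx, exc)
            continue
        rec = _params_record(kind, idx, params)
        rec.update(metrics)
        rec.update({f"pass_{k}": v for k, v in flags.items()})
        rec["n_pass"] = sum(flags.values())
        rec["all_pass"] = all(flags.values())
        rec["elapsed_s"] = time.perf_counter() - t0
        records.append(rec)
        if kind == "probabilistic":
            metric_rows.append(metrics)
            for s in structures:
                prob_curves[s].append(curves[s].rel_volume.astype(np.float32))
        else:
            for name, v in metrics.items():
                wc_metrics.setdefault(name, []).append(v)
            for s in structures:
                rv = curves[s].rel_volume
                wc_min[s] = rv.copy() if wc_min[s] is None else np.minimum(wc_min[s], rv)
                wc_max[s] = rv.copy() if wc_max[s] is None else np.maximum(wc_max[s], rv)
        if progress and (len(records) % 100 == 0):
            log.info("evaluated %d/%d scenarios (%.1f s)",
                     len(records), len(scenarios), time.perf_counter() - t_start)

    table = pd.DataFrame(records)
    prob_df = pd.DataFrame(metric_rows)
    n_wc = sum(1 for k, _, _ in scenarios if k == "worst_case")
    rows = []
    prob_flags = table[table["kind"] == "probabilistic"]
    for c in case.constraints:
        name = c.name
        vals = prob_df[name].to_numpy()
        mean, lo, hi = rstats.mean_ci_sem(vals)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        n_pass = int(prob_flags[f"pass_{name}"].sum())
        rows.append({
            "metric": name,
            "structure": c.structure,
            "limit": c.limit,
            "direction": c.direction,
            "nominal": nominal_metrics[name],
            "mean": mean, "sd": float(vals.std(ddof=1)),
            "q1": q1, "median": med, "q3": q3,
            "ci_low": lo, "ci_high": hi,
            "wc_min": min(wc_metrics[name]) if wc_metrics else np.nan,
            "wc_max": max(wc_metrics[name]) if wc_metrics else np.nan,
            "n_pass": n_pass,
            "pass_rate": n_pass / max(len(prob_flags), 1),
        })
    flag_dicts = [
        {c.name: row[f"pass_{c.name}"] for c in case.constraints}
        for _, row in prob_flags.iterrows()
    ]
    rates = rstats.pass_rates(flag_dicts)
    prob_curve_arrays = {s: np.asarray(v) for s, v in prob_curves.items()}
    sd_areas = {
        s: rstats.sd_area(prob_curve_arrays[s], bin_width)
        for s in structures
        if len(prob_curve_arrays[s]) >= 2
    }
    summary = RobustSummary(
        table=pd.DataFrame(rows),
        pass_rate_all=rates["all"],
        pass_rate_excl_v200=rates["all_excluding"],
        sd_areas=sd_areas,
        n_probabilistic=len(prob_df),
        n_worst_case=n_wc - sum(1 for f in failures if f["kind"] == "worst_case"),
        n_failed=len(failures),
    )
    return EvaluationResult(
        summary=summary,
        scenario_table=table,
        nominal_metrics=nominal_metrics,
        nominal_flags=nominal_flags,
        dose_bins=dose_bins,
        nominal_curves={s: nominal_curves[s].rel_volume for s in structures},
        prob_curves=prob_curve_arrays,
        wc_envelope={
            s: (wc_min[s], wc_max[s]) for s in structures if wc_min[s] is not None
        },
        failures=failures,
        config={
            "n_probabilistic": n_probabilistic,
            "seed": seed,
            "worst_case": worst_case,
            "n_worst_case": n_wc,
            "wc_modes": list(wc_modes),
            "grid_spacing_mm": grid_spacing,
            "bin_width_gy": bin_width,
            "v200_waiver": v200_waiver,
        },
    )
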