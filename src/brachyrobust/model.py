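"""Model/Results interface to the robust evaluation.

`RobustEvaluation` wraps a nominal case (plus source model, uncertainty
budget and evaluation settings) the way a statistical model wraps data;
``fit()`` runs the scenario ensemble and returns a
`RobustEvaluationResults` carrying the per-metric estimates, their
dispersion and confidence intervals, worst-case extrema, pass rates and
whole-curve robustness areas, with ``summary()`` producing the report
table and plotting methods hanging off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .budget import UncertaintyBudget
from .case import CaseModel
from .dvh import DEFAULT_BIN_WIDTH, DEFAULT_GRID_SPACING
from .engine import DEFAULT_WC_MODES, EvaluationResult, run_evaluation
from .io import load_case
from .stats import bootstrap_percentile_ci, one_tail_t, skewness_fp
from .tg43 import SourceModel, synthetic_ir192


class RobustEvaluation:
    """Robust-evaluation model for a nominal HDR brachytherapy plan.

    Parameters
    ----------
    case : CaseModel
        The nominal plan (dwells, contours, prescription, constraints).
    source : SourceModel, optional
        TG-43 source; defaults to the synthetic generic Ir-192 source.
    budget : UncertaintyBudget, optional
        Per-parameter standard deviations; defaults to the published
        TRUS live-planning budget.
    grid_spacing, bin_width : float
        Dose-point grid spacing (mm) and DVH bin width (Gy).
    """

    def __init__(
        self,
        case: CaseModel,
        source: SourceModel | None = None,
        budget: UncertaintyBudget | None = None,
        grid_spacing: float = DEFAULT_GRID_SPACING,
        bin_width: float = DEFAULT_BIN_WIDTH,
        v200_waiver: bool = False,
    ):
        case.validate()
        self.case = case
        self.source = source or synthetic_ir192()
        self.budget = budget or UncertaintyBudget()
        self.grid_spacing = grid_spacing
        self.bin_width = bin_width
        self.v200_waiver = v200_waiver

    @classmethod
    def from_files(cls, plan_path, struct_path, **kwargs) -> "RobustEvaluation":
        """Build the model from DICOM-RT or fixture-dialect files."""
        return cls(load_case(plan_path, struct_path), **kwargs)

    def fit(
        self,
        n_scenarios: int = 1000,
        seed: int | None = None,
        worst_case: bool = True,
        wc_modes: tuple[str, ...] = DEFAULT_WC_MODES,
        progress: bool = False,
    ) -> "RobustEvaluationResults":
        """Run the scenario ensemble and return the results object."""
        raw = run_evaluation(
            self.case,
            source=self.source,
            n_probabilistic=n_scenarios,
            seed=seed,
            worst_case=worst_case,
            budget=self.budget,
            wc_modes=wc_modes,
            grid_spacing=self.grid_spacing,
            bin_width=self.bin_width,
            v200_waiver=self.v200_waiver,
            progress=progress,
        )
        return RobustEvaluationResults(self, raw)


class RobustEvaluationResults:
    """Results of a robust evaluation run."""

    def __init__(self, model: RobustEvaluation, raw: EvaluationResult):
        self.model = model
        self.raw = raw
        self.summary_table: pd.DataFrame = raw.summary.table
        self.scenario_table: pd.DataFrame = raw.scenario_table
        self.nominal_metrics = raw.nominal_metrics
        self.pass_rate_all = raw.summary.pass_rate_all
        self.pass_rate_excl_v200 = raw.summary.pass_rate_excl_v200
        self.sd_areas = raw.summary.sd_areas
        self.config = raw.config

    # -- statistics ---------------------------------------------------------

    def metric_values(self, name: str) -> np.ndarray:
        """Probabilistic ensemble values of one metric."""
        t = self.scenario_table
        return t.loc[t["kind"] == "probabilistic", name].to_numpy()

    def skewness(self, name: str, adjusted: bool = False) -> float:
        return skewness_fp(self.metric_values(name), adjusted=adjusted)

    def median_ci(self, name: str, n_boot: int = 1000, seed: int | None = 0):
        """Bootstrap percentile CI of the median — for skewed metrics."""
        return bootstrap_percentile_ci(
            self.metric_values(name), n_boot=n_boot, seed=seed
        )

    def t_test(self, name: str, direction: str | None = None):
        """One-tailed t-test of a metric's ensemble mean against its limit."""
        row = self.summary_table.set_index("metric").loc[name]
        if direction is None:
            direction = "greater" if row["direction"] == "ge" else "less"
        return one_tail_t(self.metric_values(name), row["limit"], direction)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Human-readable summary table (doses 2 dp, volumes 1 dp)."""
        rows = []
        for _, r in self.summary_table.iterrows():
            dp = 2 if "D" in r["metric"].split("_")[1][:1] else 1
            fmt = f"{{:.{dp}f}}"
            lim = f"{'≥' if r['direction'] == 'ge' else '≤'} {r['limit']:g}"
            rows.append({
                "metric": r["metric"],
                "constraint": lim,
                "nominal": fmt.format(r["nominal"]),
                "mean ± SD": f"{fmt.format(r['mean'])} ± {fmt.format(r['sd'])}",
                "95% CI": f"[{fmt.format(r['ci_low'])}, {fmt.format(r['ci_high'])}]",
                "worst case": (
                    fmt.format(r["wc_min"] if r["direction"] == "ge" else r["wc_max"])
                    if np.isfinite(r["wc_min"]) else "—"
                ),
                "passed": f"{r['n_pass']} ({100 * r['pass_rate']:.1f}%)",
            })
        s = self.raw.summary
        lines = [
            "Robust evaluation summary",
            "=" * 25,
            pd.DataFrame(rows).to_string(index=False),
            "",
            f"probabilistic scenarios: {s.n_probabilistic}   "
            f"worst-case scenarios: {s.n_worst_case}   failed: {s.n_failed}",
            f"pass rate (all constraints): {100 * s.pass_rate_all:.1f}%   "
            f"excluding V200: {100 * s.pass_rate_excl_v200:.1f}%",
            "SD-per-dose area (Gy): "
            + "  ".join(f"{k}: {v:.2f}" for k, v in s.sd_areas.items()),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<RobustEvaluationResults: {self.raw.summary.n_probabilistic} probabilistic, "
            f"{self.raw.summary.n_worst_case} worst-case scenarios>"
        )

    # -- plots --------------------------------------------------------------

    def plot_dvh_bands(self, ax=None):
        """Nominal DVH, probabilistic band and worst-case envelope per structure."""
        import matplotlib.pyplot as plt

        raw = self.raw
        structures = list(raw.nominal_curves)
        if ax is None:
            _, ax = plt.subplots(1, len(structures), figsize=(4 * len(structures), 3.2))
        axes = np.atleast_1d(ax)
        for a, s in zip(axes, structures):
            x = raw.dose_bins
            pc = raw.prob_curves.get(s)
            if pc is not None and len(pc):
                a.fill_between(x, 100 * pc.min(axis=0), 100 * pc.max(axis=0),
                               color="lightgreen", alpha=0.7, label="probabilistic")
            if s in raw.wc_envelope:
                lo, hi = raw.wc_envelope[s]
                a.plot(x, 100 * lo, color="darkgreen", lw=0.8, label="worst case")
                a.plot(x, 100 * hi, color="darkgreen", lw=0.8)
            a.plot(x, 100 * raw.nominal_curves[s], "k-", lw=1.2, label="nominal")
            a.set_title(s)
            a.set_xlabel("dose (Gy)")
            a.set_ylabel("relative volume (%)")
            a.set_xlim(0, x[-1])
            a.legend(fontsize=7)
        return axes

    def plot_metric_distributions(self, ax=None):
        """Strip + box plot of each metric's probabilistic distribution."""
        import matplotlib.pyplot as plt

        names = list(self.summary_table["metric"])
        if ax is None:
            _, ax = plt.subplots(2, 4, figsize=(14, 6))
        axes = np.ravel(ax)
        rng = np.random.default_rng(0)
        for a, name in zip(axes, names):
            vals = self.metric_values(name)
            a.boxplot(vals, widths=0.4)
            a.plot(1 + rng.uniform(-0.12, 0.12, len(vals)), vals,
                   ".", ms=2, alpha=0.4)
            row = self.summary_table.set_index("metric").loc[name]
            a.axhline(row["limit"], color="r", ls=":", lw=1)
            a.set_title(name, fontsize=8)
            a.set_xticks([])
        return axes

    def plot_sd_per_dose(self, ax=None):
        """Across-scenario SD of relative volume per dose, with areas."""
        import matplotlib.pyplot as plt

        from .stats import sd_per_dose

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        for s, curves in self.raw.prob_curves.items():
            if len(curves) < 2:
                continue
            sd = sd_per_dose(curves)
            ax.fill_between(self.raw.dose_bins, sd, alpha=0.4,
                            label=f"{s} ({self.sd_areas[s]:.2f} Gy)")
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("SD of relative volume")
        ax.legend()
        return ax

    def save(self, out_dir) -> dict:
        """Write the full report (CSVs, plots, manifest) to a directory."""
        from .report import report

        return report(self, out_dir)
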