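"""Human-readable reporting: summary CSVs, DVH plots and a run manifest.

Every artifact is regenerable from the per-scenario table plus the
stored curves — computation and rendering are kept separate so reports
can be re-rendered without re-running scenarios.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def _write_band_csv(results, out_dir: Path) -> Path:
    """DVH band data: nominal curve, probabilistic band and worst-case
    envelope per structure, as (dose, relative-volume) columns."""
    import pandas as pd

    raw = results.raw
    frames = []
    for s, nominal in raw.nominal_curves.items():
        d = {"structure": s, "dose_gy": raw.dose_bins, "nominal": nominal}
        pc = raw.prob_curves.get(s)
        if pc is not None and len(pc) >= 1:
            d["prob_min"] = pc.min(axis=0)
            d["prob_max"] = pc.max(axis=0)
        if s in raw.wc_envelope:
            lo, hi = raw.wc_envelope[s]
            d["wc_min"], d["wc_max"] = lo, hi
        frames.append(pd.DataFrame(d))
    path = out_dir / "dvh_bands.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def _write_sd_csv(results, out_dir: Path) -> Path:
    """Across-scenario SD of relative volume per dose bin, per structure."""
    import pandas as pd

    from .stats import sd_per_dose

    raw = results.raw
    frames = []
    for s, curves in raw.prob_curves.items():
        if len(curves) < 2:
            continue
        frames.append(pd.DataFrame({
            "structure": s, "dose_gy": raw.dose_bins, "sd": sd_per_dose(curves),
        }))
    path = out_dir / "sd_per_dose.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def render_from_band_csv(band_csv, out_dir: Path) -> Path:
    """Re-render the DVH band plot from stored band data alone."""
    import pandas as pd

    df = pd.read_csv(band_csv)
    structures = list(dict.fromkeys(df["structure"]))
    fig, axes = plt.subplots(1, len(structures), figsize=(4 * len(structures), 3.2))
    import numpy as np

    for a, s in zip(np.atleast_1d(axes), structures):
        d = df[df["structure"] == s]
        x = d["dose_gy"]
        if "prob_min" in d:
            a.fill_between(x, 100 * d["prob_min"], 100 * d["prob_max"],
                           color="lightgreen", alpha=0.7, label="probabilistic")
        if "wc_min" in d and d["wc_min"].notna().any():
            a.plot(x, 100 * d["wc_min"], color="darkgreen", lw=0.8, label="worst case")
            a.plot(x, 100 * d["wc_max"], color="darkgreen", lw=0.8)
        a.plot(x, 100 * d["nominal"], "k-", lw=1.2, label="nominal")
        a.set_title(s)
        a.set_xlabel("dose (Gy)")
        a.set_ylabel("relative volume (%)")
        a.legend(fontsize=7)
    fig.tight_layout()
    out = Path(out_dir) / "dvh_bands.png"
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out


def report(results, out_dir) -> dict:
    """Write all report artifacts for a fitted evaluation; returns the paths.

    Artifacts: ``summary.csv`` (per-metric summary table),
    ``scenario_metrics.csv`` (one row per scenario), ``dvh_bands.png``,
    ``metric_distributions.png``, ``sd_per_dose.png`` and
    ``manifest.json`` (configuration, seed, versions, pass rates).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create report directory {out_dir}: {exc}") from exc
    paths = {}

    summary_csv = out_dir / "summary.csv"
    results.summary_table.to_csv(summary_csv, index=False)
    paths["summary"] = summary_csv

    scen_csv = out_dir / "scenario_metrics.csv"
    results.scenario_table.to_csv(scen_csv, index=False)
    paths["scenarios"] = scen_csv

    paths["dvh_bands_csv"] = _write_band_csv(results, out_dir)
    paths["sd_per_dose_csv"] = _write_sd_csv(results, out_dir)

    axes = results.plot_dvh_bands()
    fig = axes[0].figure
    fig.tight_layout()
    fig.savefig(out_dir / "dvh_bands.png", dpi=110)
    plt.close(fig)
    paths["dvh_bands"] = out_dir / "dvh_bands.png"

    axes = results.plot_metric_distributions()
    fig = axes[0].figure
    fig.tight_layout()
    fig.savefig(out_dir / "metric_distributions.png", dpi=110)
    plt.close(fig)
    paths["metric_distributions"] = out_dir / "metric_distributions.png"

    ax = results.plot_sd_per_dose()
    fig = ax.figure
    fig.tight_layout()
    fig.savefig(out_dir / "sd_per_dose.png", dpi=110)
    plt.close(fig)
    paths["sd_per_dose"] = out_dir / "sd_per_dose.png"

    import brachyrobust

    manifest = {
        "config": results.config,
        "pass_rate_all": results.pass_rate_all,
        "pass_rate_excl_v200": results.pass_rate_excl_v200,
        "sd_areas_gy": results.sd_areas,
        "n_failed": results.raw.summary.n_failed,
        "versions": {
            "brachyrobust": brachyrobust.__version__,
            "python": platform.python_version(),
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = manifest_path
    return paths
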