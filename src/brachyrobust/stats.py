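"""Statistical summaries of scenario ensembles.

SEM-based normal confidence intervals for metric means, one-sided
normal tail probabilities, Fisher–Pearson skewness, bootstrap
percentile intervals for the median of skewed metrics, one-sample
one-tailed t-tests against constraint values, constraint pass rates,
and the SD-per-dose area — the integral over dose of the
across-scenario standard deviation of relative volume, a whole-curve
robustness measure (in Gy since relative volume is dimensionless).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def mean_ci_sem(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and normal CI from the standard error of the mean.

    Uses the normal quantile (z = 1.96 at 95%) rather than a t-quantile;
    at ensemble sizes of hundreds to thousands the difference is
    negligible and the printed intervals of the reference workflow use z.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a CI")
    z = sps.norm.ppf(0.5 + level / 2.0)
    m = float(values.mean())
    half = z * values.std(ddof=1) / np.sqrt(values.size)
    return m, m - half, m + half


def sem_ci_from_moments(
    mean: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Normal SEM confidence interval from reported mean, SD and n.

    Reconstructs mean ± z·SD/√n for published summary statistics where
    the raw ensemble is unavailable.
    """
    if n < 2:
        raise ValueError("need n ≥ 2")
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * sd / np.sqrt(n)
    return mean - half, mean + half


def tail_probability(z_limit: float) -> float:
    """One-sided standard-normal upper-tail probability beyond ``z_limit`` SD."""
    if z_limit < 0:
        raise ValueError("z_limit must be ≥ 0")
    return float(sps.norm.sf(z_limit))


def skewness_fp(values, adjusted: bool = False) -> float:
    """Fisher–Pearson coefficient of skewness (g₁; G₁ when ``adjusted``)."""
    values = np.asarray(values, float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(values) == 0:
        raise ValueError("zero variance")
    return float(sps.skew(values, bias=not adjusted))


def bootstrap_percentile_ci(
    values,
    statistic=np.median,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bootstrap percentile CI of a statistic (default: the median).

    ``n_boot`` resamples of size n; interval endpoints are the
    (1±level)/2 percentiles of the bootstrap distribution.  Seeded and
    fully deterministic for a given seed.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 100:
        raise ValueError("n_boot must be ≥ 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = statistic(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def one_tail_t(values, mu0: float, direction: str = "greater") -> tuple[float, float]:
    """One-sample one-tailed t-test of the ensemble mean against ``mu0``.

    ``direction="greater"`` tests H₁: mean > mu0; ``"less"`` the reverse.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(values) == 0:
        raise ValueError("zero variance")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    res = sps.ttest_1samp(values, mu0, alternative=direction)
    return float(res.statistic), float(res.pvalue)


def sd_area(curves: np.ndarray, bin_width: float) -> float:
    """Area under the per-dose-bin SD of relative volume across scenarios (Gy).

    ``curves`` is an (n_scenarios, n_bins) array on a common dose grid.
    Invariant under permutation of the ensemble.
    """
    curves = np.asarray(curves, float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need ≥ 2 curves on a common dose grid")
    sd = curves.std(axis=0, ddof=1)
    return float(sd.sum() * bin_width)


def sd_per_dose(curves: np.ndarray) -> np.ndarray:
    """Per-bin SD of relative volume across the scenario ensemble."""
    curves = np.asarray(curves, float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need ≥ 2 curves on a common dose grid")
    return curves.std(axis=0, ddof=1)


def pass_rates(flag_table, exclude: str | None = "prostate_V200") -> dict:
    """Per-constraint and overall pass fractions from a scenario flag table.

    ``flag_table`` is a sequence of ``{metric_name: bool}`` dicts (one
    per scenario).  Returns per-constraint rates, the all-constraints
    rate, and the rate with ``exclude`` (default prostate V200) left out.
    """
    flag_table = list(flag_table)
    if not flag_table:
        raise ValueError("need at least one scenario")
    names = list(flag_table[0])
    arr = np.array([[f[n] for n in names] for f in flag_table], dtype=bool)
    per = {n: float(arr[:, j].mean()) for j, n in enumerate(names)}
    overall = float(arr.all(axis=1).mean())
    if exclude is not None and exclude in names:
        keep = [j for j, n in enumerate(names) if n != exclude]
        excl = float(arr[:, keep].all(axis=1).mean())
    else:
        excl = overall
    return {"per_constraint": per, "all": overall, "all_excluding": excl}
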