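"""The uncertainty budget: six per-parameter standard deviations.

Literature uncertainty components are combined in quadrature into six
variable parameters (the program inputs), each treated as a zero-mean
normal distribution sampled within its 90% confidence interval
(±1.65 SD).  Defaults reproduce the published budget for live
TRUS-planned single-fraction HDR prostate brachytherapy; every value is
user-configurable because clinic-specific budgets differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def combine_quadrature(components) -> float:
    """Root-sum-of-squares of uncertainty components (rounded only on display)."""
    components = np.asarray(list(components), float)
    if components.size == 0:
        raise ValueError("no components to combine")
    if np.any(components < 0):
        raise ValueError("components must be ≥ 0")
    return float(np.sqrt(np.sum(components**2)))


@dataclass
class UncertaintyBudget:
    """Standard deviations driving the six variable parameters.

    * p1 — dwell shift along the needle (SI), mm: needle-tip
      reconstruction, rigid SI needle motion, source positioning.
    * p2 — prostate boundary expansion from its centre, mm.
    * p3 — urethra / rectum slice-wise boundary change, mm.  The
      published urethra value is quoted as a *diameter*; with
      ``urethra_value_is_diameter`` the radial SD is half of it.
    * p4 — per-needle transverse movement, mm per axis: transverse
      reconstruction and rigid components.
    * p5 — dwell-time percentage change (%, dosimetric components) and
      constant offset (s, dwell-time precision).
    * p6 — prostate rigid movement SD per axis (LR, AP, SI), mm.

    ``ci_multiplier`` (1.65) maps an SD to its 90% CI limit, used both
    for truncating probabilistic draws and for worst-case levels.
    """

    p1_components_mm: tuple[float, ...] = (1.1, 0.34, 1.0)
    p2_sd_mm: float = 2.0
    p3_urethra_value_mm: float = 0.5
    urethra_value_is_diameter: bool = True
    p3_rectum_sd_mm: float = 1.0
    p4_components_mm: tuple[float, ...] = (1.2, 0.86)
    p5_percent_components: tuple[float, ...] = (1.0, 3.0, 3.0)
    p5_offset_sd_s: float = 0.06
    p6_sd_mm: tuple[float, float, float] = (0.1, 0.5, 0.0)  # (LR, AP, SI)
    ci_multiplier: float = 1.65

    @property
    def p1_sd(self) -> float:
        return combine_quadrature(self.p1_components_mm)

    @property
    def p2_sd(self) -> float:
        return self.p2_sd_mm

    @property
    def p3_urethra_sd(self) -> float:
        v = self.p3_urethra_value_mm
        return v / 2.0 if self.urethra_value_is_diameter else v

    @property
    def p3_rectum_sd(self) -> float:
        return self.p3_rectum_sd_mm

    @property
    def p4_sd(self) -> float:
        return combine_quadrature(self.p4_components_mm)

    @property
    def p5_percent_sd(self) -> float:
        return combine_quadrature(self.p5_percent_components)

    @property
    def p6_sd(self) -> np.ndarray:
        return np.asarray(self.p6_sd_mm, float)

    def limit(self, sd: float) -> float:
        """90% CI limit (±) for a given SD."""
        return self.ci_multiplier * sd

    def validate(self) -> None:
        sds = [self.p1_sd, self.p2_sd, self.p3_urethra_sd, self.p3_rectum_sd,
               self.p4_sd, self.p5_percent_sd, self.p5_offset_sd_s, *self.p6_sd]
        if any(s < 0 for s in sds):
            raise ValueError("all standard deviations must be ≥ 0")
        if self.ci_multiplier <= 0:
            raise ValueError("ci_multiplier must be > 0")
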