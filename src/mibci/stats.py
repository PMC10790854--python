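"""Paired condition comparison with a normality gate.

The comparison logic is: Shapiro-Wilk on the paired differences; if normality
is not rejected at alpha, a paired-sample t-test; otherwise a Wilcoxon
signed-rank test. Results carry everything needed for an "M +/- SD, p" report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TestReport:
    """Outcome of a paired comparison."""

    route: str  # "paired-t", "wilcoxon", or "degenerate"
    statistic: float | None
    p_value: float | None
    shapiro_p: float | None
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    n: int
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "route": self.route,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "shapiro_p": self.shapiro_p,
            "mean_x": self.mean_x, "sd_x": self.sd_x,
            "mean_y": self.mean_y, "sd_y": self.sd_y,
            "n": self.n, "alpha": self.alpha,
        }

    def sentence(self) -> str:
        """Human-readable 'M +/- SD, p' summary."""
        if self.route == "degenerate":
            return (f"x (M={self.mean_x:.2f}, SD={self.sd_x:.2f}) and "
                    f"y are identical in all pairs; no test performed")
        test = "paired t-test" if self.route == "paired-t" else "Wilcoxon signed-rank"
        return (f"x: M={self.mean_x:.2f}, SD={self.sd_x:.2f}; "
                f"y: M={self.mean_y:.2f}, SD={self.sd_y:.2f}; "
                f"{test}: statistic={self.statistic:.3f}, p={self.p_value:.4f}")


def compare_paired(x, y, alpha: float = 0.05, force_route: str | None = None
                   ) -> TestReport:
    """Paired two-sided comparison with Shapiro-Wilk routing.

    ``force_route`` overrides the automatic choice ("paired-t" or "wilcoxon"),
    e.g. to check routing consistency. The Wilcoxon test is exact for
    n <= 25 and uses the normal approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    base = {
        "mean_x": float(x.mean()), "sd_x": float(x.std(ddof=1)),
        "mean_y": float(y.mean()), "sd_y": float(y.std(ddof=1)),
        "n": n, "alpha": alpha,
    }
    if np.all(diff == 0):
        return TestReport(route="degenerate", statistic=None, p_value=None,
                          shapiro_p=None, **base)
    sw_stat, sw_p = stats.shapiro(diff)
    if force_route is not None:
        route = force_route
        if route not in ("paired-t", "wilcoxon"):
            raise ValueError("force_route must be 'paired-t' or 'wilcoxon'")
    else:
        route = "paired-t" if sw_p >= alpha else "wilcoxon"
    if route == "paired-t":
        res = stats.ttest_rel(x, y)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        method = "exact" if n <= 25 else "approx"
        res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    return TestReport(route=route, statistic=stat, p_value=p,
                      shapiro_p=float(sw_p), **base)
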