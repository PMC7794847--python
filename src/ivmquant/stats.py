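"""Group comparison layer.

Four comparison tools mirror how calibrated uptake data are analyzed:

* **pooled-pixel PDFs** — normalized histograms of calibrated pixel
  intensities pooled across all animals in a group, for distribution-level
  comparison that inter-tumor heterogeneity cannot mask;
* **two-sample Kolmogorov–Smirnov tests** on pooled raw pixels (pixel
  intensities are non-normal, so a distribution-free test is used);
* **Wilcoxon signed-rank** for paired longitudinal designs (same animal on
  day 0 and day 4) and **Wilcoxon rank-sum** with Bonferroni correction for
  unpaired multi-group designs;
* **two-way ANOVA** (group x time) on kinetic curves.

A caveat the outputs carry: pixels within one image are spatially
correlated, so pooled-pixel tests overstate the effective sample size;
``n_per_group`` reports raw pixel counts so readers can judge.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError
from .kinetics import KineticCurve

__all__ = [
    "PixelPDF",
    "TestResult",
    "pixel_pdf",
    "ks_compare",
    "paired_group_test",
    "unpaired_group_tests",
    "curve_anova",
]


@dataclasses.dataclass
class PixelPDF:
    """Unit-integral histogram of pooled pixel intensities for one group."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_pixels: int
    group: str = ""
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise ValidationError("bin_edges must be strictly increasing")
        integral = float((self.density * widths).sum())
        if abs(integral - 1.0) > 1e-9:
            raise ValidationError(f"density must integrate to 1, got {integral}")

    @property
    def median(self) -> float:
        """Median of the binned distribution (linear within the median bin)."""
        widths = np.diff(self.bin_edges)
        cdf = np.concatenate([[0.0], np.cumsum(self.density * widths)])
        i = int(np.searchsorted(cdf, 0.5))
        lo = self.bin_edges[i - 1]
        mass = self.density[i - 1] * widths[i - 1]
        if mass == 0:
            return float(lo)
        return float(lo + widths[i - 1] * (0.5 - cdf[i - 1]) / mass)


@dataclasses.dataclass
class TestResult:
    """A single hypothesis test outcome."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    p_adjusted: float | None = None
    direction: str = ""
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value out of [0, 1]: {self.p_value}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value:
            raise ValidationError("p_adjusted must be >= p_value")


def pixel_pdf(
    images: Sequence[np.ndarray],
    bins: int | np.ndarray = 100,
    group: str = "",
    sources: Sequence[str] = (),
    clip_negative: bool = True,
) -> PixelPDF:
    """Pool all pixels of a group's images into a unit-integral histogram.

    ``bins`` may be a count (edges span the pooled 0.1–99.9 percentile
    range) or explicit edges — pass shared edges when comparing groups.
    Negative calibrated pixels are clipped to 0 for display-style PDFs
    (``clip_negative=False`` keeps them).
    """
    if len(images) == 0:
        raise ValidationError("no images to pool")
    pooled = np.concatenate([np.asarray(im, dtype=float).ravel() for im in images])
    if pooled.size == 0:
        raise ValidationError("empty pixel pool")
    if clip_negative:
        pooled = np.clip(pooled, 0.0, None)
    if np.isscalar(bins):
        lo, hi = np.percentile(pooled, [0.1, 99.9])
        if hi <= lo:
            hi = lo + 1.0  # degenerate (constant) pool
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    if pooled.size < len(edges) - 1:
        raise ValidationError("pooled pixel count smaller than bin count")
    density, edges = np.histogram(pooled, bins=edges, density=True)
    return PixelPDF(
        bin_edges=edges,
        density=density,
        n_pixels=int(pooled.size),
        group=group,
        sources=tuple(sources),
    )


def _direction(a: np.ndarray, b: np.ndarray) -> str:
    """Shift descriptor for sample b relative to sample a, by medians."""
    ma, mb = np.median(a), np.median(b)
    if mb < ma:
        return "left-shifted"
    if mb > ma:
        return "right-shifted"
    return "none"


def ks_compare(pixels_a: np.ndarray, pixels_b: np.ndarray) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test on pooled raw pixel values.

    D is the supremum ECDF difference; the p-value is asymptotic (pixel
    pools are large). ``direction`` describes sample b relative to a.
    """
    a = np.asarray(pixels_a, dtype=float).ravel()
    b = np.asarray(pixels_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("KS test requires two nonempty samples")
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return TestResult(
        test_name="ks_2samp",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_per_group=(a.size, b.size),
        direction=_direction(a, b),
    )


def paired_group_test(
    values_day0: Sequence[float], values_day4: Sequence[float]
) -> TestResult:
    """Wilcoxon signed-rank test on paired per-animal values.

    Zero differences are dropped (Wilcoxon's rule); the exact two-sided
    null distribution is used for n <= 25 (normal approximation above).
    All-zero differences yield a degenerate result with p = 1 and
    direction "degenerate".
    """
    d0 = np.asarray(values_day0, dtype=float)
    d4 = np.asarray(values_day4, dtype=float)
    if d0.shape != d4.shape:
        raise ValidationError("paired samples must have equal length")
    if d0.size < 2:
        raise ValidationError("need n >= 2 pairs")
    diffs = d4 - d0
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return TestResult(
            test_name="wilcoxon_signed_rank",
            statistic=0.0,
            p_value=1.0,
            n_per_group=(d0.size, d4.size),
            direction="degenerate",
        )
    method = "exact" if nonzero.size <= 25 else "approx"
    res = scipy.stats.wilcoxon(
        d0, d4, zero_method="wilcox", alternative="two-sided", method=method
    )
    return TestResult(
        test_name="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(d0.size, d4.size),
        direction="decrease" if np.median(diffs) < 0 else "increase",
    )


def unpaired_group_tests(
    groups: Mapping[str, Sequence[float]],
    correction: str = "bonferroni",
) -> list[TestResult]:
    """All pairwise Wilcoxon rank-sum tests with Bonferroni correction.

    ``p_adjusted = min(1, p * n_comparisons)``. Exact null distribution
    when both groups have n <= 8 and no cross-group ties.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 values")
    if correction not in ("bonferroni", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    pairs = list(itertools.combinations(sorted(groups), 2))
    m = len(pairs)
    results = []
    for la, lb in pairs:
        a = np.asarray(groups[la], dtype=float)
        b = np.asarray(groups[lb], dtype=float)
        small = a.size <= 8 and b.size <= 8
        no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
        method = "exact" if small and no_ties else "asymptotic"
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        p = float(res.pvalue)
        results.append(
            TestResult(
                test_name="wilcoxon_rank_sum",
                statistic=float(res.statistic),
                p_value=p,
                n_per_group=(a.size, b.size),
                p_adjusted=min(1.0, p * m) if correction == "bonferroni" else None,
                direction=_direction(a, b),
                labels=(la, lb),
            )
        )
    return results


def curve_anova(curves: Mapping[str, Sequence[KineticCurve]]) -> pd.DataFrame:
    """Two-way ANOVA (group x time) on kinetic-curve mean intensities.

    All curves must share one time grid; each animal's curve is an
    independent replicate (no repeated-measures term). Returns the ANOVA
    table with F and p for group, time, and interaction.
    """
    if len(curves) < 2:
        raise ValidationError("need at least 2 groups")
    grids = {tuple(np.round(c.times_min, 9)) for cs in curves.values() for c in cs}
    if len(grids) != 1:
        raise ValidationError(
            "curves have mismatched time grids; resample to a common grid first"
        )
    rows = []
    for label, cs in curves.items():
        for i, c in enumerate(cs):
            for t, v in zip(c.times_min, c.mean_intensity):
                rows.append(
                    {"group": label, "time": float(t),
                     "animal": c.animal_id or f"{label}_{i}", "value": float(v)}
                )
    df = pd.DataFrame(rows)
    model = smf.ols("value ~ C(group) * C(time)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={"C(group)": "group", "C(time)": "time",
               "C(group):C(time)": "group:time", "Residual": "residual"}
    )
    return table
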