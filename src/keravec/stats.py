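"""Method-comparison statistics for paired device measurements.

Descriptive summaries, paired-difference (device H minus device Z)
summaries, Bland-Altman regression of differences on pairwise means,
empirical CDFs and double-angle centroid/error-ellipse summaries of
astigmatic vector differences.

Percentiles use linear interpolation of the empirical distribution
(numpy's default); standard deviations use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .optics import PowerVector

__all__ = [
    "DescriptiveSummary",
    "BlandAltmanResult",
    "DoubleAngleSummary",
    "EmpiricalCDF",
    "descriptive_summary",
    "paired_difference_summary",
    "bland_altman",
    "empirical_cdf",
    "astigmatism_difference_centroid",
]


@dataclass(frozen=True)
class DescriptiveSummary:
    """Mean, SD, median and the empirical 2.5/97.5 percentiles."""

    mean: float
    sd: float
    median: float
    q2_5: float
    q97_5: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "q2_5": self.q2_5,
            "q97_5": self.q97_5,
            "n": self.n,
        }


@dataclass(frozen=True)
class BlandAltmanResult:
    """Difference-vs-mean agreement analysis for one variable.

    ``slope``/``intercept`` are the OLS fit of the paired differences
    (H - Z) on the pairwise means; a nonzero slope indicates a
    magnitude-dependent (proportional) disagreement.
    """

    diff_summary: DescriptiveSummary
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    q1: float
    q3: float


@dataclass(frozen=True)
class DoubleAngleSummary:
    """Centroid and 95% error ellipse of paired astigmatism differences
    in the double-angle plane (x: 0/90 component, y: 45/135 component)."""

    centroid_x: float
    centroid_y: float
    covariance: np.ndarray
    ellipse_axes: tuple[float, float]
    ellipse_angle: float
    n: int


def _as_clean_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return arr


def descriptive_summary(values) -> DescriptiveSummary:
    """Summary statistics of a scalar sample (n >= 2)."""
    arr = _as_clean_array(values)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a descriptive summary")
    return DescriptiveSummary(
        mean=float(np.mean(arr)),
        sd=float(np.std(arr, ddof=1)),
        median=float(np.median(arr)),
        q2_5=float(np.percentile(arr, 2.5)),
        q97_5=float(np.percentile(arr, 97.5)),
        n=int(arr.size),
    )


def paired_difference_summary(z, h) -> DescriptiveSummary:
    """Summary of per-eye differences H - Z (device H minus device Z)."""
    z = _as_clean_array(z)
    h = _as_clean_array(h)
    if z.size != h.size:
        raise ValueError("paired samples must have equal length")
    return descriptive_summary(h - z)


def bland_altman(z, h) -> BlandAltmanResult:
    """Bland-Altman analysis of paired measurements (differences H - Z
    regressed on pairwise means)."""
    z = _as_clean_array(z)
    h = _as_clean_array(h)
    if z.size != h.size:
        raise ValueError("paired samples must have equal length")
    diff = h - z
    mean = 0.5 * (h + z)
    if np.ptp(mean) == 0.0:
        raise ValueError("pairwise means have zero variance; slope undefined")
    fit = sps.linregress(mean, diff)
    resid = diff - (fit.intercept + fit.slope * mean)
    # constant differences: correlation is undefined, agreement is perfect
    r_squared = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    return BlandAltmanResult(
        diff_summary=descriptive_summary(diff),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        rmse=float(np.sqrt(np.mean(resid**2))),
        q1=float(np.percentile(diff, 25)),
        q3=float(np.percentile(diff, 75)),
    )


@dataclass(frozen=True)
class EmpiricalCDF:
    """Right-continuous empirical CDF: F(t) = #{x_i <= t} / n."""

    x: np.ndarray  # sorted sample
    p: np.ndarray  # cumulative probabilities i/n

    def __call__(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="right")
        out = idx / self.x.size
        return float(out) if np.isscalar(t) else out


def empirical_cdf(values) -> EmpiricalCDF:
    arr = _as_clean_array(values)
    if arr.size < 1:
        raise ValueError("need at least one value")
    x = np.sort(arr)
    return EmpiricalCDF(x=x, p=np.arange(1, x.size + 1) / x.size)


def astigmatism_difference_centroid(
    z: PowerVector, h: PowerVector, coverage: float = 0.95
) -> DoubleAngleSummary:
    """Centroid and error ellipse of the paired astigmatism differences.

    Per-eye differences (h.v0 - z.v0, h.v45 - z.v45) are summarised by
    their componentwise mean (the centroid of the double-angle plot) and
    sample covariance; the ellipse semi-axes are scaled so the ellipse
    covers ``coverage`` of a bivariate normal with that covariance
    (chi-square with 2 degrees of freedom).
    """
    dx = _as_clean_array(np.asarray(h.v0) - np.asarray(z.v0))
    dy = _as_clean_array(np.asarray(h.v45) - np.asarray(z.v45))
    if dx.size != dy.size:
        raise ValueError("paired samples must have equal length")
    if dx.size < 3:
        raise ValueError("need at least 3 pairs for a covariance estimate")
    cov = np.cov(np.vstack([dx, dy]), ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    scale = sps.chi2.ppf(coverage, df=2)
    # eigh returns ascending order; report major axis first
    major, minor = np.sqrt(scale * evals[1]), np.sqrt(scale * evals[0])
    angle = np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])) % 180.0
    return DoubleAngleSummary(
        centroid_x=float(np.mean(dx)),
        centroid_y=float(np.mean(dy)),
        covariance=cov,
        ellipse_axes=(float(major), float(minor)),
        ellipse_angle=float(angle),
        n=int(dx.size),
    )
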