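"""Robust and classical location/scale summaries with type-A uncertainties.

For a monitoring series of *p* repeated determinations the robust summary is
built from the median and one of two normal-consistent robust scale
estimators:

* ``MADe = 1.483 * median(|x_i - median(x)|)`` (scaled median absolute
  deviation), and
* ``nIQR = 0.7413 * (q3 - q1)`` (normalized interquartile range),

with the standard uncertainty of the robust location given by
``u = 1.25 * s / sqrt(p)``, where the factor 1.25 accounts for the extra
variability of the median relative to the mean, and the expanded uncertainty
by ``U = k * u`` for a coverage factor *k* (~95% coverage at k ≈ 2).

The multiplicative constants are used exactly as written above (1.483,
0.7413, 1.25) rather than at higher precision, so results are reproducible
against references that use the same rounded constants.

Quartiles use linear interpolation of order statistics (R type 7, the numpy
default); this is the convention that reproduces the reference interquartile
ranges for the bundled Macaé fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .datasets import MeasurementSeries, round_half_up

__all__ = [
    "MADE_CONSISTENCY",
    "NIQR_CONSISTENCY",
    "MEDIAN_FACTOR",
    "RobustSummary",
    "NormalityResult",
    "median",
    "quartiles",
    "made",
    "niqr",
    "standard_uncertainty",
    "expanded_uncertainty",
    "classical_summary",
    "normality_check",
    "summarize",
]

MADE_CONSISTENCY = 1.483    # scales the MAD to estimate sigma under normality
NIQR_CONSISTENCY = 0.7413   # scales the IQR likewise
MEDIAN_FACTOR = 1.25        # sqrt(pi/2)-style penalty for using the median


def _values(series) -> np.ndarray:
    if isinstance(series, MeasurementSeries):
        return series.values
    return np.asarray(series, dtype=float)


def median(series) -> float:
    """Sample median (mean of the two central order statistics for even p)."""
    x = _values(series)
    if x.size == 0:
        raise ValueError("median of an empty series")
    return float(np.median(x))


def quartiles(series) -> tuple[float, float]:
    """First and third quartiles by linear interpolation of order statistics."""
    x = _values(series)
    if x.size < 4:
        raise ValueError(f"quartiles need at least 4 values, got {x.size}")
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def made(series) -> float:
    """Scaled median absolute deviation, ``1.483 * Med|x_i - Med(x)|``."""
    x = _values(series)
    if x.size == 0:
        raise ValueError("MADe of an empty series")
    med = np.median(x)
    return float(MADE_CONSISTENCY * np.median(np.abs(x - med)))


def niqr(series) -> float:
    """Normalized interquartile range, ``0.7413 * (q3 - q1)``."""
    q1, q3 = quartiles(series)
    return NIQR_CONSISTENCY * (q3 - q1)


def standard_uncertainty(s_star: float, p: int) -> float:
    """Type-A standard uncertainty of a robust location, ``1.25 * s / sqrt(p)``."""
    if p < 1:
        raise ValueError("p must be a positive number of observations")
    if s_star < 0:
        raise ValueError("robust scale must be non-negative")
    return MEDIAN_FACTOR * s_star / np.sqrt(p)


def expanded_uncertainty(u: float, k: float) -> float:
    """Expanded uncertainty ``U = k * u`` for coverage factor k."""
    if u < 0:
        raise ValueError("standard uncertainty must be non-negative")
    if k <= 0:
        raise ValueError("coverage factor must be positive")
    return k * u


def classical_summary(series) -> tuple[float, float, float]:
    """Arithmetic mean, sample SD (n-1 denominator), and ``u = SD / sqrt(p)``."""
    x = _values(series)
    if x.size < 2:
        raise ValueError("classical summary needs at least 2 values")
    sd = float(np.std(x, ddof=1))
    return float(np.mean(x)), sd, sd / np.sqrt(x.size)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    rejected_at_5pct: bool


def normality_check(series, alpha: float = 0.05) -> NormalityResult:
    """One-sample Kolmogorov–Smirnov test against N(mean, SD) of the data.

    Location and scale are estimated from the series itself, without the
    Lilliefors small-sample correction; the test is therefore conservative
    (its true level under the null is well below ``alpha``).  A rejection is
    strong evidence of non-normality; a non-rejection is weak evidence of
    normality.
    """
    x = _values(series)
    if x.size < 5:
        raise ValueError("normality check needs at least 5 values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("normality check is undefined for a constant series")
    res = sps.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return NormalityResult(float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha))


@dataclass(frozen=True)
class RobustSummary:
    """Location/scale/uncertainty estimates for one monitoring series.

    ``u_*`` are standard uncertainties of the corresponding location estimate
    (median for the robust routes, mean for the SD route); ``U_* = k * u_*``.
    """

    measurand: str
    p: int
    med: float
    q1: float
    q3: float
    iqr: float
    s_made: float
    s_niqr: float
    mean: float
    sd: float
    u_made: float
    u_niqr: float
    u_sd: float
    U_made: float
    U_niqr: float
    U_sd: float
    k: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.med <= self.q3):
            raise ValueError("quartiles must bracket the median")
        if self.iqr < 0 or min(self.s_made, self.s_niqr, self.sd) < 0:
            raise ValueError("scale estimates must be non-negative")

    def at_reported_precision(self, decimals: dict[str, int]) -> "RobustSummary":
        """Summary with location/scale rounded to reporting precision.

        ``decimals`` maps statistic names (``median``, ``mean``, ``sd``,
        ``s_made``, ``s_niqr``) to decimal places.  Uncertainties are
        recomputed from the rounded scales, so the result is exactly the
        summary a reader of the printed report would work from.
        """
        med = round_half_up(self.med, decimals["median"])
        mean = round_half_up(self.mean, decimals["mean"])
        sd = round_half_up(self.sd, decimals["sd"])
        s_made = round_half_up(self.s_made, decimals["s_made"])
        s_niqr = round_half_up(self.s_niqr, decimals["s_niqr"])
        u_made = standard_uncertainty(s_made, self.p)
        u_niqr = standard_uncertainty(s_niqr, self.p)
        u_sd = sd / np.sqrt(self.p)
        return replace(
            self,
            med=med, mean=mean, sd=sd, s_made=s_made, s_niqr=s_niqr,
            q1=min(self.q1, med), q3=max(self.q3, med),
            u_made=u_made, u_niqr=u_niqr, u_sd=float(u_sd),
            U_made=self.k * u_made, U_niqr=self.k * u_niqr, U_sd=self.k * float(u_sd),
        )

    def to_json(self) -> dict:
        """Serialize with field names matching the summary-table row labels."""
        return {
            "measurand": self.measurand,
            "Median": self.med,
            "Mean": self.mean,
            "SD": self.sd,
            "q1": self.q1,
            "q3": self.q3,
            "IQR": self.iqr,
            "s*nIQR": self.s_niqr,
            "s*MADe": self.s_made,
            "p": self.p,
            "U(x) SD": self.U_sd,
            "U(x*) nIQR": self.U_niqr,
            "U(x*) MADe": self.U_made,
            "u_sd": self.u_sd,
            "u_niqr": self.u_niqr,
            "u_made": self.u_made,
            "k": self.k,
        }


def summarize(series: MeasurementSeries, k: float = 2.0) -> RobustSummary:
    """Full robust + classical summary of one series.

    ``k`` is the coverage factor for the expanded uncertainties; 2.0 is the
    conventional ~95% value.  The bundled fixture's reference tables are best
    reproduced with k = 2.05 (see the pipeline module).
    """
    x = series.values
    med = median(x)
    q1, q3 = quartiles(x)
    s_made = made(x)
    s_niqr = niqr(x)
    mean, sd, u_sd = classical_summary(x)
    u_made = standard_uncertainty(s_made, x.size)
    u_niqr = standard_uncertainty(s_niqr, x.size)
    return RobustSummary(
        measurand=series.measurand,
        p=int(x.size),
        med=med, q1=q1, q3=q3, iqr=q3 - q1,
        s_made=s_made, s_niqr=s_niqr,
        mean=mean, sd=sd,
        u_made=u_made, u_niqr=u_niqr, u_sd=u_sd,
        U_made=expanded_uncertainty(u_made, k),
        U_niqr=expanded_uncertainty(u_niqr, k),
        U_sd=expanded_uncertainty(u_sd, k),
        k=k,
    )
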