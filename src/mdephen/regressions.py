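"""Fit statistics for the null-model prediction and its latitudinal trend.

Per region and species group, the observed monthly richness is regressed on
the null-model prediction by ordinary least squares with intercept (the
published analysis reports F and R^2, which are the Gaussian-identity outputs);
significance is the two-sided F-test on (1, n-2) degrees of freedom. Across
regions, the variance explained (R^2) is regressed on latitude. For the
latitude trend both the plain coefficient of determination and its adjusted
form are returned; the published per-group summary values correspond to the
adjusted form, which is what ``r2_reported`` exposes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .flora import RichnessCurve, Table1Row, TemporalDomain

GROUPS = ("all", "herb", "woody")
SIGNIFICANCE_LEVELS = ("significant", "marginal", "ns")


@dataclass(frozen=True)
class ProvinceFit:
    """Observed-vs-predicted fit for one region x group."""

    region_id: str
    group: str
    f_stat: float
    r2: float
    p: float
    df: tuple[int, int]
    period: TemporalDomain | None = None
    slope: float = float("nan")
    intercept: float = float("nan")

    @property
    def significance(self) -> str:
        return classify_significance(self.p)


@dataclass(frozen=True)
class LatitudeFit:
    """Linear trend of variance explained (R^2) against latitude."""

    group: str
    slope: float
    intercept: float
    r2: float
    r2_adj: float
    p: float
    n_points: int

    @property
    def r2_reported(self) -> float:
        """Adjusted R^2, the convention used for the published trend values."""
        return self.r2_adj


def fit_observed_vs_predicted(
    observed: RichnessCurve | Sequence[float],
    predicted: Sequence[float],
    region_id: str = "",
    group: str = "all",
) -> ProvinceFit:
    """OLS of observed monthly richness on the null-model prediction.

    Returns R^2, the F statistic on (1, n-2) df and its two-sided P value.
    Requires >= 3 months and a non-constant predictor.
    """
    period = None
    if isinstance(observed, RichnessCurve):
        period = observed.domain
        y = observed.as_array()
    else:
        y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: observed {len(y)} vs predicted {len(x)}")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 months to fit")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    df = (1, n - 2)
    if r2 >= 1.0 - 1e-15:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = r2 / (1.0 - r2) * (n - 2)
        p = float(stats.f.sf(f_stat, *df))
    return ProvinceFit(
        region_id=region_id,
        group=group,
        f_stat=float(f_stat),
        r2=float(r2),
        p=p,
        df=df,
        period=period,
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def classify_significance(p: float) -> str:
    """significant (p <= 0.05), marginal (0.05 < p < 0.10), or ns."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p <= 0.05:
        return "significant"
    if p < 0.10:
        return "marginal"
    return "ns"


def latitude_regression(
    r2_values: Sequence[float] | Sequence[ProvinceFit],
    latitudes: Sequence[float],
    group: str = "all",
) -> LatitudeFit:
    """OLS of per-region variance explained on latitude.

    Accepts either raw R^2 values or ProvinceFit objects (one per region;
    duplicated region ids are rejected).
    """
    if len(r2_values) and isinstance(r2_values[0], ProvinceFit):
        fits: Sequence[ProvinceFit] = r2_values  # type: ignore[assignment]
        regions = [f.region_id for f in fits]
        if len(set(regions)) != len(regions):
            raise ValueError("duplicated region ids")
        y = np.array([f.r2 for f in fits], dtype=float)
    else:
        y = np.asarray(r2_values, dtype=float)
    x = np.asarray(latitudes, dtype=float)
    if len(x) != len(y):
        raise ValueError("latitudes and R^2 values differ in length")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 regions")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return LatitudeFit(
        group=group,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(r2),
        r2_adj=float(r2_adj),
        p=float(res.pvalue),
        n_points=n,
    )


def latitude_regression_from_table1(rows: Sequence[Table1Row], group: str) -> LatitudeFit:
    """Latitude trend recomputed from the published per-province fit table."""
    lats = [row.latitude for row in rows]
    r2s = [row.fit(group).r2 for row in rows]
    return latitude_regression(r2s, lats, group=group)


def count_below_p(rows: Sequence[Table1Row], group: str, threshold: float = 0.10) -> int:
    """Number of provinces whose published P for ``group`` is below ``threshold``."""
    return sum(1 for row in rows if row.fit(group).p < threshold)
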