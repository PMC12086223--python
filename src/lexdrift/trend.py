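"""Linear temporal-trend tests on yearly association estimates.

For each target (and estimation method) the yearly point estimates are
regressed on calendar year by ordinary least squares. The slope measures the
annual change in cosine similarity; its two-sided t-test (n - 2 df) answers
whether the base-target relationship changed over the study period. Years are
centred before fitting for numerical stability and the intercept is reported
on the raw year-0 scale. Bootstrap CIs are not propagated into the default
fit; an inverse-CI-width weighted fit is available but off by default.

Reporting convention: a trend is labelled significant at p < 0.05, two-sided,
with no multiplicity correction across targets; raw p-values are always
printed so readers can apply their own correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import SimilarityEstimate, SimilaritySeries
from .errors import TrendError


@dataclass
class TrendResult:
    target: str
    method: str
    slope: float  # cosine units per year
    intercept: float  # raw year-0 scale
    p_value: float  # nan with exactly 2 points (undefined)
    r_squared: float
    n_years: int

    @property
    def significant(self) -> bool:
        return not math.isnan(self.p_value) and self.p_value < 0.05


def fit_trend(
    series: SimilaritySeries | Sequence[SimilarityEstimate],
    weighted: bool = False,
) -> TrendResult:
    """OLS fit of estimate on year.

    Degenerate cases: with exactly 2 points the slope is exact and the p-value
    is an explicit gap (nan); a constant series has slope 0 and r² defined as
    0 by convention (no variance to explain).
    """
    if isinstance(series, SimilaritySeries):
        target, method, estimates = series.target, series.method, series.estimates
    else:
        estimates = list(series)
        target = estimates[0].target if estimates else ""
        method = estimates[0].method if estimates else ""
    years = np.array([e.year for e in estimates], dtype=float)
    y = np.array([e.estimate for e in estimates], dtype=float)
    if len(years) < 2:
        raise TrendError(f"trend fit needs >= 2 yearly points, got {len(years)}")
    if np.unique(years).size == 1:
        raise TrendError("trend fit needs distinct year values")

    xc = years - years.mean()
    X = sm.add_constant(xc)
    if weighted:
        widths = np.array([e.ci_high - e.ci_low for e in estimates], dtype=float)
        if np.any(~np.isfinite(widths)) or np.any(widths <= 0):
            raise TrendError("weighted fit requires finite positive CI widths")
        fit = sm.WLS(y, X, weights=1.0 / widths**2).fit()
    else:
        fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    intercept = float(fit.params[0] - slope * years.mean())

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # constant series: nothing to explain
        slope, r2, p = 0.0, 0.0, 1.0
        intercept = float(y.mean())
    else:
        r2 = float(fit.rsquared)
        p = float(fit.pvalues[1])
        if len(years) == 2:
            p = math.nan
        elif math.isnan(p) and fit.bse[1] == 0.0:
            p = 0.0  # exact nonzero-slope line: zero residual variance
    return TrendResult(
        target=target,
        method=method,
        slope=slope,
        intercept=intercept,
        p_value=p,
        r_squared=r2,
        n_years=len(years),
    )


def trend_table(results: Sequence[TrendResult]) -> pd.DataFrame:
    rows = [
        {
            "target": r.target,
            "method": r.method,
            "slope": r.slope,
            "intercept": r.intercept,
            "p_value": r.p_value,
            "r_squared": r.r_squared,
            "n_years": r.n_years,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "target", "method", "slope", "intercept",
            "p_value", "r_squared", "n_years", "significant",
        ],
    )


def plot_series(
    series: SimilaritySeries,
    result: TrendResult | None = None,
    path: str | Path | None = None,
):
    """Yearly points with CI whiskers and the fitted trendline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    years = np.array(series.years, dtype=float)
    vals = [e.estimate for e in series.estimates]
    los = np.array([e.ci_low for e in series.estimates])
    his = np.array([e.ci_high for e in series.estimates])
    if np.all(np.isfinite(los)) and np.all(np.isfinite(his)):
        ax.errorbar(
            years, vals,
            yerr=[np.asarray(vals) - los, his - np.asarray(vals)],
            fmt="o-", capsize=3,
        )
    else:
        ax.plot(years, vals, "o-")
    if result is not None and len(years) >= 2:
        xs = np.array([years.min(), years.max()])
        ax.plot(xs, result.intercept + result.slope * xs, "--", color="gray")
    ax.set_xlabel("year")
    ax.set_ylabel("cosine similarity")
    ax.set_title(f"{series.target} ({series.method})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def trend_report(
    results: Sequence[TrendResult],
    series_list: Sequence[SimilaritySeries] = (),
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Trend table (one row per target x method) plus optional per-target
    plot files with points, CI whiskers and trendlines."""
    table = trend_table(results)
    if out_dir is not None and series_list:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        by_key = {(r.target, r.method): r for r in results}
        for s in series_list:
            if not s.estimates:
                continue
            plot_series(
                s,
                by_key.get((s.target, s.method)),
                out_dir / f"trend_{s.target}_{s.method}.png",
            )
    return table
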