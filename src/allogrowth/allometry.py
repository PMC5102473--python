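"""Log-log allometric regression of maximum growth rate on body mass.

The working hypothesis is the power law ``G_max = a * M**b``, equivalently
``kC = a * M**(b-1)`` since ``G_max = M * kC``.  On log10 axes the two
formulations differ only by the shear transformation ``(x, y) -> (x, x+y)``:
the slope shifts by exactly one, residuals and confidence-interval widths
are untouched, but R² is inflated when the dependent variable carries the
independent variable as a factor.  This module provides the weighted OLS
machinery, the shear diagnostic, 95% confidence and single-prediction
bands, and fixed-slope mass-adjusted rates.

Weighting follows the per-taxon convention: when a taxon contributes
several points, its total weight is one, split equally among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatePoint",
    "LogLogFit",
    "Band",
    "points_to_frame",
    "shear_transform",
    "fit_loglog",
    "compare_dependent_variables",
    "confidence_band",
    "prediction_band",
    "fixed_slope_adjust",
]


@dataclass
class RatePoint:
    """One taxon as a (mass, rate) observation with group labels.

    Rates are the derived quantities of the sigmoid framework: ``rate_Gmax``
    is the absolute peak growth rate (g/day), ``rate_kC = G_max / M`` (1/day)
    and ``rate_kD = G_max / BMatMG`` (1/day).
    """

    taxon: str
    group: str
    M: float
    rate_Gmax: Optional[float] = None
    rate_kC: Optional[float] = None
    rate_kD: Optional[float] = None
    BMatMG: Optional[float] = None
    thermo: str = "unknown"
    weight: float = 1.0
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError(f"{self.taxon}: mass must be positive, got {self.M}")
        if self.weight < 0:
            raise ValueError(f"{self.taxon}: weight must be nonnegative")

    def rate(self, which: str) -> float:
        val = {"Gmax": self.rate_Gmax, "kC": self.rate_kC, "kD": self.rate_kD}[which]
        if val is None:
            raise ValueError(f"{self.taxon}: rate {which} not available")
        return val

    def mass(self, which: str) -> float:
        if which == "M":
            return self.M
        if which == "BMatMG":
            if self.BMatMG is None:
                raise ValueError(f"{self.taxon}: BMatMG not available")
            return self.BMatMG
        raise ValueError(f"unknown independent variable {which!r}")


def points_to_frame(points: Iterable[RatePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": p.taxon,
                "group": p.group,
                "thermo": p.thermo,
                "M_g": p.M,
                "BMatMG_g": p.BMatMG,
                "Gmax_g_per_day": p.rate_Gmax,
                "kC_per_day": p.rate_kC,
                "kD_per_day": p.rate_kD,
                "weight": p.weight,
                "excluded": p.excluded,
            }
            for p in points
        ]
    )


@dataclass
class LogLogFit:
    """Weighted OLS on log10-transformed (mass, rate) data."""

    dependent: str
    independent: str
    intercept: float
    slope: float
    ci95_intercept: tuple[float, float]
    ci95_slope: tuple[float, float]
    r2: float
    n: int
    residuals: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    sigma2: float = 0.0
    weighted: bool = False

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    @property
    def x_mean(self) -> float:
        """Weighted mean of the regressor (band-width minimiser)."""
        return float(np.average(self.x, weights=self.weights))

    @property
    def sxx(self) -> float:
        return float(np.sum(self.weights * (self.x - self.x_mean) ** 2))


@dataclass
class Band:
    kind: str  # "confidence" or "prediction"
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    extrapolated: np.ndarray | None = None


def shear_transform(x, y):
    """The map (x, y) -> (x, x + y) on log-log coordinates.

    This is the geometric effect of switching the dependent variable from a
    mass-specific rate to the absolute rate (which carries mass as a factor).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x, x + y


def inverse_shear_transform(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x, y - x


def _wls(x, y, w):
    """Closed-form weighted least squares with t-based 95% CIs."""
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise ValueError("regressor has zero weighted variance")
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    n = len(x)
    dof = n - 2
    rss = np.sum(w * resid**2)
    tss = np.sum(w * (y - ybar) ** 2)
    sigma2 = rss / dof if dof > 0 else np.nan
    se_slope = np.sqrt(sigma2 / sxx)
    se_intercept = np.sqrt(sigma2 * (1.0 / sw + xbar**2 / sxx))
    tq = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return {
        "intercept": intercept,
        "slope": slope,
        "ci95_slope": (slope - tq * se_slope, slope + tq * se_slope),
        "ci95_intercept": (intercept - tq * se_intercept, intercept + tq * se_intercept),
        "r2": r2,
        "residuals": resid,
        "sigma2": sigma2,
    }


def fit_loglog(
    points: Sequence[RatePoint],
    dependent: str = "kC",
    independent: str = "M",
    weighted: bool = True,
    include_excluded: bool = False,
) -> LogLogFit:
    """Weighted OLS of log10(rate) on log10(mass).

    Parameters
    ----------
    points : sequence of RatePoint
    dependent : {"Gmax", "kC", "kD"}
    independent : {"M", "BMatMG"}
    weighted : bool
        Apply per-point weights (per-taxon total weight one).
    include_excluded : bool
        Keep points whose ``excluded`` flag is set.
    """
    pts = [p for p in points if include_excluded or not p.excluded]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points to fit, got {len(pts)}")
    for p in pts:
        if p.mass(independent) <= 0 or p.rate(dependent) <= 0:
            raise ValueError(f"{p.taxon}: non-positive mass or rate")
    x = np.log10([p.mass(independent) for p in pts])
    y = np.log10([p.rate(dependent) for p in pts])
    w = np.array([p.weight for p in pts]) if weighted else np.ones(len(pts))
    out = _wls(x, y, w)
    return LogLogFit(
        dependent=dependent,
        independent=independent,
        intercept=out["intercept"],
        slope=out["slope"],
        ci95_intercept=out["ci95_intercept"],
        ci95_slope=out["ci95_slope"],
        r2=out["r2"],
        n=len(pts),
        residuals=out["residuals"],
        x=x,
        weights=w,
        sigma2=out["sigma2"],
        weighted=weighted,
    )


def compare_dependent_variables(
    points: Sequence[RatePoint], independent: str = "M", weighted: bool = True
) -> dict:
    """Fit both G_max and kC against mass and report the shear diagnostic.

    The slopes must differ by exactly one and the CI widths must match;
    only R² changes — the signature of the shear transformation.
    """
    fit_G = fit_loglog(points, "Gmax", independent, weighted)
    fit_k = fit_loglog(points, "kC", independent, weighted)
    wG = fit_G.ci95_slope[1] - fit_G.ci95_slope[0]
    wk = fit_k.ci95_slope[1] - fit_k.ci95_slope[0]
    return {
        "slope_Gmax": fit_G.slope,
        "slope_kC": fit_k.slope,
        "slope_difference": fit_G.slope - fit_k.slope,
        "ci_width_Gmax": wG,
        "ci_width_kC": wk,
        "r2_Gmax": fit_G.r2,
        "r2_kC": fit_k.r2,
        "fit_Gmax": fit_G,
        "fit_kC": fit_k,
    }


def _band(fit: LogLogFit, grid, kind: str) -> Band:
    grid = np.asarray(grid, dtype=float)
    dof = fit.n - 2
    tq = stats.t.ppf(0.975, dof)
    sw = np.sum(fit.weights)
    lev = 1.0 / sw + (grid - fit.x_mean) ** 2 / fit.sxx
    if kind == "confidence":
        se = np.sqrt(fit.sigma2 * lev)
    elif kind == "prediction":
        # single new observation of unit weight
        se = np.sqrt(fit.sigma2 * (1.0 + lev))
    else:
        raise ValueError(f"unknown band kind {kind!r}")
    mid = fit.predict(grid)
    extrap = (grid < fit.x.min()) | (grid > fit.x.max())
    return Band(kind=kind, grid=grid, lower=mid - tq * se, upper=mid + tq * se,
                extrapolated=extrap)


def confidence_band(fit: LogLogFit, grid) -> Band:
    """95% band for the mean response (the regression line itself)."""
    return _band(fit, grid, "confidence")


def prediction_band(fit: LogLogFit, grid) -> Band:
    """95% band for a single new observation (species-level variation)."""
    return _band(fit, grid, "prediction")


def fixed_slope_adjust(
    points: Sequence[RatePoint],
    b: float = 0.75,
    dependent: str = "Gmax",
    independent: str = "M",
    groups: Optional[Sequence[str]] = None,
) -> dict:
    """Adjust rates to a 1 g body mass assuming a fixed allometric slope.

    Per point the adjusted value is ``log10(rate) - b * log10(mass)``, i.e.
    the intercept each point would imply if the slope were exactly ``b``.
    Returns per-group adjusted distributions and, when several groups are
    present, the interval where their [min, max] ranges all intersect
    (empty -> None).
    """
    pts = [p for p in points if not p.excluded]
    adj = pd.DataFrame(
        {
            "taxon": [p.taxon for p in pts],
            "group": [p.group for p in pts],
            "thermo": [p.thermo for p in pts],
            "adjusted": [
                np.log10(p.rate(dependent)) - b * np.log10(p.mass(independent))
                for p in pts
            ],
        }
    )
    wanted = groups if groups is not None else sorted(adj["group"].unique())
    lo = -np.inf
    hi = np.inf
    for g in wanted:
        vals = adj.loc[adj["group"] == g, "adjusted"]
        if vals.empty:
            continue
        lo = max(lo, vals.min())
        hi = min(hi, vals.max())
    overlap = (float(lo), float(hi)) if lo <= hi else None
    return {"b": b, "adjusted": adj, "overlap_interval": overlap}
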