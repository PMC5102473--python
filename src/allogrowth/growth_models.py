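"""Dimensionless sigmoidal growth models and constrained curve fitting.

Every determinate growth trajectory considered here can be written as

    m(t) = M * f(s) + M_c,    s = k * (t - t_c),

where ``M`` is the asymptotic mass (g), ``k`` a growth constant (1/day),
``t_c`` a time offset (day), ``M_c`` a mass offset (g, normally zero) and
``f`` a dimensionless sigmoid.  Three classical choices are supported:

=================  =======================  =======  =======  ======
model              f(s)                     C        d        D=C/d
=================  =======================  =======  =======  ======
logistic           1 / (1 + e^-s)           1/4      1/2      2
gompertz           exp(-e^-s)               1/e      1/e      1
von_bertalanffy    (1 - e^-s)^3             4/9      8/27     3/2
=================  =======================  =======  =======  ======

``C = max_s df/ds`` fixes the peak growth rate ``G_max = M*k*C`` and
``d = f(argmax df/ds)`` is the fraction of asymptotic mass at the
inflection point, so the body mass at maximum growth is ``BMatMG = M*d``.
Two mass-specific rate normalisations follow: ``kC = G_max / M`` and
``kD = G_max / BMatMG = kC / d``.

Units are fixed internally: mass in grams, time in days, rates in g/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "GrowthModelSpec",
    "GrowthCurveParams",
    "AgeMassSeries",
    "GrowthCurveFit",
    "MODELS",
    "get_model",
    "dimensionless_growth",
    "model_constants",
    "predict_mass",
    "derived_rates",
    "time_to_fraction",
    "fit_growth_curve",
    "GrowthFitError",
]


class GrowthFitError(RuntimeError):
    """Nonlinear growth-curve fit failed to converge or is under-determined."""


@dataclass(frozen=True)
class GrowthModelSpec:
    """A dimensionless sigmoid together with its analytic constants.

    Attributes
    ----------
    name : str
        One of ``logistic``, ``gompertz``, ``von_bertalanffy``.
    f : callable
        The dimensionless growth function ``f(s)``.
    f_inv : callable
        Closed-form inverse of ``f`` on (0, 1), or ``None`` (bisection used).
    C : float
        Maximum of ``df/ds`` (dimensionless peak relative growth rate).
    d : float
        Value of ``f`` at the maximiser of ``df/ds`` (inflection mass fraction).
    """

    name: str
    f: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    f_inv: Optional[Callable[[float], float]] = field(repr=False)
    C: float = 0.0
    d: float = 0.0

    @property
    def D(self) -> float:
        """Rescaling constant C/d linking the kC and kD normalisations."""
        return self.C / self.d


def _f_logistic(s):
    # expit in stable form
    s = np.asarray(s, dtype=float)
    return 0.5 * (1.0 + np.tanh(0.5 * s))


def _f_gompertz(s):
    s = np.asarray(s, dtype=float)
    with np.errstate(over="ignore"):  # exp(-s) overflow -> f underflows to 0
        return np.exp(-np.exp(-s))


def _f_von_bertalanffy(s):
    s = np.asarray(s, dtype=float)
    return (1.0 - np.exp(-s)) ** 3


MODELS: dict[str, GrowthModelSpec] = {
    "logistic": GrowthModelSpec(
        name="logistic",
        f=_f_logistic,
        f_inv=lambda p: math.log(p / (1.0 - p)),
        C=0.25,
        d=0.5,
    ),
    "gompertz": GrowthModelSpec(
        name="gompertz",
        f=_f_gompertz,
        f_inv=lambda p: -math.log(-math.log(p)),
        C=1.0 / math.e,
        d=1.0 / math.e,
    ),
    "von_bertalanffy": GrowthModelSpec(
        name="von_bertalanffy",
        f=_f_von_bertalanffy,
        f_inv=None,
        C=4.0 / 9.0,
        d=8.0 / 27.0,
    ),
}


def get_model(name: str | GrowthModelSpec) -> GrowthModelSpec:
    """Resolve a model name to its spec; raise ``KeyError`` for unknown names."""
    if isinstance(name, GrowthModelSpec):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown growth model {name!r}; expected one of {sorted(MODELS)}"
        ) from None


def dimensionless_growth(model: str | GrowthModelSpec, s):
    """Evaluate the dimensionless sigmoid ``f(s)`` for the given model."""
    return get_model(model).f(s)


def model_constants(model: str | GrowthModelSpec) -> tuple[float, float, float]:
    """Return the analytic constants ``(C, d, D)`` for a growth model."""
    spec = get_model(model)
    return spec.C, spec.d, spec.D


def numerical_model_constants(
    model: str | GrowthModelSpec,
    s_range: tuple[float, float] = (-12.0, 12.0),
    n_grid: int = 200001,
) -> tuple[float, float, float]:
    """Compute (C, d, D) by numerically maximising df/ds on a fine grid.

    Independent of the analytic constants; used to validate them.  The
    derivative is taken by central differences on a dense grid, then the
    maximiser is polished with a golden-section-free parabolic refinement
    (three-point quadratic fit around the grid argmax).
    """
    spec = get_model(model)
    s = np.linspace(*s_range, n_grid)
    h = s[1] - s[0]
    df = (spec.f(s + h) - spec.f(s - h)) / (2.0 * h)
    # restrict to the physical branch 0 < f < 1 (the von Bertalanffy cubic
    # diverges for s < 0, where f is negative and not a mass fraction)
    fvals = spec.f(s)
    df = np.where((fvals > 0.0) & (fvals < 1.0), df, -np.inf)
    i = int(np.argmax(df))
    # parabolic refinement around the discrete argmax
    if 0 < i < len(s) - 1:
        y0, y1, y2 = df[i - 1], df[i], df[i + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        s_star = s[i] + shift * h
    else:  # pragma: no cover - range chosen to avoid boundary maxima
        s_star = s[i]
    hh = 1e-5
    C = float((spec.f(s_star + hh) - spec.f(s_star - hh)) / (2.0 * hh))
    d = float(spec.f(s_star))
    return C, d, C / d


@dataclass
class GrowthCurveParams:
    """Parameters of ``m(t) = M f(k (t - t_c)) + M_c``."""

    M: float
    k: float
    t_c: float = 0.0
    M_c: float = 0.0
    model: str | GrowthModelSpec = "gompertz"

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError(f"asymptotic mass M must be positive, got {self.M}")
        if self.k <= 0:
            raise ValueError(f"growth constant k must be positive, got {self.k}")
        self.model = get_model(self.model)


@dataclass
class AgeMassSeries:
    """Age–mass observations for a single taxon.

    ``point_provenance`` flags which points are real specimens versus
    hypothetical neonates added to anchor the early part of the curve.
    """

    taxon: str
    ages: np.ndarray
    masses: np.ndarray
    point_provenance: Optional[Sequence[str]] = None
    fixed_asymptote: Optional[float] = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.ages.shape != self.masses.shape:
            raise ValueError("ages and masses must have the same length")
        if not np.all(np.isfinite(self.ages)):
            raise ValueError(f"{self.taxon}: non-finite ages")
        if np.any(self.masses <= 0):
            raise ValueError(f"{self.taxon}: masses must be positive")
        if self.point_provenance is None:
            self.point_provenance = ["observed"] * len(self.ages)

    @property
    def n(self) -> int:
        return len(self.ages)


@dataclass
class GrowthCurveFit:
    """Result of a least-squares sigmoid fit plus derived rate quantities."""

    params: GrowthCurveParams
    rss: float
    asymptote_fixed: bool
    neonate_added: bool
    derived: dict[str, float]
    taxon: str = ""

    def as_record(self) -> dict:
        p = self.params
        return {
            "taxon": self.taxon,
            "model": p.model.name,
            "M_g": p.M,
            "k_per_day": p.k,
            "tc_days": p.t_c,
            "rss": self.rss,
            "G_max_g_per_day": self.derived["G_max"],
            "kC_per_day": self.derived["kC"],
            "kD_per_day": self.derived["kD"],
            "BMatMG_g": self.derived["BMatMG"],
            "asymptote_fixed": self.asymptote_fixed,
            "neonate_added": self.neonate_added,
        }


def predict_mass(params: GrowthCurveParams, t) -> np.ndarray:
    """Mass at age ``t`` (days) under the sigmoid growth model."""
    spec = get_model(params.model)
    s = params.k * (np.asarray(t, dtype=float) - params.t_c)
    return params.M * spec.f(s) + params.M_c


def derived_rates(params: GrowthCurveParams) -> dict[str, float]:
    """Closed-form rate quantities implied by fitted sigmoid parameters.

    Returns ``G_max`` (peak growth rate, g/day), ``kC`` (mass-specific peak
    rate, 1/day), ``BMatMG`` (body mass at maximum growth, g), ``kD``
    (peak rate per unit BMatMG, 1/day) and ``t_M = 1/kC`` (days).
    """
    spec = get_model(params.model)
    G_max = params.M * params.k * spec.C
    kC = G_max / params.M
    BMatMG = params.M * spec.d
    kD = G_max / BMatMG
    return {"G_max": G_max, "kC": kC, "kD": kD, "BMatMG": BMatMG, "t_M": 1.0 / kC}


def _invert_f(spec: GrowthModelSpec, p: float) -> float:
    """Solve f(s) = p for s, p in (0, 1)."""
    if spec.f_inv is not None:
        return spec.f_inv(p)
    lo, hi = -50.0, 50.0
    return brentq(lambda s: float(spec.f(s)) - p, lo, hi, xtol=1e-12, rtol=1e-12)


def time_to_fraction(
    params: GrowthCurveParams, start_fraction: float, end_fraction: float
) -> float:
    """Days for the curve to grow from one fraction of M to another.

    Fractions refer to ``m(t) / M`` with the mass offset excluded; both must
    lie strictly inside (0, 1) with ``start_fraction < end_fraction``.
    """
    if not (0.0 < start_fraction < end_fraction < 1.0):
        raise ValueError(
            "fractions must satisfy 0 < start < end < 1, got "
            f"({start_fraction}, {end_fraction})"
        )
    spec = get_model(params.model)
    s0 = _invert_f(spec, start_fraction)
    s1 = _invert_f(spec, end_fraction)
    return (s1 - s0) / params.k


def _initial_guesses(series: AgeMassSeries) -> list[tuple[float, float, float]]:
    """Multi-start heuristics spanning the data: M from max mass, k from the
    log-slope between endpoints, t_c from the age span."""
    ages, masses = series.ages, series.masses
    span = max(ages.max() - ages.min(), 1.0)
    m_max = masses.max()
    order = np.argsort(ages)
    a_s, m_s = ages[order], masses[order]
    if m_s[-1] > m_s[0] and span > 0:
        k0 = (np.log(m_s[-1]) - np.log(m_s[0])) / span
        k0 = max(k0, 1e-6)
    else:
        k0 = 1.0 / span
    t_mid = 0.5 * (ages.min() + ages.max())
    starts = []
    for m_fac in (1.05, 1.5, 3.0):
        for k_fac in (0.5, 1.0, 2.0):
            starts.append((m_fac * m_max, k_fac * k0, t_mid))
    starts.append((1.05 * m_max, k0, ages.min()))
    starts.append((2.0 * m_max, k0, ages.max()))
    return starts


def fit_growth_curve(
    series: AgeMassSeries,
    model: str | GrowthModelSpec = "gompertz",
    fix_asymptote: Optional[float] = None,
    add_neonate: Optional[tuple[float, float]] = None,
) -> GrowthCurveFit:
    """Least-squares fit of a sigmoid growth curve to an age–mass series.

    Parameters
    ----------
    series : AgeMassSeries
        Observed (and optionally augmented) age–mass points.
    model : str or GrowthModelSpec
        Sigmoid family to fit.
    fix_asymptote : float, optional
        Constrain M to this literature value instead of estimating it.
    add_neonate : (age, mass), optional
        Append a hypothetical neonate point before fitting.

    Uses multi-start trust-region least squares; ``M_c`` is held at zero.
    """
    spec = get_model(model)
    ages, masses = series.ages, series.masses
    neonate_added = False
    if add_neonate is not None:
        ages = np.append(ages, add_neonate[0])
        masses = np.append(masses, add_neonate[1])
        neonate_added = True
    work = AgeMassSeries(series.taxon, ages, masses)
    if fix_asymptote is None and series.fixed_asymptote is not None:
        fix_asymptote = series.fixed_asymptote

    n_free = 2 if fix_asymptote is not None else 3
    if work.n <= n_free:
        raise GrowthFitError(
            f"{series.taxon}: {work.n} points cannot constrain {n_free} free parameters"
        )

    if fix_asymptote is not None:

        def resid(theta):
            k, t_c = theta
            s = k * (ages - t_c)
            return fix_asymptote * spec.f(s) - masses

        def unpack(theta):
            return fix_asymptote, theta[0], theta[1]

        lb = [1e-12, -np.inf]
        ub = [np.inf, np.inf]
        take = lambda g: (g[1], g[2])  # noqa: E731
    else:

        def resid(theta):
            M, k, t_c = theta
            s = k * (ages - t_c)
            return M * spec.f(s) - masses

        def unpack(theta):
            return theta[0], theta[1], theta[2]

        lb = [1e-12, 1e-12, -np.inf]
        ub = [np.inf, np.inf, np.inf]
        take = lambda g: g  # noqa: E731

    best = None
    for guess in _initial_guesses(work):
        try:
            res = least_squares(
                resid,
                np.asarray(take(guess), dtype=float),
                bounds=(lb, ub),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise GrowthFitError(f"{series.taxon}: all fit starts failed")
    rss, theta = best
    M, k, t_c = unpack(theta)
    params = GrowthCurveParams(M=float(M), k=float(k), t_c=float(t_c), model=spec)
    return GrowthCurveFit(
        params=params,
        rss=rss,
        asymptote_fixed=fix_asymptote is not None,
        neonate_added=neonate_added,
        derived=derived_rates(params),
        taxon=series.taxon,
    )
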