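"""Tests of the proposed growth-rate → basal-metabolic-rate link.

Three probes of the claim that maximum growth rate predicts BMR:

* ``bmr_adjust`` — ontogenetic adjustment BMR_adj = BMR * (M / M_met)**0.75
  for specimens measured below adult mass (assumes Kleiber scaling holds
  within ontogeny).
* ``direct_test`` — the fixed-proportionality claim BMR = c * G_max
  (c = 0.6 by default) evaluated record by record; reports the extreme
  over- and under-prediction factors.
* ``transitivity_report`` — the pairwise regressions kC~M, BMR~M and
  BMR~kC side by side: both marginals can be strong while the direct
  growth–metabolism correlation is near zero (correlation is not
  transitive; composing regressions as if they were equalities is the
  fallacy of averages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .allometry import LogLogFit, RatePoint, fit_loglog

__all__ = [
    "MetabolicRecord",
    "DirectTestReport",
    "bmr_adjust",
    "direct_test",
    "transitivity_report",
]


@dataclass
class MetabolicRecord:
    """BMR observation linked to a taxon's mass and growth quantities.

    ``BMR`` in watts; ``M_met`` the body mass (g) at which BMR was measured;
    ``M`` the adult asymptotic mass (g).  Growth quantities are optional.
    """

    taxon: str
    group: str
    BMR: float
    M_met: float
    M: float
    thermo: str = "unknown"
    G_max: Optional[float] = None
    kC: Optional[float] = None

    def __post_init__(self) -> None:
        if self.BMR <= 0:
            raise ValueError(f"{self.taxon}: BMR must be positive")
        if self.M_met <= 0:
            raise ValueError(f"{self.taxon}: measurement mass must be positive")
        if self.M_met > self.M:
            warnings.warn(
                f"{self.taxon}: measurement mass {self.M_met} exceeds adult mass "
                f"{self.M}; record retained",
                stacklevel=2,
            )


def bmr_adjust(record: MetabolicRecord, b: float = 0.75) -> float:
    """Scale a BMR measured at mass M_met up to adult mass M assuming
    BMR ∝ M**b throughout ontogeny."""
    return record.BMR * (record.M / record.M_met) ** b


@dataclass
class DirectTestReport:
    """Extreme error factors of the prediction BMR = c * G_max."""

    c: float
    over_factor: float   # worst over-prediction: max(predicted / observed)
    under_factor: float  # worst under-prediction: max(observed / predicted)
    n: int
    ratios: np.ndarray   # predicted / observed, per record

    @property
    def total_range(self) -> float:
        return self.over_factor * self.under_factor


def direct_test(
    records: Sequence[MetabolicRecord],
    c: float = 0.6,
    use_adjusted: bool = False,
    adjust_exponent: float = 0.75,
) -> DirectTestReport:
    """Evaluate BMR = c * G_max record by record.

    ``c`` absorbs the unit bridge between G_max (g/day) and BMR (W); records
    without G_max are skipped with a warning.  With ``use_adjusted`` the
    ontogenetically adjusted BMR is the observation.
    """
    ratios = []
    for r in records:
        if r.G_max is None or r.G_max <= 0:
            warnings.warn(f"{r.taxon}: no G_max, skipped in direct test", stacklevel=2)
            continue
        obs = bmr_adjust(r, adjust_exponent) if use_adjusted else r.BMR
        ratios.append(c * r.G_max / obs)
    if not ratios:
        raise ValueError("no records with G_max available")
    ratios = np.asarray(ratios)
    return DirectTestReport(
        c=c,
        over_factor=float(max(ratios.max(), 1.0)),
        under_factor=float(max((1.0 / ratios).max(), 1.0)),
        n=len(ratios),
        ratios=ratios,
    )


def _as_rate_points(
    records: Sequence[MetabolicRecord], y: str, use_adjusted: bool
) -> list[RatePoint]:
    pts = []
    for r in records:
        bmr = bmr_adjust(r) if use_adjusted else r.BMR
        if y == "BMR_vs_M":
            pts.append(RatePoint(r.taxon, r.group, M=r.M, rate_kC=bmr))
        elif y == "kC_vs_M":
            if r.kC is None:
                continue
            pts.append(RatePoint(r.taxon, r.group, M=r.M, rate_kC=r.kC))
        elif y == "BMR_vs_kC":
            if r.kC is None:
                continue
            # regress log BMR on log kC: mass slot holds kC
            pts.append(RatePoint(r.taxon, r.group, M=r.kC, rate_kC=bmr))
    return pts


def transitivity_report(
    records: Sequence[MetabolicRecord], use_adjusted: bool = False
) -> dict[str, LogLogFit]:
    """The three pairwise log-log regressions among kC, BMR and M.

    Returns fits keyed ``kC~M``, ``BMR~M`` and ``BMR~kC`` (BMR_adj variants
    when ``use_adjusted``).  Non-transitivity shows as a near-zero R² for
    BMR~kC despite strong marginals.
    """
    out = {}
    for key, tag in (("kC~M", "kC_vs_M"), ("BMR~M", "BMR_vs_M"),
                     ("BMR~kC", "BMR_vs_kC")):
        pts = _as_rate_points(records, tag, use_adjusted)
        if len(pts) < 3:
            raise ValueError(f"too few records for regression {key}")
        out[key] = fit_loglog(pts, dependent="kC", independent="M", weighted=False)
    return out
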