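"""Synthetic data with the statistical structure the analyses assume.

Three generators mirror the three input kinds:

* grouped allometric rate points — per-group power law ``kC = a * M**(b-1)``
  with lognormal scatter on the rate and log-uniform masses, the derived
  quantities (G_max, BMatMG, kD) computed exactly from the declared sigmoid
  model so the algebraic identities hold by construction;
* metabolic records — Kleiber-type ``BMR = a1 * M**b1`` with noise
  independent of the growth-rate noise (independence is what produces the
  non-transitive correlation structure);
* age–mass series — sigmoid trajectories with multiplicative Gaussian
  noise, optionally truncated before the inflection point to emulate the
  partial-lifespan coverage typical of fossil growth series.

Default group templates follow the observed geometry: endotherm groups
with higher rate intercepts than ectotherm groups, scatter of 0.3–0.5 in
log10 rate, and overlapping mass ranges, so that hulls overlap while the
group regressions separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .allometry import RatePoint
from .growth_models import AgeMassSeries, GrowthCurveParams, get_model, predict_mass
from .metabolic import MetabolicRecord

__all__ = [
    "GroupGenSpec",
    "MetabGenSpec",
    "DEFAULT_GROUPS",
    "generate_group",
    "generate_groups",
    "generate_metabolic",
    "generate_age_mass",
]


@dataclass
class GroupGenSpec:
    """Generating parameters for one group's rate points.

    ``slope_b`` is the exponent b of ``G_max = a M**b``; the generated
    mass-specific rate follows ``log10 kC = log10(a) + (b-1) log10(M) +
    N(0, sd)``.
    """

    group: str
    thermo: str
    n: int
    log10_mass_range: tuple[float, float]
    log10_a: float
    slope_b: float
    sd: float
    seed: int = 0
    model: str = "gompertz"

    def __post_init__(self) -> None:
        lo, hi = self.log10_mass_range
        if not lo < hi:
            raise ValueError("mass range must satisfy lo < hi")
        if self.sd < 0 or self.n < 3:
            raise ValueError("need sd >= 0 and n >= 3")


#: Four-group template: two endotherm groups with high intercepts, two
#: ectotherm groups roughly a decade lower, overlapping mass ranges.
DEFAULT_GROUPS: tuple[GroupGenSpec, ...] = (
    GroupGenSpec("mammals", "endotherm", 50, (1.0, 6.0), -0.7, 0.75, 0.35, seed=11),
    GroupGenSpec("birds", "endotherm", 40, (0.5, 4.5), -0.4, 0.75, 0.30, seed=12),
    GroupGenSpec("reptiles", "ectotherm", 40, (0.5, 5.5), -1.7, 0.75, 0.40, seed=13),
    GroupGenSpec("fish", "ectotherm", 50, (0.0, 5.0), -1.5, 0.75, 0.50, seed=14),
)


def generate_group(spec: GroupGenSpec,
                   rng: Optional[np.random.Generator] = None) -> list[RatePoint]:
    """Draw one group of rate points from its generating power law."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    model = get_model(spec.model)
    lo, hi = spec.log10_mass_range
    log_m = rng.uniform(lo, hi, size=spec.n)
    log_kc = spec.log10_a + (spec.slope_b - 1.0) * log_m + rng.normal(0, spec.sd,
                                                                      spec.n)
    M = 10.0**log_m
    kC = 10.0**log_kc
    G_max = M * kC
    BMatMG = M * model.d
    kD = G_max / BMatMG
    return [
        RatePoint(
            taxon=f"{spec.group}_{i:03d}",
            group=spec.group,
            thermo=spec.thermo,
            M=float(M[i]),
            rate_Gmax=float(G_max[i]),
            rate_kC=float(kC[i]),
            rate_kD=float(kD[i]),
            BMatMG=float(BMatMG[i]),
        )
        for i in range(spec.n)
    ]


def generate_groups(
    specs: Sequence[GroupGenSpec] = DEFAULT_GROUPS, seed: Optional[int] = None
) -> dict[str, list[RatePoint]]:
    """Generate several groups; with ``seed`` given, per-group seeds are
    derived from it deterministically."""
    out = {}
    for i, spec in enumerate(specs):
        rng = np.random.default_rng(None if seed is None else (seed * 1000 + i) % (2**31))
        out[spec.group] = generate_group(spec, rng)
    return out


@dataclass
class MetabGenSpec:
    """Generating parameters for metabolic records.

    BMR follows ``a1 * M**b1`` with lognormal noise; kC follows
    ``a2 * M**(b2-1)`` with its own noise.  When ``independent_noise`` the
    two noises are uncorrelated (the regime in which BMR and kC decouple);
    otherwise a single shared draw perturbs both.
    """

    a1: float = 0.02       # Kleiber-type intercept, W at 1 g
    b1: float = 0.75
    a2: float = 0.2        # growth intercept, g/day at 1 g
    b2: float = 0.75
    sd_bmr: float = 0.3    # log10 scatter of BMR
    sd_growth: float = 0.3  # log10 scatter of kC
    independent_noise: bool = True
    mmet_fraction_range: tuple[float, float] = (0.3, 1.0)
    seed: int = 0


def generate_metabolic(
    masses: np.ndarray,
    spec: MetabGenSpec,
    rng: Optional[np.random.Generator] = None,
    group: str = "pooled",
) -> list[MetabolicRecord]:
    """Metabolic records at the given adult masses (g)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    n = len(masses)
    eps_b = rng.normal(0, spec.sd_bmr, n)
    eps_g = rng.normal(0, spec.sd_growth, n) if spec.independent_noise else (
        eps_b * (spec.sd_growth / spec.sd_bmr if spec.sd_bmr > 0 else 1.0)
    )
    bmr = spec.a1 * masses**spec.b1 * 10.0**eps_b
    kc = spec.a2 * masses ** (spec.b2 - 1.0) * 10.0**eps_g
    frac = rng.uniform(*spec.mmet_fraction_range, n)
    return [
        MetabolicRecord(
            taxon=f"met_{i:03d}",
            group=group,
            BMR=float(bmr[i]),
            M_met=float(frac[i] * masses[i]),
            M=float(masses[i]),
            G_max=float(kc[i] * masses[i]),
            kC=float(kc[i]),
        )
        for i in range(n)
    ]


def expected_r2_bmr_kc(spec: MetabGenSpec, log10_mass_range: tuple[float, float]
                       ) -> dict[str, float]:
    """Closed-form squared correlations implied by the generating model.

    With log10 M uniform on [lo, hi] (variance V = (hi-lo)^2 / 12) and
    independent noises, on log10 axes:

        R2(BMR~M)  = b1² V / (b1² V + sd_bmr²)
        R2(kC~M)   = (b2-1)² V / ((b2-1)² V + sd_growth²)
        R2(BMR~kC) = (b1 (b2-1) V)² /
                     ((b1² V + sd_bmr²) ((b2-1)² V + sd_growth²))
    """
    lo, hi = log10_mass_range
    V = (hi - lo) ** 2 / 12.0
    vb = spec.b1**2 * V + spec.sd_bmr**2
    vk = (spec.b2 - 1.0) ** 2 * V + spec.sd_growth**2
    cov = spec.b1 * (spec.b2 - 1.0) * V
    return {
        "BMR~M": spec.b1**2 * V / vb,
        "kC~M": (spec.b2 - 1.0) ** 2 * V / vk,
        "BMR~kC": cov**2 / (vb * vk),
    }


def generate_age_mass(
    params: GrowthCurveParams,
    n: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    span: tuple[float, float] = (-4.0, 4.0),
    truncate_pre_inflection: bool = False,
) -> AgeMassSeries:
    """Sigmoid age–mass series with multiplicative Gaussian noise.

    ``span`` gives the age window in units of the dimensionless variable
    s = k (t - t_c); truncation to s < 0 emulates fossil series that stop
    before the inflection point, where the asymptote is an extrapolation.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    lo, hi = span
    if truncate_pre_inflection:
        hi = min(hi, 0.0)
    s = np.linspace(lo, hi, n)
    ages = params.t_c + s / params.k
    masses = predict_mass(params, ages)
    if noise_sd > 0:
        masses = masses * (1.0 + rng.normal(0, noise_sd, n))
    masses = np.maximum(masses, 1e-9)
    return AgeMassSeries(taxon="synthetic", ages=ages, masses=masses)
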