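"""Curvature analysis of growth-rate allometry via AICc model selection.

Log-log growth-rate data are fit with a family of polynomial models in
log10 mass (all intercept-containing subsets of {x, x², x³}) and ranked by
the small-sample-corrected Akaike information criterion.  A simple power
law corresponds to the linear model; ΔAICc = 0 marks the best model per
group, and ΔAICc < 2 conventionally marks strong support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PolyModelSpec",
    "DEFAULT_FAMILY",
    "fit_poly",
    "aicc",
    "selection_table",
]


@dataclass(frozen=True)
class PolyModelSpec:
    """A polynomial regression model: intercept plus a subset of x-powers."""

    label: str
    powers: tuple[int, ...]

    @property
    def n_coef(self) -> int:
        return 1 + len(self.powers)


#: the seven intercept-containing nonempty subsets of {x, x², x³}
DEFAULT_FAMILY: tuple[PolyModelSpec, ...] = (
    PolyModelSpec("linear", (1,)),
    PolyModelSpec("quadratic1", (1, 2)),
    PolyModelSpec("quadratic2", (2,)),
    PolyModelSpec("cubic1", (1, 2, 3)),
    PolyModelSpec("cubic2", (1, 3)),
    PolyModelSpec("cubic3", (2, 3)),
    PolyModelSpec("cubic4", (3,)),
)


def _design(x: np.ndarray, spec: PolyModelSpec) -> np.ndarray:
    return np.column_stack([np.ones_like(x)] + [x**p for p in spec.powers])


def fit_poly(
    x: np.ndarray,
    y: np.ndarray,
    spec: PolyModelSpec,
    weights: Optional[np.ndarray] = None,
) -> dict:
    """Least-squares fit of y = β0 + Σ βp x^p over the included powers.

    Returns coefficients (intercept first, then in ``spec.powers`` order)
    and the (weighted) residual sum of squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if len(x) <= spec.n_coef:
        raise ValueError(
            f"{spec.label}: need more than {spec.n_coef} points, got {len(x)}"
        )
    X = _design(x, spec)
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"{spec.label}: rank-deficient design matrix")
    resid = y - X @ beta
    return {"coefficients": beta, "rss": float(np.sum(w * resid**2)), "spec": spec}


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected AIC for a Gaussian-likelihood least-squares fit.

    AICc = n ln(rss/n) + 2k + 2k(k+1)/(n-k-1), where k counts the
    regression coefficients plus one for the residual variance.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n must exceed k+1)")
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def selection_table(
    groups: Mapping[str, tuple[np.ndarray, np.ndarray]],
    family: Sequence[PolyModelSpec] = DEFAULT_FAMILY,
    weights: Optional[Mapping[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """Per-group AICc ranking of the polynomial family.

    ``groups`` maps group label to (x, y) arrays of log10 mass and log10
    rate.  Returns a long-format table with rss, k, AICc, ΔAICc relative to
    the group minimum, and a strong-support flag (ΔAICc < 2).  Inadmissible
    models (n ≤ k+1) are reported with NaN AICc.  Ties for the minimum are
    broken toward the smaller k.
    """
    if not family:
        raise ValueError("model family must be nonempty")
    rows = []
    for g, (x, y) in groups.items():
        w = None if weights is None else weights.get(g)
        n = len(x)
        group_rows = []
        for spec in family:
            k = spec.n_coef + 1  # +1 residual-variance parameter
            try:
                fit = fit_poly(x, y, spec, w)
                val = aicc(fit["rss"], n, k)
                rss = fit["rss"]
            except ValueError:
                val, rss = np.nan, np.nan
            group_rows.append(
                {"group": g, "model": spec.label, "rss": rss, "k": k, "n": n,
                 "aicc": val}
            )
        finite = [r for r in group_rows if np.isfinite(r["aicc"])]
        if finite:
            best = min(finite, key=lambda r: (r["aicc"], r["k"]))["aicc"]
        else:
            best = np.nan
        for r in group_rows:
            r["delta_aicc"] = r["aicc"] - best if np.isfinite(r["aicc"]) else np.nan
            r["strong_support"] = (
                bool(r["delta_aicc"] < 2) if np.isfinite(r["delta_aicc"]) else False
            )
        rows.extend(group_rows)
    return pd.DataFrame(rows)


def delta_aicc_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a selection table to groups x model labels of ΔAICc values."""
    return table.pivot(index="group", columns="model", values="delta_aicc")
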