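"""CSV readers/writers for the pipeline's table schemas and the pipeline
orchestrator.

Schemas (comma-separated, UTF-8, header row, '.' decimal, NA for blanks):

* rate table: ``taxon, group, thermo, M_g, BMatMG_g, Gmax_g_per_day,
  kC_per_day, kD_per_day, weight, excluded`` (+ optional ``model``).
  Blank rate cells are filled from the algebraic identities
  ``Gmax = M * kC``, ``BMatMG = M * d``, ``kD = Gmax / BMatMG`` when a
  model column makes ``d`` known; per-taxon weights are normalised so each
  taxon's points sum to one.
* age–mass series: ``taxon, age_days, mass_g, provenance``.
* metabolic table: ``taxon, group, thermo, BMR_W, M_met_g, M_g,
  Gmax_g_per_day, kC_per_day``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import model_selection, overlap
from .allometry import (
    RatePoint,
    compare_dependent_variables,
    fit_loglog,
    fixed_slope_adjust,
    points_to_frame,
)
from .growth_models import AgeMassSeries, get_model
from .metabolic import MetabolicRecord, direct_test, transitivity_report

__all__ = [
    "read_rate_table",
    "write_rate_table",
    "read_age_mass_series",
    "read_metabolic_table",
    "run_pipeline",
    "SchemaError",
]

RATE_COLUMNS = [
    "taxon", "group", "thermo", "M_g", "BMatMG_g", "Gmax_g_per_day",
    "kC_per_day", "kD_per_day", "weight", "excluded",
]


class SchemaError(ValueError):
    """A required column is missing or a row fails validation."""


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_rate_table(path) -> list[RatePoint]:
    """Read and validate a rate-table CSV into RatePoints.

    Derivable blanks are filled; weights are normalised per taxon.
    """
    df = pd.read_csv(path)
    _require(df, ["taxon", "group", "M_g"], path)
    points: list[RatePoint] = []
    for _, row in df.iterrows():
        taxon = str(row["taxon"])
        M = row["M_g"]
        if pd.isna(M) or M <= 0:
            raise SchemaError(f"{path}: non-positive or missing mass for {taxon}")
        d = None
        if "model" in df.columns and not pd.isna(row.get("model")):
            d = get_model(str(row["model"])).d
        gmax = row.get("Gmax_g_per_day")
        kc = row.get("kC_per_day")
        kd = row.get("kD_per_day")
        bmatmg = row.get("BMatMG_g")
        gmax = None if pd.isna(gmax) else float(gmax)
        kc = None if pd.isna(kc) else float(kc)
        kd = None if pd.isna(kd) else float(kd)
        bmatmg = None if bmatmg is None or pd.isna(bmatmg) else float(bmatmg)
        # fill via Gmax = M*kC, BMatMG = M*d, kD = Gmax/BMatMG
        if gmax is None and kc is not None:
            gmax = M * kc
        if kc is None and gmax is not None:
            kc = gmax / M
        if bmatmg is None and d is not None:
            bmatmg = M * d
        if kd is None and gmax is not None and bmatmg is not None:
            kd = gmax / bmatmg
        for val, name in ((gmax, "Gmax"), (kc, "kC"), (kd, "kD")):
            if val is not None and val <= 0:
                raise SchemaError(f"{path}: non-positive rate {name} for {taxon}")
        thermo = row.get("thermo")
        excluded = row.get("excluded")
        weight = row.get("weight")
        points.append(
            RatePoint(
                taxon=taxon,
                group=str(row["group"]),
                thermo="unknown" if pd.isna(thermo) else str(thermo),
                M=float(M),
                BMatMG=bmatmg,
                rate_Gmax=gmax,
                rate_kC=kc,
                rate_kD=kd,
                weight=1.0 if weight is None or pd.isna(weight) else float(weight),
                excluded=bool(excluded) if not pd.isna(excluded) else False,
            )
        )
    # per-taxon weight normalisation: each taxon's points sum to 1
    counts: dict[str, float] = {}
    for p in points:
        counts[p.taxon] = counts.get(p.taxon, 0.0) + p.weight
    for p in points:
        if counts[p.taxon] > 0:
            p.weight = p.weight / counts[p.taxon]
    return points


def write_rate_table(points: Sequence[RatePoint], path) -> None:
    points_to_frame(points).to_csv(path, index=False, na_rep="NA")


def read_age_mass_series(path) -> dict[str, AgeMassSeries]:
    """Read age–mass CSV into one series per taxon."""
    df = pd.read_csv(path)
    _require(df, ["taxon", "age_days", "mass_g"], path)
    if "provenance" not in df.columns:
        df["provenance"] = "observed"
    df["provenance"] = df["provenance"].fillna("observed")
    out = {}
    for taxon, sub in df.groupby("taxon", sort=False):
        out[str(taxon)] = AgeMassSeries(
            taxon=str(taxon),
            ages=sub["age_days"].to_numpy(float),
            masses=sub["mass_g"].to_numpy(float),
            point_provenance=list(sub["provenance"]),
        )
    return out


def read_metabolic_table(path) -> list[MetabolicRecord]:
    df = pd.read_csv(path)
    _require(df, ["taxon", "group", "BMR_W", "M_met_g", "M_g"], path)
    records = []
    for _, row in df.iterrows():
        gmax = row.get("Gmax_g_per_day")
        kc = row.get("kC_per_day")
        thermo = row.get("thermo")
        records.append(
            MetabolicRecord(
                taxon=str(row["taxon"]),
                group=str(row["group"]),
                thermo="unknown" if pd.isna(thermo) else str(thermo),
                BMR=float(row["BMR_W"]),
                M_met=float(row["M_met_g"]),
                M=float(row["M_g"]),
                G_max=None if pd.isna(gmax) else float(gmax),
                kC=None if pd.isna(kc) else float(kc),
            )
        )
    return records


def _fit_summary(fit) -> dict:
    return {
        "dependent": fit.dependent,
        "independent": fit.independent,
        "intercept": fit.intercept,
        "slope": fit.slope,
        "ci95_slope": list(fit.ci95_slope),
        "ci95_intercept": list(fit.ci95_intercept),
        "r2": fit.r2,
        "n": fit.n,
        "weighted": fit.weighted,
    }


def run_pipeline(
    rate_table: Optional[str] = None,
    metabolic_table: Optional[str] = None,
    out_dir: str = "run",
    dependent: str = "kC",
    independent: str = "M",
    fixed_slopes: Sequence[float] = (0.75, 0.66),
    include_excluded: bool = False,
    seed: int = 0,
) -> dict:
    """Run every analysis stage for which inputs are available.

    Without a rate table, a default synthetic scenario is generated from
    ``seed``.  Writes CSV/JSON reports plus a manifest under ``out_dir``
    and returns the report bundle.
    """
    from .synthetic_data import (
        DEFAULT_GROUPS,
        MetabGenSpec,
        generate_groups,
        generate_metabolic,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": []}

    if rate_table is not None:
        points = read_rate_table(rate_table)
        manifest["rate_table"] = str(rate_table)
        manifest["rate_table_sha256"] = hashlib.sha256(
            Path(rate_table).read_bytes()
        ).hexdigest()
    else:
        groups_pts = generate_groups(DEFAULT_GROUPS, seed=seed)
        points = [p for pts in groups_pts.values() for p in pts]
        write_rate_table(points, out / "synthetic_rate_table.csv")
        manifest["rate_table"] = "synthetic"

    groups: dict[str, list[RatePoint]] = {}
    for p in points:
        groups.setdefault(p.group, []).append(p)

    bundle: dict = {}

    # per-group regressions and the shear comparison
    regressions = {}
    fits = {}
    for g, pts in groups.items():
        try:
            rep = compare_dependent_variables(pts, independent)
        except ValueError:
            continue
        fits[g] = fit_loglog(pts, dependent, independent,
                             include_excluded=include_excluded)
        regressions[g] = {
            "fit": _fit_summary(fits[g]),
            "slope_Gmax": rep["slope_Gmax"],
            "slope_kC": rep["slope_kC"],
            "r2_Gmax": rep["r2_Gmax"],
            "r2_kC": rep["r2_kC"],
        }
    bundle["regressions"] = regressions
    manifest["stages"].append("allometry")

    # overlap machinery
    mat = overlap.hull_membership_matrix(groups, dependent, independent)
    mat.to_csv(out / "hull_membership.csv")
    nl = overlap.nearest_line_classification(groups, fits, dependent, independent)
    nl.to_csv(out / "nearest_line.csv")
    bundle["hull_membership"] = mat
    bundle["nearest_line"] = nl
    manifest["stages"].append("overlap")

    # fixed-slope mass-adjusted rates
    adjusted = {}
    for b in fixed_slopes:
        adj = fixed_slope_adjust(points, b=b, dependent="Gmax",
                                 independent=independent)
        adj["adjusted"].to_csv(out / f"adjusted_b{b}.csv", index=False)
        adjusted[str(b)] = adj["overlap_interval"]
    bundle["fixed_slope_overlap"] = adjusted
    manifest["stages"].append("fixed_slope")

    # curvature model selection
    sel_groups = {}
    sel_weights = {}
    for g, pts in groups.items():
        kept = [p for p in pts if include_excluded or not p.excluded]
        sel_groups[g] = (
            np.log10([p.mass(independent) for p in kept]),
            np.log10([p.rate(dependent) for p in kept]),
        )
        sel_weights[g] = np.array([p.weight for p in kept])
    table = model_selection.selection_table(sel_groups, weights=sel_weights)
    table.to_csv(out / "model_selection.csv", index=False)
    model_selection.delta_aicc_matrix(table).round(3).to_csv(
        out / "delta_aicc_matrix.csv"
    )
    bundle["model_selection"] = table
    manifest["stages"].append("model_selection")

    # metabolic stage
    records = None
    if metabolic_table is not None:
        records = read_metabolic_table(metabolic_table)
    elif rate_table is None:
        spec = MetabGenSpec(seed=(seed * 1000 + 99) % (2**31))
        rng = np.random.default_rng(spec.seed)
        masses = 10.0 ** rng.uniform(0, 5, 120)
        records = generate_metabolic(masses, spec, rng)
    if records is not None:
        rep = transitivity_report(records)
        dt = direct_test(records)
        bundle["metabolic"] = {
            "transitivity": {k: _fit_summary(f) for k, f in rep.items()},
            "direct_test": {
                "over_factor": dt.over_factor,
                "under_factor": dt.under_factor,
                "total_range": dt.total_range,
                "n": dt.n,
            },
        }
        manifest["stages"].append("metabolic")

    json_bundle = {
        k: v for k, v in bundle.items()
        if k in ("regressions", "fixed_slope_overlap", "metabolic")
    }
    (out / "report.json").write_text(json.dumps(json_bundle, indent=2, default=str))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
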