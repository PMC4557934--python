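"""Cross-platform summaries: means +/- SE, OLS regressions, taxon tables."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import life_history as lh
from .io_formats import PlatformGeometry, RunConfig
from .survey_metrics import (
    recruitment_production_density,
    somatic_production_density,
    ssb_density,
    transect_area,
)

__all__ = [
    "RegressionFit",
    "mean_se",
    "ols_depth_area",
    "log10_regressions",
    "per_taxon_overall",
    "taxon_contributions",
]


@dataclass(frozen=True)
class RegressionFit:
    """Simple (one-predictor) ordinary least-squares fit."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int


def mean_se(values) -> tuple[float, float | None]:
    """Arithmetic mean and sample standard error; SE is None for n = 1."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_se of an empty collection")
    if arr.size == 1:
        return float(arr[0]), None
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def _simple_ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    n = len(x)
    if n < 3:
        raise ValueError(f"simple OLS needs >= 3 points, got {n}")
    if np.ptp(y) == 0:
        # constant response: zero slope, no variance explained
        return RegressionFit(
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            f_stat=0.0,
            df=(1, n - 2),
            p_value=1.0,
            n=n,
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        p_value=float(model.f_pvalue),
        n=n,
    )


def ols_depth_area(geometries: list[PlatformGeometry]) -> RegressionFit:
    """Regress total submerged structural surface area on seafloor depth.

    Total area is shallow + midwater + base.  Deeper platforms need more
    jacket, so area scales roughly linearly with seafloor depth.
    """
    depth = np.array([g.seafloor_depth_m for g in geometries], dtype=float)
    area = np.array([g.total_surface_area for g in geometries], dtype=float)
    return _simple_ols(depth, area)


def log10_regressions(
    overall: pd.DataFrame, geometries: list[PlatformGeometry]
) -> tuple[RegressionFit, RegressionFit]:
    """OLS of log10 overall SSB and log10 production on total surface area.

    ``overall`` needs columns ``platform``, ``ssb_kg``, ``production_kg_yr``
    (complete-platform means).  Non-positive metrics make the log
    undefined and raise.
    """
    areas = {g.platform: g.total_surface_area for g in geometries}
    merged = overall.assign(area=overall["platform"].map(areas)).dropna(subset=["area"])
    if (merged[["ssb_kg", "production_kg_yr"]] <= 0).any().any():
        raise ValueError("log10 regression requires strictly positive SSB and production")
    x = merged["area"].to_numpy(float)
    ssb_fit = _simple_ols(x, np.log10(merged["ssb_kg"].to_numpy(float)))
    prod_fit = _simple_ols(x, np.log10(merged["production_kg_yr"].to_numpy(float)))
    return ssb_fit, prod_fit


def per_taxon_overall(
    survey: pd.DataFrame,
    params_table: dict[str, lh.TaxonParameters],
    geometries: list[PlatformGeometry],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Mean annual overall SSB (kg) and production (kg/yr) per taxon per platform.

    Built from observed records only — proxy-filled habitat-years are by
    construction absent, so these totals reflect species actually seen on
    each platform.  Shell-mound records are excluded.
    """
    config = config or RunConfig()
    geom_by_platform = {g.platform: g for g in geometries}
    records = []
    platform_rows = survey[survey["habitat"] != "shellmound"]
    for platform, pgroup in platform_rows.groupby("platform"):
        geom = geom_by_platform.get(platform)
        if geom is None:
            raise ValueError(f"no geometry for platform {platform!r}")
        years = sorted(pgroup["year"].unique())
        per_taxon_year: dict[str, dict[int, dict[str, float]]] = {}
        for (habitat, year), hgroup in pgroup.groupby(["habitat", "year"]):
            area_structure = geom.structure_area(habitat)
            for taxon, tgroup in hgroup.groupby("taxon"):
                # densities need the full slice's transect area, so rebuild a
                # one-taxon slice that keeps the slice's pooled transect length
                ssb = ssb_density(tgroup, params_table, config)
                somatic = somatic_production_density(tgroup, params_table, config)
                recruit = recruitment_production_density(tgroup, params_table, config)
                slot = per_taxon_year.setdefault(taxon, {}).setdefault(
                    int(year), {"ssb": 0.0, "prod": 0.0}
                )
                slot["ssb"] += ssb * area_structure
                slot["prod"] += (somatic + recruit) * area_structure
        for taxon, by_year in per_taxon_year.items():
            ssb_mean = sum(by_year.get(y, {"ssb": 0.0})["ssb"] for y in years) / len(years)
            prod_mean = sum(by_year.get(y, {"prod": 0.0})["prod"] for y in years) / len(years)
            records.append(
                {
                    "platform": platform,
                    "taxon": taxon,
                    "ssb_kg": ssb_mean,
                    "production_kg_yr": prod_mean,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["platform", "taxon", "ssb_kg", "production_kg_yr"]
    )


def taxon_contributions(per_taxon: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Percent contribution of each taxon to platform SSB and production.

    Percentages are of the platform totals over *all* taxa; only taxa
    contributing at least ``threshold`` percent of Total Production are
    kept in the table (dropped taxa still count in the denominators).
    Sorted by production contribution within platform.
    """
    if per_taxon.empty:
        return pd.DataFrame(columns=["platform", "taxon", "pct_ssb", "pct_production"])
    out = []
    for platform, group in per_taxon.groupby("platform"):
        tot_ssb = group["ssb_kg"].sum()
        tot_prod = group["production_kg_yr"].sum()
        pct = group.assign(
            pct_ssb=100.0 * group["ssb_kg"] / tot_ssb if tot_ssb > 0 else 0.0,
            pct_production=100.0 * group["production_kg_yr"] / tot_prod if tot_prod > 0 else 0.0,
        )
        pct = pct[pct["pct_production"] >= threshold]
        out.append(pct.sort_values("pct_production", ascending=False))
    return (
        pd.concat(out, ignore_index=True)[["platform", "taxon", "pct_ssb", "pct_production"]]
        if out
        else pd.DataFrame(columns=["platform", "taxon", "pct_ssb", "pct_production"])
    )
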