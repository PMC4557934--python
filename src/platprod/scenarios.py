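"""Decommissioning scenario accounting.

Density metrics (per m^2 of structure) are combined with structural
surface areas to give overall platform metrics in kg and kg/yr, per year
and then averaged.  Three entities are accounted:

* **complete** platform — shallow + midwater + base habitats;
* **partially removed** platform — midwater + base only (structure above
  the cut depth removed, and with it the fish observed there);
* **shell mound** — the biogenic reef around the platform base, where its
  areal extent is known.

Habitat-years that could not be surveyed are filled in first: missing
years of an otherwise-surveyed habitat take the mean of that habitat's
available annual values, and never-surveyed habitats borrow density
metrics from designated donor platforms (areas always come from the
recipient's own geometry).  Retention after partial removal is computed
per year and then averaged; a ratio-of-mean-values variant is reported
alongside because published summary tables are built from means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PlatformGeometry, PLATFORM_HABITATS
from .platform_geometry import per_seafloor_density
from .summary_stats import mean_se
from .survey_metrics import METRIC_COLUMNS

__all__ = [
    "ProxyRules",
    "ScenarioResult",
    "impute_missing",
    "annual_overall",
    "overall_metrics",
    "partial_removal_summary",
    "shellmound_overall",
    "mound_loss_fraction",
    "combined_loss_fraction",
    "mean_se",
]

DENSITY_COLUMNS = ["ssb_density", "somatic_density", "recruit_density", "total_density"]

#: Platforms whose base habitat was never surveyed borrow Holly's mean
#: base densities (geographic proximity and habitat similarity).
DEFAULT_BASE_PROXY = {"A": "Holly", "B": "Holly", "Hillhouse": "Holly", "Habitat": "Holly"}
#: Northernmost platforms' shallow habitat borrows the average of the
#: southern platforms' shallow densities.
DEFAULT_SHALLOW_PROXY = {
    p: ("Holly", "B", "A", "Hillhouse", "Habitat")
    for p in ("Irene", "Hidalgo", "Harvest", "Hermosa")
}


@dataclass(frozen=True)
class ProxyRules:
    """Donor rules for never-surveyed platform habitats."""

    base_proxy: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BASE_PROXY))
    shallow_proxy: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SHALLOW_PROXY)
    )

    def __post_init__(self) -> None:
        for recipient, donor in self.base_proxy.items():
            if donor == recipient:
                raise ValueError(f"base proxy donor equals recipient: {recipient}")
        for recipient, donors in self.shallow_proxy.items():
            if recipient in donors:
                raise ValueError(f"shallow proxy donors include recipient: {recipient}")

    def donors_for(self, platform: str, habitat: str) -> tuple[str, ...] | None:
        if habitat == "base" and platform in self.base_proxy:
            return (self.base_proxy[platform],)
        if habitat == "shallow" and platform in self.shallow_proxy:
            return tuple(self.shallow_proxy[platform])
        return None


@dataclass(frozen=True)
class ScenarioResult:
    """Overall metrics for one platform under one scenario.

    ``ssb`` (kg) and ``total_production`` (kg/yr) are means of annual
    values with sample standard errors over years (``None`` for a single
    year).  Retention percentages compare partial to complete removal
    (only populated on partial results): ``retention_*`` is the mean of
    per-year percentages, ``retention_*_of_means`` the ratio of the two
    scenario means.  Per-seafloor values scale the overall metrics by the
    platform footprint, in g/m^2 (g/m^2/yr).  ``None`` metrics mean the
    entity could not be quantified (unknown shell-mound extent).
    """

    platform_id: str
    scenario: str
    ssb: float | None
    total_production: float | None
    ssb_se: float | None = None
    production_se: float | None = None
    n_years: int = 0
    retention_ssb: float | None = None
    retention_production: float | None = None
    retention_ssb_of_means: float | None = None
    retention_production_of_means: float | None = None
    per_seafloor_ssb: float | None = None
    per_seafloor_production: float | None = None


# ---------------------------------------------------------------------------
# imputation


def _imputed_row(platform: str, habitat: str, year: int, densities: pd.Series) -> dict:
    row = {
        "platform": platform,
        "habitat": habitat,
        "year": int(year),
        "surveyed_area": np.nan,
        "imputed": True,
    }
    row.update({c: float(densities[c]) for c in DENSITY_COLUMNS})
    return row


def impute_missing(metrics: pd.DataFrame, rules: ProxyRules | None = None) -> pd.DataFrame:
    """Complete the platform-habitat x year grid of density metrics.

    Every platform must end with all three platform habitats present for
    every year it was surveyed (in any habitat).  Gap years take the mean
    of the habitat's own annual values; never-surveyed habitats take donor
    platforms' mean densities per :class:`ProxyRules` (averaged across
    donors when there are several).  Added rows are flagged ``imputed``.
    Shell-mound records pass through untouched: mound metrics are means
    over the years the mound itself was surveyed.
    """
    rules = rules or ProxyRules()
    metrics = metrics.copy()
    platform_rows = metrics[metrics["habitat"].isin(PLATFORM_HABITATS)]
    added: list[dict] = []
    for platform, group in platform_rows.groupby("platform"):
        years = sorted(group["year"].unique())
        for habitat in PLATFORM_HABITATS:
            hab = group[group["habitat"] == habitat]
            if not hab.empty:
                observed_years = set(hab["year"])
                fill = hab[DENSITY_COLUMNS].mean()
                for year in years:
                    if year not in observed_years:
                        added.append(_imputed_row(platform, habitat, year, fill))
                continue
            donors = rules.donors_for(platform, habitat)
            if donors is None:
                raise ValueError(
                    f"platform {platform!r} habitat {habitat!r}: never surveyed "
                    "and no proxy rule applies"
                )
            donor_means = []
            for donor in donors:
                rows = platform_rows[
                    (platform_rows["platform"] == donor) & (platform_rows["habitat"] == habitat)
                ]
                if rows.empty:
                    raise ValueError(
                        f"proxy donor {donor!r} has no {habitat!r} data for {platform!r}"
                    )
                donor_means.append(rows[DENSITY_COLUMNS].mean())
            fill = pd.concat(donor_means, axis=1).mean(axis=1)
            for year in years:
                added.append(_imputed_row(platform, habitat, year, fill))
    if added:
        metrics = pd.concat(
            [metrics, pd.DataFrame.from_records(added, columns=METRIC_COLUMNS)],
            ignore_index=True,
        )
    return metrics.sort_values(["platform", "habitat", "year"], ignore_index=True)


# ---------------------------------------------------------------------------
# overall platform metrics

SCENARIO_HABITATS = {
    "complete": ("shallow", "midwater", "base"),
    "partial": ("midwater", "base"),
}


def annual_overall(
    metrics: pd.DataFrame, geometry: PlatformGeometry, habitats: tuple[str, ...]
) -> pd.DataFrame:
    """Per-year overall kg and kg/yr for one platform over given habitats.

    Each year's overall value is the sum over habitats of density times
    the habitat's structural surface area.
    """
    rows = metrics[
        (metrics["platform"] == geometry.platform) & metrics["habitat"].isin(habitats)
    ]
    if rows.empty:
        raise ValueError(f"no metrics for platform {geometry.platform!r}")
    missing = set(habitats) - set(rows["habitat"])
    if missing:
        raise ValueError(f"platform {geometry.platform!r} lacks habitat(s) {sorted(missing)}")
    out = []
    for year, group in rows.groupby("year"):
        ssb = prod = 0.0
        for r in group.itertuples(index=False):
            area = geometry.structure_area(r.habitat)
            ssb += r.ssb_density * area
            prod += r.total_density * area
        out.append({"year": int(year), "ssb_kg": ssb, "production_kg_yr": prod})
    return pd.DataFrame(out).sort_values("year", ignore_index=True)


def overall_metrics(
    metrics: pd.DataFrame,
    geometries: list[PlatformGeometry],
    scenario: str,
) -> list[ScenarioResult]:
    """Mean +/- SE overall metrics for every platform under one scenario."""
    if scenario not in SCENARIO_HABITATS:
        raise ValueError(f"unknown scenario {scenario!r}")
    habitats = SCENARIO_HABITATS[scenario]
    results = []
    for geom in geometries:
        annual = annual_overall(metrics, geom, habitats)
        ssb, ssb_se = mean_se(annual["ssb_kg"])
        prod, prod_se = mean_se(annual["production_kg_yr"])
        results.append(
            ScenarioResult(
                platform_id=geom.platform,
                scenario=scenario,
                ssb=ssb,
                total_production=prod,
                ssb_se=ssb_se,
                production_se=prod_se,
                n_years=len(annual),
                per_seafloor_ssb=per_seafloor_density(ssb, geom.footprint_m2),
                per_seafloor_production=per_seafloor_density(prod, geom.footprint_m2),
            )
        )
    return results


def _retention(partial: pd.Series, complete: pd.Series) -> float:
    """Mean over years of 100 * partial / complete."""
    return float((100.0 * partial / complete).mean())


def partial_removal_summary(
    metrics: pd.DataFrame, geometries: list[PlatformGeometry]
) -> list[ScenarioResult]:
    """Partial-removal results with retention relative to the complete platform.

    Retention is the mean of per-year percentages; the ratio of the two
    scenario means is reported alongside (``*_of_means``).  Per-year
    additivity (complete = partial + shallow contribution) holds exactly
    by construction.
    """
    results = []
    for geom in geometries:
        complete = annual_overall(metrics, geom, SCENARIO_HABITATS["complete"])
        partial = annual_overall(metrics, geom, SCENARIO_HABITATS["partial"])
        if not complete["year"].equals(partial["year"]):
            raise ValueError(f"year mismatch between scenarios for {geom.platform!r}")
        ssb, ssb_se = mean_se(partial["ssb_kg"])
        prod, prod_se = mean_se(partial["production_kg_yr"])
        c_ssb = complete["ssb_kg"].mean()
        c_prod = complete["production_kg_yr"].mean()
        results.append(
            ScenarioResult(
                platform_id=geom.platform,
                scenario="partial",
                ssb=ssb,
                total_production=prod,
                ssb_se=ssb_se,
                production_se=prod_se,
                n_years=len(partial),
                retention_ssb=_retention(partial["ssb_kg"], complete["ssb_kg"]),
                retention_production=_retention(
                    partial["production_kg_yr"], complete["production_kg_yr"]
                ),
                retention_ssb_of_means=float(100.0 * ssb / c_ssb),
                retention_production_of_means=float(100.0 * prod / c_prod),
                per_seafloor_ssb=per_seafloor_density(ssb, geom.footprint_m2),
                per_seafloor_production=per_seafloor_density(prod, geom.footprint_m2),
            )
        )
    return results


def shellmound_overall(
    metrics: pd.DataFrame, geometry: PlatformGeometry
) -> ScenarioResult:
    """Overall shell-mound metrics, or an unavailable result without an area.

    Annual mound densities are scaled by the mound's areal extent; an
    unknown extent yields ``None`` metrics (densities may still exist).
    """
    rows = metrics[
        (metrics["platform"] == geometry.platform) & (metrics["habitat"] == "shellmound")
    ]
    if rows.empty or geometry.shellmound_m2 is None:
        return ScenarioResult(
            platform_id=geometry.platform, scenario="shellmound", ssb=None, total_production=None
        )
    area = geometry.shellmound_m2
    ssb, ssb_se = mean_se(rows["ssb_density"] * area)
    prod, prod_se = mean_se(rows["total_density"] * area)
    return ScenarioResult(
        platform_id=geometry.platform,
        scenario="shellmound",
        ssb=ssb,
        total_production=prod,
        ssb_se=ssb_se,
        production_se=prod_se,
        n_years=len(rows),
    )


# ---------------------------------------------------------------------------
# loss fractions


def mound_loss_fraction(partial_production: float, mound_production: float) -> float:
    """Percent of the partially-removed entity's production lost with the mound.

    100 * mound / (partial platform + mound): the additional reduction if
    the shell mound around a partially removed platform were lost entirely.
    """
    if partial_production < 0 or mound_production < 0:
        raise ValueError("production inputs must be >= 0")
    total = partial_production + mound_production
    if total == 0:
        raise ValueError("loss fraction undefined: platform and mound production both zero")
    return 100.0 * mound_production / total


def combined_loss_fraction(
    complete_production: float, shallow_production: float, mound_production: float
) -> float:
    """Percent of combined platform + mound production lost under partial
    removal with total mound loss.

    100 * (shallow + mound) / (complete + mound): the shallow structure's
    production goes with the removed structure and the mound's with the
    mound.
    """
    if min(complete_production, shallow_production, mound_production) < 0:
        raise ValueError("production inputs must be >= 0")
    if shallow_production > complete_production:
        raise ValueError("shallow production cannot exceed the complete platform's")
    denom = complete_production + mound_production
    if denom == 0:
        raise ValueError("loss fraction undefined: zero combined production")
    return 100.0 * (shallow_production + mound_production) / denom
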