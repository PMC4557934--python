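"""Survey counts to per-m^2 annual density metrics.

Each platform x habitat x year slice of the survey is reduced to four
densities over the belt-transect area surveyed that year:

* standing-stock biomass (SSB), kg/m^2 — observed counts times weight at
  the recorded length;
* somatic production, kg/m^2/yr — survivorship-discounted one-year growth
  of the fish present;
* recruitment production, kg/m^2/yr — standing biomass of individuals
  small enough to have settled within the year (at or below one interval
  of growth from the settlement length);
* total production = somatic + recruitment.

Counts are pooled across a year's transects before dividing by the pooled
area (total count / total area), matching an annual-density design where
survey effort tracks structure area.  Length classes enter the formulas
at their nominal recorded value.
"""

from __future__ import annotations

import pandas as pd

from . import life_history as lh
from .io_formats import RunConfig

__all__ = [
    "transect_area",
    "ssb_density",
    "somatic_production_density",
    "recruitment_production_density",
    "habitat_year_metrics",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "platform",
    "habitat",
    "year",
    "ssb_density",
    "somatic_density",
    "recruit_density",
    "total_density",
    "surveyed_area",
    "imputed",
]


def transect_area(observations: pd.DataFrame, width: float = 2.0) -> float:
    """Total belt-transect area (m^2) for one platform x habitat x year.

    With a ``transect_id`` column, distinct transects' length x width are
    summed; otherwise the rows must share one pooled transect length.
    """
    if width <= 0:
        raise ValueError(f"transect width must be > 0, got {width}")
    if observations.empty:
        raise ValueError("no observations: transect area undefined")
    if "transect_id" in observations.columns:
        lengths = observations.groupby("transect_id")["transect_length_m"].first()
        area = float(lengths.sum()) * width
    else:
        lengths = observations["transect_length_m"].unique()
        if len(lengths) != 1:
            raise ValueError(
                "rows without transect_id must share one pooled transect length; "
                f"got {sorted(lengths)}"
            )
        area = float(lengths[0]) * width
    if area <= 0:
        raise ValueError("total surveyed area must be > 0")
    return area


def _resolve(observations: pd.DataFrame, params_table, config: RunConfig):
    """Yield (params, length, count) triples with proxies resolved."""
    for row in observations.itertuples(index=False):
        params = lh.resolve_taxon(row.taxon, params_table, config.proxy_map)
        yield params, float(row.length_class_cm), int(row.count)


def ssb_density(
    observations: pd.DataFrame,
    params_table: dict[str, lh.TaxonParameters],
    config: RunConfig | None = None,
) -> float:
    """Standing-stock biomass density, kg/m^2, for one habitat-year slice."""
    config = config or RunConfig()
    if observations.empty:
        return 0.0
    area = transect_area(observations, config.transect_width)
    grams = sum(
        count * lh.weight_at_length(L, params)
        for params, L, count in _resolve(observations, params_table, config)
    )
    return grams / 1000.0 / area


def somatic_production_density(
    observations: pd.DataFrame,
    params_table: dict[str, lh.TaxonParameters],
    config: RunConfig | None = None,
) -> float:
    """Somatic production density, kg/m^2/yr, for one habitat-year slice."""
    config = config or RunConfig()
    if observations.empty:
        return 0.0
    area = transect_area(observations, config.transect_width)
    grams = sum(
        count * lh.individual_production(L, params, config.interval)
        for params, L, count in _resolve(observations, params_table, config)
    )
    return grams / 1000.0 / area


def recruitment_production_density(
    observations: pd.DataFrame,
    params_table: dict[str, lh.TaxonParameters],
    config: RunConfig | None = None,
) -> float:
    """Recruitment production density, kg/m^2/yr, for one habitat-year slice.

    Individuals at or below the taxon's recruit length threshold (one
    interval of growth from the settlement length) contribute their full
    observed standing biomass; larger individuals contribute nothing.
    """
    config = config or RunConfig()
    if observations.empty:
        return 0.0
    area = transect_area(observations, config.transect_width)
    grams = 0.0
    for params, L, count in _resolve(observations, params_table, config):
        threshold = lh.recruit_length_threshold(
            params, config.recruit_settlement_length, config.interval
        )
        if L <= threshold:
            grams += count * lh.weight_at_length(L, params)
    return grams / 1000.0 / area


def habitat_year_metrics(
    survey: pd.DataFrame,
    params_table: dict[str, lh.TaxonParameters],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """All four density metrics for every platform x habitat x year surveyed.

    Returns one row per slice with columns :data:`METRIC_COLUMNS`; the
    ``imputed`` flag is False here (filled-in slices are added later by the
    scenario layer).
    """
    config = config or RunConfig()
    records = []
    if survey.empty:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    for (platform, habitat, year), group in survey.groupby(
        ["platform", "habitat", "year"], sort=True
    ):
        somatic = somatic_production_density(group, params_table, config)
        recruit = recruitment_production_density(group, params_table, config)
        records.append(
            {
                "platform": platform,
                "habitat": habitat,
                "year": int(year),
                "ssb_density": ssb_density(group, params_table, config),
                "somatic_density": somatic,
                "recruit_density": recruit,
                "total_density": somatic + recruit,
                "surveyed_area": transect_area(group, config.transect_width),
                "imputed": False,
            }
        )
    return pd.DataFrame.from_records(records, columns=METRIC_COLUMNS)
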