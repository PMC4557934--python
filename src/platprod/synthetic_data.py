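"""Synthetic surveys with known ground truth.

The generator emits size-structured belt-transect counts for a set of
platforms, taxa and years from specified per-m^2 expected densities, with
an optional annual settlement pulse of recruits.  Three count models are
available:

* ``deterministic`` — counts are exactly density x transect area (the
  spec must make these integers, or generation fails with a suggested
  transect length); the pipeline then matches the closed-form oracle to
  numerical precision;
* ``poisson`` — independent Poisson counts with the same means, the
  classic model for transect counts of independently encountered fish;
* ``negative_binomial`` — Poisson-gamma overdispersed counts
  (``var = m + m^2/k``), mimicking patchy schooling.

:func:`expected_metrics` computes the analytic density metrics implied by
a spec, and :func:`expected_overall` the overall platform values — the
independent oracle against which the survey pipeline is checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import life_history as lh
from .io_formats import (
    PLATFORM_HABITATS,
    PlatformGeometry,
    RunConfig,
    geometry_frame,
)
from .survey_metrics import METRIC_COLUMNS

__all__ = ["SyntheticSpec", "generate_survey", "expected_metrics", "expected_overall",
           "write_inputs", "example_spec"]

DENSITY_COLUMNS = ["habitat", "taxon", "length_class_cm", "density_per_m2"]


@dataclass
class SyntheticSpec:
    """Ground truth for a synthetic multi-platform survey.

    ``densities`` holds expected fish per m^2 by habitat, taxon and 5-cm
    length class (applied identically to every platform and year);
    ``recruit_pulse`` adds an annual settlement pulse of that many recruits
    per m^2 in the smallest (5 cm) class per taxon.
    """

    platforms: list[PlatformGeometry]
    taxa: list[lh.TaxonParameters]
    densities: pd.DataFrame
    years: int = 1
    count_model: str = "deterministic"
    dispersion: float = 5.0
    transect_length: dict[str, float] = field(
        default_factory=lambda: {h: 100.0 for h in ("shallow", "midwater", "base", "shellmound")}
    )
    recruit_pulse: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0
    start_year: int = 2001

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.count_model not in ("deterministic", "poisson", "negative_binomial"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if (self.densities["density_per_m2"] < 0).any():
            raise ValueError("expected densities must be >= 0")

    @property
    def params_table(self) -> dict[str, lh.TaxonParameters]:
        return {t.taxon_code: t for t in self.taxa}

    def full_densities(self) -> pd.DataFrame:
        """Densities with the recruit pulse folded into the 5-cm class."""
        df = self.densities.copy()
        for taxon, pulse in self.recruit_pulse.items():
            for habitat in df["habitat"].unique():
                mask = (
                    (df["habitat"] == habitat)
                    & (df["taxon"] == taxon)
                    & (df["length_class_cm"] == 5)
                )
                if mask.any():
                    df.loc[mask, "density_per_m2"] += pulse
                else:
                    df = pd.concat(
                        [
                            df,
                            pd.DataFrame(
                                [{
                                    "habitat": habitat,
                                    "taxon": taxon,
                                    "length_class_cm": 5,
                                    "density_per_m2": pulse,
                                }]
                            ),
                        ],
                        ignore_index=True,
                    )
        return df

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        platforms = [PlatformGeometry(**p) for p in raw["platforms"]]
        taxa = [
            lh.TaxonParameters(
                taxon_code=t["taxon_code"],
                L_inf=t["L_inf"],
                K=t["K"],
                weight_a=t["weight_a"],
                weight_b=t["weight_b"],
                length_conversion=tuple(t["length_conversion"])
                if t.get("length_conversion")
                else None,
                transient=bool(t.get("transient", False)),
                proxy_for=tuple(t.get("proxy_for", ())),
            )
            for t in raw["taxa"]
        ]
        densities = pd.DataFrame(raw["densities"], columns=DENSITY_COLUMNS)
        kwargs = {
            k: raw[k]
            for k in (
                "years",
                "count_model",
                "dispersion",
                "transect_length",
                "recruit_pulse",
                "rng_seed",
                "start_year",
            )
            if k in raw
        }
        return cls(platforms=platforms, taxa=taxa, densities=densities, **kwargs)


def _draw_counts(mean: np.ndarray, model: str, dispersion: float, rng: np.random.Generator):
    if model == "poisson":
        return rng.poisson(mean)
    if model == "negative_binomial":
        p = dispersion / (dispersion + mean)
        return rng.negative_binomial(dispersion, p)
    raise ValueError(model)


def generate_survey(spec: SyntheticSpec, seed: int | None = None) -> pd.DataFrame:
    """Emit a survey observation table for the spec.

    Deterministic mode requires every expected count (density x transect
    area, width 2 m) to be an integer; otherwise a ``ValueError`` suggests
    a transect length that makes it one.  Stochastic modes are reproducible
    from the seed (``spec.rng_seed`` unless overridden).
    """
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    width = RunConfig().transect_width
    dens = spec.full_densities()
    rows = []
    years = range(spec.start_year, spec.start_year + spec.years)
    for geom in spec.platforms:
        for habitat in dens["habitat"].unique():
            tlen = spec.transect_length[habitat]
            area = tlen * width
            hd = dens[dens["habitat"] == habitat]
            means = hd["density_per_m2"].to_numpy(float) * area
            for year in years:
                if spec.count_model == "deterministic":
                    counts = np.rint(means)
                    bad = np.abs(counts - means) > 1e-9
                    if bad.any():
                        m = float(means[bad][0]) / area
                        raise ValueError(
                            "deterministic counts must be integers; density "
                            f"{m} with transect area {area} m^2 gives expectation "
                            f"{m * area}; choose a transect length that makes "
                            "density x length x width an integer"
                        )
                else:
                    counts = _draw_counts(means, spec.count_model, spec.dispersion, rng)
                for (_, drow), count in zip(hd.iterrows(), counts):
                    if count == 0:
                        continue
                    rows.append(
                        {
                            "platform": geom.platform,
                            "year": int(year),
                            "habitat": habitat,
                            "transect_length_m": tlen,
                            "taxon": drow["taxon"],
                            "length_class_cm": int(drow["length_class_cm"]),
                            "count": int(count),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "platform",
            "year",
            "habitat",
            "transect_length_m",
            "taxon",
            "length_class_cm",
            "count",
        ],
    )


def expected_metrics(spec: SyntheticSpec, config: RunConfig | None = None) -> pd.DataFrame:
    """Analytic density metrics implied by the spec (the pipeline oracle).

    One row per platform x habitat x year in the same shape as
    ``habitat_year_metrics``; every year carries the same expectations.
    """
    config = config or RunConfig()
    params_table = spec.params_table
    dens = spec.full_densities()
    per_habitat = {}
    for habitat, group in dens.groupby("habitat"):
        ssb = somatic = recruit = 0.0
        for row in group.itertuples(index=False):
            params = lh.resolve_taxon(row.taxon, params_table, config.proxy_map)
            L = float(row.length_class_cm)
            d = float(row.density_per_m2)
            ssb += d * lh.weight_at_length(L, params)
            somatic += d * lh.individual_production(L, params, config.interval)
            threshold = lh.recruit_length_threshold(
                params, config.recruit_settlement_length, config.interval
            )
            if L <= threshold:
                recruit += d * lh.weight_at_length(L, params)
        per_habitat[habitat] = (ssb / 1000.0, somatic / 1000.0, recruit / 1000.0)
    records = []
    for geom in spec.platforms:
        for habitat, (ssb, somatic, recruit) in per_habitat.items():
            for year in range(spec.start_year, spec.start_year + spec.years):
                records.append(
                    {
                        "platform": geom.platform,
                        "habitat": habitat,
                        "year": year,
                        "ssb_density": ssb,
                        "somatic_density": somatic,
                        "recruit_density": recruit,
                        "total_density": somatic + recruit,
                        "surveyed_area": spec.transect_length[habitat]
                        * (config.transect_width),
                        "imputed": False,
                    }
                )
    return pd.DataFrame.from_records(records, columns=METRIC_COLUMNS)


def expected_overall(spec: SyntheticSpec, config: RunConfig | None = None) -> pd.DataFrame:
    """Expected overall complete/partial kg and kg/yr plus retention, per platform."""
    metrics = expected_metrics(spec, config)
    one_year = metrics[metrics["year"] == spec.start_year]
    records = []
    for geom in spec.platforms:
        rows = one_year[one_year["platform"] == geom.platform].set_index("habitat")
        ssb_c = prod_c = ssb_p = prod_p = 0.0
        for habitat in PLATFORM_HABITATS:
            if habitat not in rows.index:
                continue
            area = geom.structure_area(habitat)
            ssb = rows.loc[habitat, "ssb_density"] * area
            prod = rows.loc[habitat, "total_density"] * area
            ssb_c += ssb
            prod_c += prod
            if habitat != "shallow":
                ssb_p += ssb
                prod_p += prod
        records.append(
            {
                "platform": geom.platform,
                "ssb_complete_kg": ssb_c,
                "production_complete_kg_yr": prod_c,
                "ssb_partial_kg": ssb_p,
                "production_partial_kg_yr": prod_p,
                "retention_ssb_pct": 100.0 * ssb_p / ssb_c if ssb_c > 0 else np.nan,
                "retention_production_pct": 100.0 * prod_p / prod_c if prod_c > 0 else np.nan,
            }
        )
    return pd.DataFrame.from_records(records)


def write_inputs(spec: SyntheticSpec, out_dir, seed: int | None = None) -> dict[str, str]:
    """Write survey, parameter and geometry CSVs for file-based runs."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survey = generate_survey(spec, seed=seed)
    survey.to_csv(out / "survey.csv", index=False)
    params = pd.DataFrame(
        [
            {
                "taxon": t.taxon_code,
                "L_inf_cm": t.L_inf,
                "K_per_yr": t.K,
                "weight_a": t.weight_a,
                "weight_b": t.weight_b,
                "len_conv_slope": t.length_conversion[0] if t.length_conversion else "",
                "len_conv_intercept": t.length_conversion[1] if t.length_conversion else "",
                "transient": t.transient,
                "proxy_of": ";".join(t.proxy_for),
            }
            for t in spec.taxa
        ]
    )
    params.to_csv(out / "params.csv", index=False)
    geometry_frame(spec.platforms).to_csv(out / "geometry.csv", index=False)
    return {name: str(out / f"{name}.csv") for name in ("survey", "params", "geometry")}


def example_spec(
    years: int = 3, count_model: str = "deterministic", rng_seed: int = 0
) -> SyntheticSpec:
    """A small two-platform, two-taxon survey used by tests and the CLI.

    Densities are chosen so that deterministic expected counts over the
    100 m x 2 m transects are integers.
    """
    platforms = [
        PlatformGeometry("Alpha", 100.0, 2600.0, 7200.0, 200.0, 2000.0, 5000.0),
        PlatformGeometry("Bravo", 60.0, 1500.0, 3000.0, 150.0, 1500.0, None),
    ]
    taxa = [
        lh.TaxonParameters("Sebastes synthetica", L_inf=30.0, K=0.5, weight_a=0.01, weight_b=3.0),
        lh.TaxonParameters("Ophiodon synthetica", L_inf=100.0, K=0.2, weight_a=0.005, weight_b=3.1),
    ]
    rows = []
    for habitat, base in (("shallow", 0.05), ("midwater", 0.10), ("base", 0.25), ("shellmound", 0.05)):
        rows += [
            {"habitat": habitat, "taxon": "Sebastes synthetica", "length_class_cm": 10, "density_per_m2": base},
            {"habitat": habitat, "taxon": "Sebastes synthetica", "length_class_cm": 20, "density_per_m2": base / 2},
            {"habitat": habitat, "taxon": "Ophiodon synthetica", "length_class_cm": 50, "density_per_m2": 0.01},
        ]
    densities = pd.DataFrame(rows, columns=DENSITY_COLUMNS)
    return SyntheticSpec(
        platforms=platforms,
        taxa=taxa,
        densities=densities,
        years=years,
        count_model=count_model,
        recruit_pulse={"Sebastes synthetica": 0.05},
        rng_seed=rng_seed,
    )
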