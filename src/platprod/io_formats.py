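"""Tabular input/output, validation, run configuration and packaged fixtures.

All inputs and outputs are flat comma-separated tables (UTF-8, "." decimal).

Survey table columns
    ``platform, year, habitat, transect_length_m, taxon, length_class_cm,
    count`` plus an optional ``transect_id``.  One row is one taxon x 5-cm
    size-class count on one transect.  When ``transect_id`` is absent, all
    rows of a platform x habitat x year share a single pooled transect
    length.

Geometry table
    Wide form (one row per platform): ``platform, seafloor_depth_m,
    area_shallow_m2, area_midwater_m2, area_base_m2, footprint_m2,
    shellmound_m2``.  Long form (one row per platform x sub-habitat):
    ``platform, seafloor_depth_m, habitat, area_m2, footprint_m2,
    shellmound_m2``.  A missing shell-mound area means "unknown extent":
    overall shell-mound metrics are then unavailable, not zero.

Life-history parameter table
    ``taxon, L_inf_cm, K_per_yr, weight_a, weight_b, len_conv_slope,
    len_conv_intercept, transient, proxy_of`` (``proxy_of`` lists the
    survey codes this row stands in for, ";"-separated).

Masses are carried in grams internally and reported in kg (kg/yr).
The packaged fixtures reproduce the published survey-platform geometry
and habitat-level mean density tables for the 16 California platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .life_history import TaxonParameters

logger = logging.getLogger("platprod")

__all__ = [
    "HABITATS",
    "PLATFORM_HABITATS",
    "LENGTH_CLASSES",
    "SurveyObservation",
    "PlatformGeometry",
    "RunConfig",
    "SchemaError",
    "ValidationError",
    "read_survey_table",
    "read_geometry_table",
    "read_params_table",
    "geometry_frame",
    "write_results",
    "read_results",
    "load_platform_geometry",
    "load_habitat_mean_metrics",
    "habitat_means_as_metrics",
]

#: Habitat labels, in depth order; the first three are platform structure.
HABITATS = ("shallow", "midwater", "base", "shellmound")
PLATFORM_HABITATS = ("shallow", "midwater", "base")
#: Valid 5-cm total-length class nominal values, cm.
LENGTH_CLASSES = tuple(range(5, 305, 5))

SURVEY_COLUMNS = (
    "platform",
    "year",
    "habitat",
    "transect_length_m",
    "taxon",
    "length_class_cm",
    "count",
)
GEOMETRY_WIDE_COLUMNS = (
    "platform",
    "seafloor_depth_m",
    "area_shallow_m2",
    "area_midwater_m2",
    "area_base_m2",
    "footprint_m2",
    "shellmound_m2",
)


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


class ValidationError(ValueError):
    """A row violates a domain invariant; the message carries the row number."""


@dataclass(frozen=True)
class SurveyObservation:
    """One taxon x size-class count on one transect."""

    platform: str
    year: int
    habitat: str
    transect_length_m: float
    taxon: str
    length_class_cm: int
    count: int


@dataclass(frozen=True)
class PlatformGeometry:
    """Structural surface areas (m^2) and depths for one platform.

    ``shellmound_m2 is None`` encodes an unknown shell-mound extent.
    """

    platform: str
    seafloor_depth_m: float
    area_shallow_m2: float
    area_midwater_m2: float
    area_base_m2: float
    footprint_m2: float
    shellmound_m2: float | None = None

    @property
    def total_surface_area(self) -> float:
        return self.area_shallow_m2 + self.area_midwater_m2 + self.area_base_m2

    def structure_area(self, habitat: str) -> float:
        return getattr(self, f"area_{habitat}_m2")


@dataclass
class RunConfig:
    """Tunable constants of a pipeline run.

    Defaults reflect the study design: a 26 m partial-removal cut depth,
    a 2 m platform-base band, 2 m wide belt transects, a one-year
    production interval, and Squarespot Rockfish standing in for
    unidentified rockfishes.
    """

    cut_depth: float = 26.0
    base_band: float = 2.0
    interval: float = 1.0  # years; the model is annual
    transect_width: float = 2.0
    recruit_settlement_length: float = 1.0
    unidentified_rockfish_proxy: str = "Sebastes hopkinsi"
    unidentified_rockfish_codes: tuple[str, ...] = ("Sebastes spp.",)
    gislason_coeffs: tuple[float, float, float] = (0.55, -1.61, 1.44)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cut_depth <= 0:
            raise ValueError("cut_depth must be > 0")
        if self.transect_width <= 0:
            raise ValueError("transect_width must be > 0")

    @property
    def proxy_map(self) -> dict[str, str]:
        return {code: self.unidentified_rockfish_proxy for code in self.unidentified_rockfish_codes}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("unidentified_rockfish_codes", "gislason_coeffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["unidentified_rockfish_codes"] = list(self.unidentified_rockfish_codes)
        d["gislason_coeffs"] = list(self.gislason_coeffs)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_survey_table(
    path: str | Path,
    params_table: dict[str, TaxonParameters] | None = None,
    schema: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a survey table.

    ``schema`` optionally maps the documented column names to the names
    actually present in the file (the deposited data's layout varies).
    Rows for taxa flagged transient in ``params_table`` are dropped and
    the exclusion is logged.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require_columns(df, SURVEY_COLUMNS, f"survey table {path}")
    df = df.loc[:, [c for c in df.columns if c in SURVEY_COLUMNS + ("transect_id",)]].copy()

    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            count = int(row.count)
            length = int(row.length_class_cm)
            tlen = float(row.transect_length_m)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"line {i}: non-numeric field ({exc})") from None
        if count < 0:
            raise ValidationError(f"line {i}: count must be >= 0, got {count}")
        if tlen <= 0:
            raise ValidationError(f"line {i}: transect_length_m must be > 0, got {tlen}")
        if length not in LENGTH_CLASSES:
            raise ValidationError(
                f"line {i}: length_class_cm must be a 5-cm class in [5, 300], got {length}"
            )
        if row.habitat not in HABITATS:
            raise ValidationError(f"line {i}: unknown habitat {row.habitat!r}")

    df["year"] = df["year"].astype(int)
    df["count"] = df["count"].astype(int)
    df["length_class_cm"] = df["length_class_cm"].astype(int)
    df["transect_length_m"] = df["transect_length_m"].astype(float)

    if params_table:
        transient = {code for code, p in params_table.items() if p.transient}
        mask = df["taxon"].isin(transient)
        if mask.any():
            logger.info(
                "dropped %d transient-taxon record(s) (%s)",
                int(mask.sum()),
                ", ".join(sorted(df.loc[mask, "taxon"].unique())),
            )
            df = df.loc[~mask].reset_index(drop=True)
    return df


def _geometry_from_wide(df: pd.DataFrame) -> list[PlatformGeometry]:
    if df["platform"].duplicated().any():
        dupes = df.loc[df["platform"].duplicated(), "platform"].tolist()
        raise ValidationError(f"duplicate platform row(s): {dupes}")
    out = []
    for row in df.itertuples(index=False):
        mound = getattr(row, "shellmound_m2", None)
        mound = None if mound is None or pd.isna(mound) else float(mound)
        out.append(
            PlatformGeometry(
                platform=str(row.platform),
                seafloor_depth_m=float(row.seafloor_depth_m),
                area_shallow_m2=float(row.area_shallow_m2),
                area_midwater_m2=float(row.area_midwater_m2),
                area_base_m2=float(row.area_base_m2),
                footprint_m2=float(row.footprint_m2),
                shellmound_m2=mound,
            )
        )
    return out


def _geometry_from_long(df: pd.DataFrame) -> list[PlatformGeometry]:
    if df.duplicated(subset=["platform", "habitat"]).any():
        pairs = df.loc[df.duplicated(subset=["platform", "habitat"]), ["platform", "habitat"]]
        raise ValidationError(
            "duplicate platform/habitat pair(s): "
            + "; ".join(f"{p}/{h}" for p, h in pairs.itertuples(index=False))
        )
    wide = df.pivot(index="platform", columns="habitat", values="area_m2")
    meta = df.groupby("platform").first()
    out = []
    for platform, areas in wide.iterrows():
        m = meta.loc[platform]
        mound = m.get("shellmound_m2")
        mound = None if mound is None or pd.isna(mound) else float(mound)
        out.append(
            PlatformGeometry(
                platform=str(platform),
                seafloor_depth_m=float(m["seafloor_depth_m"]),
                area_shallow_m2=float(areas["shallow"]),
                area_midwater_m2=float(areas["midwater"]),
                area_base_m2=float(areas["base"]),
                footprint_m2=float(m["footprint_m2"]),
                shellmound_m2=mound,
            )
        )
    return out


def read_geometry_table(path: str | Path) -> list[PlatformGeometry]:
    """Read a platform geometry table in wide or long layout."""
    df = pd.read_csv(path)
    if "area_shallow_m2" in df.columns:
        _require_columns(df, GEOMETRY_WIDE_COLUMNS[:-1], f"geometry table {path}")
        return _geometry_from_wide(df)
    if "habitat" in df.columns and "area_m2" in df.columns:
        return _geometry_from_long(df)
    raise SchemaError(
        f"geometry table {path} matches neither the wide layout "
        "(area_shallow_m2/...) nor the long layout (habitat, area_m2)"
    )


def read_params_table(path: str | Path) -> dict[str, TaxonParameters]:
    """Read a life-history parameter table keyed by taxon code."""
    df = pd.read_csv(path)
    _require_columns(
        df, ("taxon", "L_inf_cm", "K_per_yr", "weight_a", "weight_b"), f"parameter table {path}"
    )
    table: dict[str, TaxonParameters] = {}
    for row in df.itertuples(index=False):
        conv = None
        slope = getattr(row, "len_conv_slope", None)
        if slope is not None and not pd.isna(slope):
            conv = (float(slope), float(getattr(row, "len_conv_intercept", 0.0) or 0.0))
        proxy_raw = getattr(row, "proxy_of", None)
        proxies: tuple[str, ...] = ()
        if proxy_raw is not None and not pd.isna(proxy_raw) and str(proxy_raw).strip():
            proxies = tuple(s.strip() for s in str(proxy_raw).split(";") if s.strip())
        transient = bool(getattr(row, "transient", False))
        table[str(row.taxon)] = TaxonParameters(
            taxon_code=str(row.taxon),
            L_inf=float(row.L_inf_cm),
            K=float(row.K_per_yr),
            weight_a=float(row.weight_a),
            weight_b=float(row.weight_b),
            length_conversion=conv,
            transient=transient,
            proxy_for=proxies,
        )
    return table


def geometry_frame(geometries: list[PlatformGeometry]) -> pd.DataFrame:
    """Wide-layout DataFrame view of a geometry list (round-trips via CSV)."""
    return pd.DataFrame([asdict(g) for g in geometries])


# ---------------------------------------------------------------------------
# results I/O


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named result table to ``<out_dir>/<name>.csv``.

    Floats are written at full precision so tables round-trip bit-
    identically through :func:`read_results`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_results(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back every result table written by :func:`write_results`."""
    return {p.stem: pd.read_csv(p) for p in sorted(Path(out_dir).glob("*.csv"))}


# ---------------------------------------------------------------------------
# packaged fixtures (published tables for the 16 California platforms)


def _data_path(name: str):
    return resources.files("platprod.data").joinpath(name)


def load_platform_geometry() -> list[PlatformGeometry]:
    """Published structural dimensions of the 16 surveyed platforms.

    Seafloor depth, structural surface area by sub-habitat, seafloor
    footprint and (where estimated) shell-mound extent.
    """
    with resources.as_file(_data_path("platform_geometry.csv")) as p:
        return read_geometry_table(p)


def habitat_means_as_metrics() -> pd.DataFrame:
    """The packaged mean-density table in habitat-year-metrics shape.

    The published means carry SSB and total production densities only, so
    the somatic/recruitment split is not recoverable: the total is placed
    in ``somatic_density`` and ``recruit_density`` is zero.  Each platform
    x habitat becomes a single pseudo-year (year 0), so scenario results
    built from this table are mean-based approximations of the per-year
    computation, with no SE.
    """
    df = load_habitat_mean_metrics()
    out = pd.DataFrame(
        {
            "platform": df["platform"],
            "habitat": df["habitat"],
            "year": 0,
            "ssb_density": df["ssb_density_kg_m2"],
            "somatic_density": df["production_density_kg_m2_yr"],
            "recruit_density": 0.0,
            "total_density": df["production_density_kg_m2_yr"],
            "surveyed_area": pd.NA,
            "imputed": False,
        }
    )
    return out


def load_habitat_mean_metrics() -> pd.DataFrame:
    """Published mean annual density and overall metrics per habitat.

    Columns: platform, habitat, surface_area_m2, ssb_density_kg_m2,
    ssb_kg, production_density_kg_m2_yr, production_kg_yr.  Shell-mound
    rows with unknown extent have empty area/overall cells.
    """
    with resources.as_file(_data_path("habitat_mean_metrics.csv")) as p:
        return pd.read_csv(p)
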