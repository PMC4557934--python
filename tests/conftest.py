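import pandas as pd
import pytest

from platprod import PlatformGeometry, RunConfig, TaxonParameters

SURVEY_COLUMNS = [
    "platform",
    "year",
    "habitat",
    "transect_length_m",
    "taxon",
    "length_class_cm",
    "count",
]


def make_survey(rows):
    """Build a survey observation frame from (platform, year, habitat,
    transect_length_m, taxon, length_class_cm, count) tuples."""
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


@pytest.fixture
def rockfish():
    """Reference parameter set used throughout: L_inf=30 cm, K=0.5/yr, W=0.01 L^3."""
    return TaxonParameters("rockfish", L_inf=30.0, K=0.5, weight_a=0.01, weight_b=3.0)


@pytest.fixture
def lingcod():
    return TaxonParameters("lingcod", L_inf=100.0, K=0.2, weight_a=0.005, weight_b=3.1)


@pytest.fixture
def params_table(rockfish, lingcod):
    return {p.taxon_code: p for p in (rockfish, lingcod)}


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def toy_geometry():
    return PlatformGeometry(
        platform="Toy",
        seafloor_depth_m=100.0,
        area_shallow_m2=10.0,
        area_midwater_m2=20.0,
        area_base_m2=5.0,
        footprint_m2=2000.0,
        shellmound_m2=50.0,
    )
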