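"""Imputation, overall platform metrics, retention and loss fractions."""

import math

import numpy as np
import pandas as pd
import pytest

from platprod import (
    PlatformGeometry,
    ProxyRules,
    annual_overall,
    combined_loss_fraction,
    impute_missing,
    mound_loss_fraction,
    overall_metrics,
    partial_removal_summary,
    shellmound_overall,
)
from platprod.survey_metrics import METRIC_COLUMNS


def metrics_frame(rows):
    """(platform, habitat, year, ssb, somatic, recruit) -> metrics frame."""
    records = [
        {
            "platform": p,
            "habitat": h,
            "year": y,
            "ssb_density": ssb,
            "somatic_density": som,
            "recruit_density": rec,
            "total_density": som + rec,
            "surveyed_area": 200.0,
            "imputed": False,
        }
        for p, h, y, ssb, som, rec in rows
    ]
    return pd.DataFrame.from_records(records, columns=METRIC_COLUMNS)


@pytest.fixture
def toy_metrics():
    # densities 0.1 / 0.2 / 0.3 kg/m^2 as in the worked retention example
    return metrics_frame(
        [
            ("Toy", "shallow", 2001, 0.1, 0.1, 0.0),
            ("Toy", "midwater", 2001, 0.2, 0.2, 0.0),
            ("Toy", "base", 2001, 0.3, 0.3, 0.0),
        ]
    )


class TestImputeMissing:
    def test_gap_years_filled_with_habitat_mean(self):
        m = metrics_frame(
            [
                ("P", "shallow", y, 0.1, 0.1, 0.0) for y in (2001, 2002, 2003, 2004, 2005)
            ]
            + [("P", "midwater", y, 0.2, 0.2, 0.0) for y in (2001, 2002, 2003, 2004, 2005)]
            + [("P", "base", y, v, v, 0.0) for y, v in ((2001, 0.2), (2002, 0.4), (2003, 0.6))]
        )
        filled = impute_missing(m, ProxyRules(base_proxy={}, shallow_proxy={}))
        base = filled[(filled["habitat"] == "base")].set_index("year")
        assert len(base) == 5
        for year in (2004, 2005):
            assert base.loc[year, "ssb_density"] == pytest.approx(0.4)
            assert bool(base.loc[year, "imputed"])
        assert not base.loc[2001, "imputed"]

    def test_never_surveyed_base_borrows_donor_mean(self):
        m = metrics_frame(
            [("A", "shallow", 2001, 0.1, 0.1, 0.0), ("A", "midwater", 2001, 0.2, 0.2, 0.0)]
            + [
                ("Holly", h, y, v, v, 0.0)
                for h in ("shallow", "midwater")
                for y, v in ((2001, 0.1), (2002, 0.1))
            ]
            + [("Holly", "base", 2001, 0.3, 0.3, 0.0), ("Holly", "base", 2002, 0.5, 0.5, 0.0)]
        )
        filled = impute_missing(m)  # default rules: A's base <- Holly
        a_base = filled[(filled["platform"] == "A") & (filled["habitat"] == "base")]
        assert len(a_base) == 1  # A was surveyed in one year
        assert a_base["ssb_density"].iloc[0] == pytest.approx(0.4)
        assert a_base["imputed"].all()

    def test_shallow_proxy_averages_donor_means(self):
        donors = ["Holly", "B", "A", "Hillhouse", "Habitat"]
        rows = []
        for i, d in enumerate(donors):
            rows += [
                (d, "shallow", 2001, 0.1 * (i + 1), 0.1, 0.0),
                (d, "midwater", 2001, 0.2, 0.2, 0.0),
                (d, "base", 2001, 0.3, 0.3, 0.0),
            ]
        rows += [("Irene", "midwater", 2001, 0.2, 0.2, 0.0), ("Irene", "base", 2001, 0.3, 0.3, 0.0)]
        filled = impute_missing(metrics_frame(rows))
        irene_shallow = filled[
            (filled["platform"] == "Irene") & (filled["habitat"] == "shallow")
        ]
        assert irene_shallow["ssb_density"].iloc[0] == pytest.approx(0.1 * (1 + 2 + 3 + 4 + 5) / 5)

    def test_fully_observed_platform_unchanged(self, toy_metrics):
        filled = impute_missing(toy_metrics, ProxyRules(base_proxy={}, shallow_proxy={}))
        pd.testing.assert_frame_equal(
            filled.sort_values(["habitat"]).reset_index(drop=True),
            toy_metrics.sort_values(["habitat"]).reset_index(drop=True),
        )

    def test_unproxied_missing_habitat_raises(self):
        m = metrics_frame([("Lonely", "midwater", 2001, 0.2, 0.2, 0.0)])
        with pytest.raises(ValueError, match="Lonely"):
            impute_missing(m)


class TestOverallMetrics:
    def test_worked_retention_example(self, toy_metrics, toy_geometry):
        # areas 10/20/5: complete = 1 + 4 + 1.5 = 6.5 kg, partial = 5.5 kg
        (complete,) = overall_metrics(toy_metrics, [toy_geometry], "complete")
        (partial,) = partial_removal_summary(toy_metrics, [toy_geometry])
        assert complete.ssb == pytest.approx(6.5)
        assert partial.ssb == pytest.approx(5.5)
        assert partial.retention_ssb == pytest.approx(100 * 5.5 / 6.5)
        assert partial.retention_ssb == pytest.approx(84.6, abs=0.1)

    def test_per_seafloor_scaling(self, toy_metrics, toy_geometry):
        (complete,) = overall_metrics(toy_metrics, [toy_geometry], "complete")
        assert complete.per_seafloor_ssb == pytest.approx(6.5 * 1000 / 2000)

    def test_zero_shallow_density_gives_full_retention(self, toy_geometry):
        m = metrics_frame(
            [
                ("Toy", "shallow", 2001, 0.0, 0.0, 0.0),
                ("Toy", "midwater", 2001, 0.2, 0.2, 0.0),
                ("Toy", "base", 2001, 0.3, 0.3, 0.0),
            ]
        )
        (partial,) = partial_removal_summary(m, [toy_geometry])
        assert partial.retention_ssb == pytest.approx(100.0)
        assert partial.retention_production == pytest.approx(100.0)

    def test_per_year_additivity_complete_vs_partial(self, toy_geometry):
        rng = np.random.default_rng(3)
        rows = []
        for year in (2001, 2002, 2003):
            for habitat in ("shallow", "midwater", "base"):
                v = float(rng.uniform(0.01, 0.5))
                rows.append(("Toy", habitat, year, v, v / 2, v / 4))
        m = metrics_frame(rows)
        complete = annual_overall(m, toy_geometry, ("shallow", "midwater", "base"))
        partial = annual_overall(m, toy_geometry, ("midwater", "base"))
        shallow = m[m["habitat"] == "shallow"].set_index("year")
        for row_c, row_p in zip(complete.itertuples(), partial.itertuples()):
            contrib = shallow.loc[row_c.year, "ssb_density"] * toy_geometry.area_shallow_m2
            assert row_c.ssb_kg == pytest.approx(row_p.ssb_kg + contrib, rel=1e-12)

    def test_retention_invariant_under_density_rescaling(self, toy_metrics, toy_geometry):
        scaled = toy_metrics.copy()
        for c in ("ssb_density", "somatic_density", "recruit_density", "total_density"):
            scaled[c] *= 7.3
        (a,) = partial_removal_summary(toy_metrics, [toy_geometry])
        (b,) = partial_removal_summary(scaled, [toy_geometry])
        assert a.retention_ssb == pytest.approx(b.retention_ssb, rel=1e-12)
        assert a.retention_production == pytest.approx(b.retention_production, rel=1e-12)

    def test_se_matches_textbook_sample_se(self, toy_geometry):
        values = {2001: 0.1, 2002: 0.3, 2003: 0.2}
        rows = []
        for year, v in values.items():
            for habitat in ("shallow", "midwater", "base"):
                rows.append(("Toy", habitat, year, v, v, 0.0))
        (complete,) = overall_metrics(metrics_frame(rows), [toy_geometry], "complete")
        annual = [v * 35.0 for v in values.values()]  # total area 10+20+5
        mean = sum(annual) / 3
        sd = math.sqrt(sum((x - mean) ** 2 for x in annual) / 2)
        assert complete.ssb == pytest.approx(mean, rel=1e-12)
        assert complete.ssb_se == pytest.approx(sd / math.sqrt(3), rel=1e-12)

    def test_single_year_has_no_se(self, toy_metrics, toy_geometry):
        (complete,) = overall_metrics(toy_metrics, [toy_geometry], "complete")
        assert complete.ssb_se is None
        assert complete.n_years == 1

    def test_missing_habitat_raises(self, toy_geometry):
        m = metrics_frame([("Toy", "midwater", 2001, 0.2, 0.2, 0.0)])
        with pytest.raises(ValueError, match="shallow"):
            overall_metrics(m, [toy_geometry], "complete")


class TestShellmoundOverall:
    def test_density_times_area(self, toy_geometry):
        m = metrics_frame(
            [("Toy", "shellmound", 2001, 0.04, 0.02, 0.0), ("Toy", "shellmound", 2002, 0.06, 0.02, 0.0)]
        )
        result = shellmound_overall(m, toy_geometry)
        assert result.ssb == pytest.approx(0.05 * 50.0)
        assert result.total_production == pytest.approx(0.02 * 50.0)
        assert result.n_years == 2

    def test_unknown_extent_is_unavailable(self):
        geom = PlatformGeometry("P", 100, 10, 20, 5, 2000, shellmound_m2=None)
        m = metrics_frame([("P", "shellmound", 2001, 0.04, 0.02, 0.0)])
        result = shellmound_overall(m, geom)
        assert result.ssb is None and result.total_production is None

    def test_zero_density_gives_zero_overall(self, toy_geometry):
        m = metrics_frame([("Toy", "shellmound", 2001, 0.0, 0.0, 0.0)])
        assert shellmound_overall(m, toy_geometry).ssb == 0.0


class TestLossFractions:
    def test_mound_only_fraction(self):
        # partial platform 1606 kg/yr + mound 238 kg/yr
        assert mound_loss_fraction(1563 + 43, 238) == pytest.approx(12.9, abs=0.05)

    def test_zero_mound_means_no_loss(self):
        assert mound_loss_fraction(100.0, 0.0) == 0.0

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            mound_loss_fraction(0.0, 0.0)

    def test_combined_fraction(self):
        # complete 435, shallow 27, mound 1253
        assert combined_loss_fraction(27 + 268 + 140, 27, 1253) == pytest.approx(
            75.8, abs=0.05
        )

    def test_combined_edge_cases(self):
        assert combined_loss_fraction(100.0, 0.0, 0.0) == 0.0
        assert combined_loss_fraction(100.0, 100.0, 0.0) == 100.0
        with pytest.raises(ValueError):
            combined_loss_fraction(10.0, 20.0, 0.0)
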