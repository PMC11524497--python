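"""Pollen percentages, openness ratio, biomass and windowed correlation."""

import logging

import numpy as np
import pandas as pd
import pytest

import dungprint as dp


GROUPS = {"Pinus": "terrestrial", "Pseudotsuga": "terrestrial",
          "Artemisia": "terrestrial", "Poaceae": "terrestrial",
          "Salix": "terrestrial", "Cyperaceae": "aquatic"}


def counts_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows).fillna(0).astype(int)
    df.index = pd.Index([f"p{i}" for i in range(len(df))], name="sample_id")
    return df


class TestPollenPercentages:
    def test_terrestrial_percent_on_terrestrial_sum(self):
        counts = counts_frame(
            [{"Pinus": 150, "Artemisia": 100, "Poaceae": 50, "Cyperaceae": 30}]
        )
        pct = dp.pollen_percentages(counts, GROUPS)["percent"]
        assert pct.loc["p0", "Pinus"] == pytest.approx(50.0)

    def test_aquatic_percent_on_total_sum(self):
        counts = counts_frame(
            [{"Pinus": 200, "Artemisia": 50, "Poaceae": 50, "Cyperaceae": 30}]
        )
        pct = dp.pollen_percentages(counts, GROUPS)["percent"]
        assert pct.loc["p0", "Cyperaceae"] == pytest.approx(100.0 * 30 / 330)

    def test_terrestrial_sums_to_100(self):
        rng = np.random.default_rng(0)
        counts = counts_frame(
            [dict(zip(GROUPS, rng.integers(1, 200, len(GROUPS)))) for _ in range(10)]
        )
        pct = dp.pollen_percentages(counts, GROUPS)["percent"]
        terr = [t for t, g in GROUPS.items() if g == "terrestrial"]
        assert np.allclose(pct[terr].sum(axis=1), 100.0, atol=1e-6)

    def test_marker_spike_concentration(self):
        counts = counts_frame([{"Pinus": 50, "Artemisia": 1, "Poaceae": 1, "Cyperaceae": 0}])
        out = dp.pollen_percentages(
            counts, GROUPS,
            spike_counted=pd.Series({"p0": 100}),
            spike_added=10_000.0,
            volume_cm3=1.0,
        )
        assert out["concentration"].loc["p0", "Pinus"] == pytest.approx(5000.0)

    def test_zero_spike_logged_and_undefined(self, caplog):
        counts = counts_frame([{"Pinus": 50, "Artemisia": 1, "Poaceae": 1, "Cyperaceae": 0}])
        with caplog.at_level(logging.WARNING):
            out = dp.pollen_percentages(
                counts, GROUPS, spike_counted=pd.Series({"p0": 0}), spike_added=1000.0
            )
        assert out["concentration"].loc["p0"].isna().all()
        assert any("spike" in rec.message for rec in caplog.records)

    def test_zero_terrestrial_sum_rejected(self):
        counts = counts_frame([{"Pinus": 0, "Artemisia": 0, "Poaceae": 0, "Cyperaceae": 5}])
        with pytest.raises(ValueError, match="terrestrial"):
            dp.pollen_percentages(counts, GROUPS)

    def test_ungrouped_taxon_rejected(self):
        counts = counts_frame([{"Pinus": 10, "Quercus": 5}])
        with pytest.raises(ValueError, match="Quercus"):
            dp.pollen_percentages(counts, GROUPS)


class TestOpennessRatio:
    def test_equal_sums_give_one(self):
        pct = pd.DataFrame(
            [{"Artemisia": 20.0, "Poaceae": 20.0, "Pinus": 30.0, "Pseudotsuga": 10.0}],
            index=["p0"],
        )
        assert dp.openness_ratio(pct).loc["p0"] == pytest.approx(1.0)

    def test_doubling_numerator_doubles_ratio(self):
        base = pd.DataFrame(
            [{"Artemisia": 10.0, "Poaceae": 15.0, "Pinus": 40.0, "Pseudotsuga": 10.0}],
            index=["p0"],
        )
        doubled = base.copy()
        doubled[["Artemisia", "Poaceae"]] *= 2.0
        assert dp.openness_ratio(doubled).loc["p0"] == pytest.approx(
            2.0 * dp.openness_ratio(base).loc["p0"]
        )

    def test_zero_denominator_undefined(self, caplog):
        pct = pd.DataFrame(
            [{"Artemisia": 10.0, "Poaceae": 15.0, "Pinus": 0.0, "Pseudotsuga": 0.0}],
            index=["p0"],
        )
        with caplog.at_level(logging.WARNING):
            ratio = dp.openness_ratio(pct)
        assert np.isnan(ratio.loc["p0"])


class TestBiomass:
    def test_bison_biomass_conversion(self):
        pops = pd.DataFrame({"year": [2022], "species": ["bison"], "count": [4000]})
        out = dp.biomass_series(pops, interpolate=False)
        assert out.loc[2022, "total_biomass_kg"] == pytest.approx(2_660_000.0)

    def test_combined_species_biomass(self):
        pops = pd.DataFrame(
            {"year": [2000, 2000], "species": ["bison", "elk"], "count": [1000, 1000]}
        )
        out = dp.biomass_series(pops)
        assert out.loc[2000, "total_biomass_kg"] == pytest.approx(900_000.0)

    def test_zero_counts_zero_biomass(self):
        pops = pd.DataFrame({"year": [1990], "species": ["elk"], "count": [0]})
        out = dp.biomass_series(pops)
        assert out.loc[1990, "total_biomass_kg"] == 0.0

    def test_gaps_interpolated_within_span_only(self):
        pops = pd.DataFrame(
            {"year": [1900, 1910], "species": ["bison", "bison"], "count": [100, 200]}
        )
        out = dp.biomass_series(pops)
        assert out.loc[1905, "biomass_bison_kg"] == pytest.approx(150 * 665.0)
        assert set(out.index) == set(range(1900, 1911))

    def test_unknown_species_rejected(self):
        pops = pd.DataFrame({"year": [1990], "species": ["mammoth"], "count": [2]})
        with pytest.raises(ValueError, match="mammoth"):
            dp.biomass_series(pops)


class TestWindowedCorrelation:
    def make_pair(self, values, years_ce):
        marker = pd.DataFrame(
            {"age_cal_BP": 1950.0 - np.asarray(years_ce, dtype=float), "value": values}
        )
        return marker

    def biomass_linear(self, years, slope=1000.0, intercept=5e5):
        return pd.DataFrame(
            {"total_biomass_kg": intercept + slope * (np.asarray(years) - years[0])},
            index=pd.Index(years, name="year"),
        )

    def test_exact_linear_relation_gives_r_one(self):
        years = list(range(1920, 1971))
        biomass = self.biomass_linear(years)
        sample_years = [1925, 1935, 1945, 1955, 1965]
        marker = self.make_pair(
            [2.0 * (y - 1920) + 3.0 for y in sample_years], sample_years
        )
        r, p, n = dp.windowed_correlation(marker, biomass, (1920, 1970), "value")
        assert r == pytest.approx(1.0)
        assert p < 1e-6
        assert n == 5

    def test_exact_inverse_relation_gives_r_minus_one(self):
        years = list(range(1920, 1971))
        biomass = self.biomass_linear(years)
        sample_years = [1925, 1935, 1945, 1955, 1965]
        marker = self.make_pair([-1.0 * y for y in sample_years], sample_years)
        r, _, _ = dp.windowed_correlation(marker, biomass, (1920, 1970), "value")
        assert r == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self):
        years = list(range(1900, 2001))
        rng = np.random.default_rng(5)
        biomass = pd.DataFrame(
            {"total_biomass_kg": rng.uniform(1e5, 1e6, len(years))},
            index=pd.Index(years, name="year"),
        )
        sample_years = list(range(1910, 1995, 7))
        values = rng.normal(10.0, 2.0, len(sample_years))
        m1 = self.make_pair(values, sample_years)
        m2 = self.make_pair(5.0 * values + 100.0, sample_years)
        r1, _, _ = dp.windowed_correlation(m1, biomass, (1900, 2000), "value")
        r2, _, _ = dp.windowed_correlation(m2, biomass, (1900, 2000), "value")
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_nearest_year_pairing_agrees_on_dense_series(self):
        years = list(range(1920, 1971))
        biomass = self.biomass_linear(years)
        sample_years = [1925.0, 1940.0, 1960.0]
        marker = self.make_pair([1.0, 5.0, 2.0], sample_years)
        r_i, _, _ = dp.windowed_correlation(marker, biomass, (1920, 1970), "value")
        r_n, _, _ = dp.windowed_correlation(
            marker, biomass, (1920, 1970), "value", pairing="nearest"
        )
        assert r_i == pytest.approx(r_n, abs=1e-9)

    def test_too_few_pairs_error_names_window(self):
        biomass = self.biomass_linear(list(range(1920, 1971)))
        marker = self.make_pair([1.0, 2.0], [1930, 1940])
        with pytest.raises(ValueError, match="1920"):
            dp.windowed_correlation(marker, biomass, (1920, 1970), "value")


class TestMniPresence:
    def test_presence_rule(self):
        levels = pd.DataFrame(
            {
                "stratum": ["L1", "L1", "L2", "L2"],
                "species": ["bison", "elk", "bison", "elk"],
                "mni": [0, 1, 7, 0],
                "age_cal_BP": [100.0, 100.0, 900.0, 900.0],
            }
        )
        matrix = dp.mni_presence(levels)
        assert not matrix.loc["L1", "bison"]
        assert matrix.loc["L1", "elk"]
        assert matrix.loc["L2", "bison"]
        assert matrix.loc["L1", "age_cal_BP"] == 100.0

    def test_non_integer_mni_rejected(self):
        levels = pd.DataFrame(
            {"stratum": ["L1"], "species": ["elk"], "mni": [0.5]}
        )
        with pytest.raises(ValueError, match="integer"):
            dp.mni_presence(levels)
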