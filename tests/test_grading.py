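"""Grading tables, standard clouds and IAQI/AQI computation."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aircloud import (
    LevelBand,
    aqi_record,
    build_standard_set,
    iaqi,
    load_grading_table,
    standard_cloud_from_band,
)
from aircloud.grading import AQI_KEY, GradingTableError

# the full published standard-cloud table: (indicator, level) -> (Ex, En, He)
# as printed to two decimals
PUBLISHED_STANDARD_CLOUDS = {
    ("AQI", 1): (25, 8.33, 0.83), ("AQI", 2): (75, 8.33, 0.83),
    ("AQI", 3): (125, 8.33, 0.83), ("AQI", 4): (175, 8.33, 0.83),
    ("AQI", 5): (250, 16.67, 1.67),
    ("PM2.5", 1): (17.5, 5.83, 0.58), ("PM2.5", 2): (55, 6.67, 0.67),
    ("PM2.5", 3): (95, 6.67, 0.67), ("PM2.5", 4): (132.5, 5.83, 0.58),
    ("PM2.5", 5): (200, 16.67, 1.67),
    ("PM10", 1): (25, 8.33, 0.83), ("PM10", 2): (100, 16.67, 1.67),
    ("PM10", 3): (200, 16.67, 1.67), ("PM10", 4): (300, 16.67, 1.67),
    ("PM10", 5): (385, 11.67, 1.17),
    ("SO2", 1): (25, 8.33, 0.83), ("SO2", 2): (100, 16.67, 1.67),
    ("SO2", 3): (312.5, 54.17, 5.42), ("SO2", 4): (637.5, 54.17, 5.42),
    ("SO2", 5): (1200, 133.33, 13.33),
    ("CO", 1): (1, 0.33, 0.03), ("CO", 2): (3, 0.33, 0.03),
    ("CO", 3): (9, 1.67, 0.17), ("CO", 4): (19, 1.67, 0.17),
    ("CO", 5): (30, 2, 0.2),
    ("NO2", 1): (20, 6.67, 0.67), ("NO2", 2): (60, 6.67, 0.67),
    ("NO2", 3): (130, 16.67, 1.67), ("NO2", 4): (230, 16.67, 1.67),
    ("NO2", 5): (422.5, 47.5, 4.75),
    ("O3", 1): (50, 16.67, 1.67), ("O3", 2): (130, 10, 1),
    ("O3", 3): (187.5, 9.17, 0.92), ("O3", 4): (240, 8.33, 0.83),
    ("O3", 5): (532.5, 89.17, 8.92),
}


class TestGradingTable:
    def test_default_table_shape(self, table):
        assert table.indicator_names == ("PM2.5", "PM10", "SO2", "CO", "NO2", "O3")
        assert len(table.levels) == 5
        assert [b.cmax for b in table.index_bands] == [50, 100, 150, 200, 300]
        assert table.scale("CO").unit == "mg/m3"

    def test_bands_are_contiguous_from_zero(self, table):
        for name in table.indicator_names:
            bands = table.scale(name).bands
            assert bands[0].cmin == 0
            for prev, nxt in zip(bands, bands[1:]):
                assert prev.cmax == nxt.cmin

    def test_unknown_indicator(self, table):
        with pytest.raises(KeyError, match="unknown indicator"):
            table.scale("NH3")

    def test_malformed_documents_rejected(self):
        with pytest.raises(GradingTableError, match="missing"):
            load_grading_table({"levels": ["a"], "indicators": {}})
        with pytest.raises(GradingTableError, match="strictly increasing"):
            load_grading_table(
                {
                    "levels": ["a", "b"],
                    "index_scale": {"upper_limits": [50, 40]},
                    "indicators": {},
                }
            )


class TestStandardClouds:
    @pytest.mark.parametrize(
        "cmin, cmax, expected",
        [
            (150, 475, (312.5, 54.17, 5.42)),  # SO2 Lightly Polluted
            (280, 565, (422.5, 47.5, 4.75)),  # NO2 Heavily Polluted
            (0, 6, (3, 1, 0.1)),  # unit-entropy case
        ],
    )
    def test_bilateral_constraint_formulas(self, cmin, cmax, expected):
        cloud = standard_cloud_from_band(LevelBand(1, "x", cmin, cmax), k=0.1)
        assert round(cloud.ex, 2) == expected[0]
        assert round(cloud.en, 2) == expected[1]
        assert round(cloud.he, 2) == expected[2]

    def test_invalid_band_and_k(self):
        with pytest.raises(ValueError):
            LevelBand(1, "x", 5, 5)
        with pytest.raises(ValueError):
            standard_cloud_from_band(LevelBand(1, "x", 0, 10), k=0)
        with pytest.warns(UserWarning, match="1/3"):
            standard_cloud_from_band(LevelBand(1, "x", 0, 10), k=0.5)

    def test_full_set_matches_published_table(self, standards):
        """All 35 standard-cloud cells agree with the published table to
        half a unit in the last printed digit."""
        assert len(standards.clouds) == 35
        for (ind, level), (ex, en, he) in PUBLISHED_STANDARD_CLOUDS.items():
            cloud = standards.clouds[(ind, level)]
            assert cloud.ex == pytest.approx(ex, abs=0.005), (ind, level)
            assert cloud.en == pytest.approx(en, abs=0.005), (ind, level)
            assert cloud.he == pytest.approx(he, abs=0.005), (ind, level)

    def test_identities_per_cell(self, table, standards):
        for name in table.indicator_names:
            for band, cloud in zip(table.scale(name).bands, standards.level_clouds(name)):
                assert 2 * cloud.ex == pytest.approx(band.cmin + band.cmax)
                assert 6 * cloud.en == pytest.approx(band.cmax - band.cmin)
                assert cloud.he == pytest.approx(0.1 * cloud.en)

    def test_expectations_increase_with_level(self, table, standards):
        for name in table.indicator_names + (AQI_KEY,):
            exs = [c.ex for c in standards.level_clouds(name)]
            assert exs == sorted(exs) and len(set(exs)) == len(exs)

    def test_shift_equivariance(self, table):
        doc = {
            "levels": list(table.levels),
            "index_scale": {"upper_limits": [50, 100, 150, 200, 300]},
            "indicators": {
                "PM2.5": {"unit": "ug/m3", "upper_limits": [35, 75, 115, 150, 250]}
            },
        }
        base = build_standard_set(load_grading_table(doc), k=0.1)
        doc["indicators"]["PM2.5"]["upper_limits"] = [35 + 10, 75 + 10, 115 + 10, 150 + 10, 250 + 10]
        # shifting every band bound by +c shifts each Ex by +c/2 for band 1
        # (whose lower bound stays 0) — so compare bands 2..5 where both
        # bounds move: Ex shifts by +c exactly and En is unchanged
        shifted = build_standard_set(load_grading_table(doc), k=0.1)
        for level in (2, 3, 4, 5):
            b, s = base.clouds[("PM2.5", level)], shifted.clouds[("PM2.5", level)]
            assert s.ex == pytest.approx(b.ex + 10)
            assert s.en == pytest.approx(b.en)

    def test_json_round_trip(self, standards, tmp_path):
        path = tmp_path / "standards.json"
        standards.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["k"] == 0.1
        assert doc["clouds"]["SO2/3"] == pytest.approx([312.5, 54.166666666666664, 5.416666666666667])


class TestIaqi:
    @pytest.mark.parametrize(
        "indicator, conc, expected",
        [
            ("PM2.5", 75.0, 100.0),  # breakpoint maps exactly
            ("PM2.5", 220.2, 270.2),  # hand interpolation on (150,250]->(200,300]
            ("PM10", 274.4, 162.2),  # hand interpolation on (250,350]->(150,200]
            ("NO2", 57.8, 72.25),  # hand interpolation on (40,80]->(50,100]
            ("PM2.5", 0.0, 0.0),
        ],
    )
    def test_interpolation(self, table, indicator, conc, expected):
        result = iaqi(indicator, conc, table)
        assert result.value == pytest.approx(expected)
        assert not result.above_scale

    def test_breakpoints_map_to_index_breakpoints(self, table):
        """Continuity: at every concentration breakpoint the index equals
        the corresponding index breakpoint exactly, from both sides."""
        for name in table.indicator_names:
            for band, ib in zip(table.scale(name).bands, table.index_bands):
                assert iaqi(name, band.cmax, table).value == pytest.approx(ib.cmax)
                eps = 1e-9 * band.cmax
                assert iaqi(name, band.cmax + eps, table).value == pytest.approx(
                    ib.cmax, abs=1e-5
                )

    def test_above_scale_extrapolates(self, table):
        result = iaqi("PM2.5", 300.0, table)
        assert result.above_scale
        assert result.value == pytest.approx(300 + (300 - 250) * 100 / 100)

    def test_value_in_index_band_when_on_scale(self, table):
        result = iaqi("SO2", 87.3, table)
        lo, hi = result.segment[2], result.segment[3]
        assert lo <= result.value <= hi

    def test_rounding_mode_ceils(self, table):
        assert iaqi("NO2", 57.8, table, rounding=True).value == 73.0

    def test_validation(self, table):
        with pytest.raises(ValueError):
            iaqi("PM2.5", -1.0, table)
        with pytest.raises(KeyError):
            iaqi("XX", 10.0, table)

    @given(
        name=st.sampled_from(["PM2.5", "PM10", "SO2", "CO", "NO2", "O3"]),
        c1=st.floats(min_value=0, max_value=2000),
        c2=st.floats(min_value=0, max_value=2000),
    )
    @settings(max_examples=80, deadline=None)
    def test_monotone_nondecreasing(self, table, name, c1, c2):
        lo, hi = sorted([c1, c2])
        assert iaqi(name, lo, table).value <= iaqi(name, hi, table).value + 1e-9


class TestAqiRecord:
    def test_heavy_day_dominated_by_pm25(self, table, november):
        row = november.iloc[4]  # 5 Nov
        res = aqi_record({n: row[n] for n in table.indicator_names}, table)
        assert res.aqi == pytest.approx(270.2)
        assert res.dominant == ("PM2.5",)

    def test_light_day_dominated_by_no2(self, table, november):
        row = november.iloc[1]  # 2 Nov
        res = aqi_record({n: row[n] for n in table.indicator_names}, table)
        assert res.aqi == pytest.approx(72.25)
        assert res.dominant == ("NO2",)

    def test_all_zero_concentrations(self, table):
        res = aqi_record({n: 0.0 for n in table.indicator_names}, table)
        assert res.aqi == 0.0
        assert set(res.dominant) == set(table.indicator_names)

    def test_aqi_is_max_of_iaqis(self, table, november):
        for _, row in november.head(10).iterrows():
            res = aqi_record({n: row[n] for n in table.indicator_names}, table)
            values = [r.value for r in res.iaqis.values()]
            assert res.aqi == max(values)
            assert all(res.aqi >= v for v in values)

    def test_missing_indicator_named(self, table):
        record = {n: 10.0 for n in table.indicator_names if n != "O3"}
        with pytest.raises(ValueError, match="O3"):
            aqi_record(record, table)
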