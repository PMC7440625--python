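"""Blank zeroing, per-cell normalization, control scaling, chlorophyll."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopleak import (
    AnalysisError,
    ConfigError,
    chlorophyll_concentration,
    normalize_per_cell,
    scale_to_control,
    zero_readings,
)


class TestZeroReadings:
    def test_mean_of_blanks_is_subtracted(self, tiny_measurements):
        zeroed = zero_readings(tiny_measurements)
        b1 = zeroed.set_index(["plate_id", "well"]).loc[("P1", "B1")]
        assert b1["venus"] == pytest.approx(150.0 - 50.0)
        assert b1["od750"] == pytest.approx(0.5)
        assert b1["chl"] == pytest.approx(100.0)

    def test_well_equal_to_blank_mean_zeroes_out(self, tiny_measurements):
        zeroed = zero_readings(tiny_measurements)
        b2 = zeroed.set_index(["plate_id", "well"]).loc[("P1", "B2")]
        assert np.allclose(b2[["od750", "venus", "chl"]].astype(float), 0.0)

    def test_blanks_are_consumed(self, tiny_measurements):
        zeroed = zero_readings(tiny_measurements)
        assert (zeroed["role"] == "sample").all()
        assert len(zeroed) == 3

    def test_per_plate_means_match_brute_force(self):
        """Each plate corrected by its own blanks on a 3-plate fixture."""
        rng = np.random.default_rng(1)
        rows = []
        for p in ("P1", "P2", "P3"):
            for i in range(3):
                rows.append((p, f"A{i + 1}", "blank", *rng.normal(10, 2, 3)))
            for i in range(5):
                rows.append((p, f"B{i + 1}", "sample", *rng.normal(100, 20, 3)))
        meas = pd.DataFrame(
            rows, columns=["plate_id", "well", "role", "od750", "venus", "chl"]
        )
        zeroed = zero_readings(meas)
        for _, row in zeroed.iterrows():
            blanks = meas[(meas["plate_id"] == row["plate_id"]) & (meas["role"] == "blank")]
            raw = meas.set_index(["plate_id", "well"]).loc[(row["plate_id"], row["well"])]
            for ch in ("od750", "venus", "chl"):
                expected = float(raw[ch]) - float(blanks[ch].mean())
                assert row[ch] == pytest.approx(expected, rel=1e-12)

    def test_plate_without_blanks_is_named(self, tiny_measurements):
        meas = tiny_measurements[
            ~((tiny_measurements["plate_id"] == "P2") & (tiny_measurements["role"] == "blank"))
        ]
        with pytest.raises(ConfigError, match="P2"):
            zero_readings(meas)

    def test_idempotent_when_blanks_read_zero(self, tiny_measurements):
        once = zero_readings(tiny_measurements)
        blanks = tiny_measurements[tiny_measurements["role"] == "blank"].copy()
        blanks[["od750", "venus", "chl"]] = 0.0
        again = zero_readings(pd.concat([blanks, once], ignore_index=True))
        key = ["plate_id", "well"]
        pd.testing.assert_frame_equal(
            once.sort_values(key).reset_index(drop=True),
            again.sort_values(key).reset_index(drop=True),
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(-1e4, 1e4, allow_nan=False))
    def test_channel_offset_invariance(self, offset):
        """A constant added to one channel on one plate (blanks and samples
        alike) leaves the zeroed values unchanged."""
        rows = [
            ("P1", "A1", "blank", 0.10, 48.0, 10.0),
            ("P1", "A2", "blank", 0.10, 52.0, 10.0),
            ("P1", "B1", "sample", 0.60, 150.0, 110.0),
        ]
        meas = pd.DataFrame(
            rows, columns=["plate_id", "well", "role", "od750", "venus", "chl"]
        )
        shifted = meas.copy()
        shifted["venus"] = shifted["venus"] + offset
        base = zero_readings(meas)
        moved = zero_readings(shifted)
        assert np.allclose(base["venus"], moved["venus"], atol=1e-8)


class TestNormalizePerCell:
    def test_ratio(self, tiny_measurements, tiny_layout):
        records = normalize_per_cell(zero_readings(tiny_measurements), tiny_layout)
        r = records.set_index(["plate_id", "well"])
        assert r.loc[("P1", "B1"), "normalized_venus"] == pytest.approx(100.0 / 0.5)

    def test_zero_denominator_flagged_invalid(self, tiny_measurements, tiny_layout):
        records = normalize_per_cell(zero_readings(tiny_measurements), tiny_layout)
        r = records.set_index(["plate_id", "well"])
        assert not r.loc[("P1", "B2"), "valid"]
        assert np.isnan(r.loc[("P1", "B2"), "normalized_venus"])

    def test_ratio_scale_invariance(self, tiny_measurements, tiny_layout):
        zeroed = zero_readings(tiny_measurements)
        doubled = zeroed.copy()
        doubled[["venus", "od750"]] = 2.0 * doubled[["venus", "od750"]]
        a = normalize_per_cell(zeroed, tiny_layout)
        b = normalize_per_cell(doubled, tiny_layout)
        valid = a["valid"] & b["valid"]
        assert np.allclose(
            a.loc[valid, "normalized_venus"], b.loc[valid, "normalized_venus"]
        )

    def test_chl_denominator(self, tiny_measurements, tiny_layout):
        records = normalize_per_cell(
            zero_readings(tiny_measurements), tiny_layout, denominator="chl"
        )
        r = records.set_index(["plate_id", "well"])
        assert r.loc[("P1", "B1"), "normalized_venus"] == pytest.approx(100.0 / 100.0)

    def test_unknown_denominator_is_usage_error(self, tiny_measurements, tiny_layout):
        with pytest.raises(ConfigError, match="denominator"):
            normalize_per_cell(
                zero_readings(tiny_measurements), tiny_layout, denominator="od600"
            )


class TestScaleToControl:
    def _records(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(12):
            rows.append(("no_venus", f"A{i + 1}", rng.uniform(40, 60)))
        for i in range(12):
            rows.append(("leaky", f"B{i + 1}", rng.uniform(40, 200)))
        df = pd.DataFrame(rows, columns=["construct", "well", "normalized_venus"])
        df["strain"], df["replicate"], df["plate_id"] = "T222", "rep1", "P1"
        df["valid"] = True
        return df

    def test_control_population_mean_is_one(self):
        scaled = scale_to_control(self._records(), "no_venus")
        controls = scaled[scaled["construct"] == "no_venus"]
        assert controls["control_scaled_venus"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_sample_at_twice_control_mean_maps_to_two(self):
        records = self._records()
        mean = records.loc[
            records["construct"] == "no_venus", "normalized_venus"
        ].mean()
        records.loc[records.index[-1], "normalized_venus"] = 2.0 * mean
        scaled = scale_to_control(records, "no_venus")
        assert scaled["control_scaled_venus"].iloc[-1] == pytest.approx(2.0, rel=1e-12)

    def test_matches_spreadsheet_style_recomputation(self):
        """Agreement to 12 significant digits with a cell-by-cell oracle."""
        records = self._records()
        scaled = scale_to_control(records, "no_venus")
        mean = records.loc[
            records["construct"] == "no_venus", "normalized_venus"
        ].mean()
        oracle = records["normalized_venus"] / mean
        assert np.allclose(scaled["control_scaled_venus"], oracle, rtol=1e-12)

    def test_commutes_with_positive_rescaling(self):
        records = self._records()
        scaled = scale_to_control(records, "no_venus")
        multiplied = records.copy()
        multiplied["normalized_venus"] *= 37.5
        scaled2 = scale_to_control(multiplied, "no_venus")
        assert np.allclose(
            scaled["control_scaled_venus"], scaled2["control_scaled_venus"], rtol=1e-12
        )

    def test_too_few_controls_is_analysis_error(self):
        records = self._records()
        records = records[records["construct"] != "no_venus"]
        with pytest.raises(AnalysisError):
            scale_to_control(records, "no_venus")

    def test_non_positive_control_mean_is_analysis_error(self):
        records = self._records()
        records.loc[records["construct"] == "no_venus", "normalized_venus"] = -1.0
        with pytest.raises(AnalysisError, match="non-positive"):
            scale_to_control(records, "no_venus")


class TestChlorophyll:
    def test_equal_absorbances_give_zero(self):
        assert chlorophyll_concentration(0.4, 0.4).concentration == 0.0

    def test_inverse_of_coefficient_gives_unity(self):
        est = chlorophyll_concentration(1.0 / 0.11, 0.0)
        assert est.concentration == pytest.approx(1.0)

    def test_printed_formula(self):
        assert chlorophyll_concentration(0.75, 0.05).concentration == pytest.approx(
            0.077
        )

    def test_negative_estimate_carries_warning(self):
        est = chlorophyll_concentration(0.1, 0.3)
        assert est.concentration < 0 and est.warning is not None

    def test_non_finite_input_rejected(self):
        with pytest.raises(ConfigError):
            chlorophyll_concentration(np.nan, 0.0)
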