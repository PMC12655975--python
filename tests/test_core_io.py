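"""Sample-table I/O, distribution specs and reference-bundle validation."""

import numpy as np
import pandas as pd
import pytest

import pterisk as pk
from pterisk.core_io import DistributionSpec, Medium, Pathway, Population, SampleTable


class TestLoadSamples:
    def test_well_formed_file_round_trips_identically(self, water_csv):
        table = pk.load_samples(water_csv, "surface_water")
        assert table.values.shape == (3, 10)
        assert not table.bdl_flags.any().any()
        assert table.unit == "ug/L"

    def test_write_read_round_trip_bit_identical(self, water_csv, tmp_path):
        table = pk.load_samples(water_csv, "surface_water")
        # introduce a BDL cell to exercise flag round-tripping
        table.detection_limits["Pb"] = 0.05
        table.values.iloc[0, 0] = 0.025
        table.bdl_flags.iloc[0, 0] = True
        out = tmp_path / "rt.csv"
        pk.write_samples(table, out)
        back = pk.load_samples(out, "surface_water")
        pd.testing.assert_frame_equal(back.values, table.values)
        pd.testing.assert_frame_equal(back.bdl_flags, table.bdl_flags)

    def test_bdl_marker_substitutes_half_detection_limit(self, tmp_path):
        path = tmp_path / "bdl.csv"
        path.write_text("site,Pb\nA,<0.05\nB,1.0\n")
        table = pk.load_samples(path, "soil", required_elements=("Pb",))
        assert table.values.loc["A", "Pb"] == pytest.approx(0.025)
        assert bool(table.bdl_flags.loc["A", "Pb"]) is True
        assert not table.bdl_flags.loc["B", "Pb"]
        assert table.values.loc["A", "Pb"] <= table.detection_limits["Pb"]

    def test_configured_detection_limit_flags_low_values(self, tmp_path):
        path = tmp_path / "dl.csv"
        path.write_text("site,Pb\nA,0.03\nB,1.0\n")
        table = pk.load_samples(
            path, "soil", required_elements=("Pb",), detection_limits={"Pb": 0.05}
        )
        assert table.values.loc["A", "Pb"] == pytest.approx(0.025)
        assert bool(table.bdl_flags.loc["A", "Pb"]) is True

    def test_missing_element_column_is_named(self, tmp_path, water_csv):
        df = pd.read_csv(water_csv).drop(columns=["Sb"])
        path = tmp_path / "missing.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="Sb"):
            pk.load_samples(path, "surface_water")

    @pytest.mark.parametrize(
        "cell, match",
        [("-1.0", "negative"), ("oops", "non-numeric")],
    )
    def test_bad_cells_raise_with_location(self, tmp_path, cell, match):
        path = tmp_path / "bad.csv"
        path.write_text(f"site,Pb\nA,{cell}\n")
        with pytest.raises(ValueError, match=match):
            pk.load_samples(path, "soil", required_elements=("Pb",))

    def test_tab_delimited_accepted(self, tmp_path):
        path = tmp_path / "tab.tsv"
        path.write_text("site\tPb\tCd\nA\t1.0\t0.2\n")
        table = pk.load_samples(path, "soil", required_elements=("Pb", "Cd"))
        assert table.values.loc["A", "Cd"] == 0.2


class TestSampleTable:
    def test_unit_must_match_medium(self):
        df = pd.DataFrame({"Pb": [1.0]}, index=["A"])
        with pytest.raises(ValueError, match="unit"):
            SampleTable(medium=Medium.surface_water, values=df, unit="mg/kg")

    def test_negative_values_rejected(self):
        df = pd.DataFrame({"Pb": [-1.0]}, index=["A"])
        with pytest.raises(ValueError, match="negative"):
            SampleTable(medium=Medium.soil, values=df)

    def test_duplicate_elements_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], columns=["Pb", "Pb"], index=["A"])
        with pytest.raises(ValueError, match="duplicate"):
            SampleTable(medium=Medium.soil, values=df)


class TestDistributionSpec:
    def test_point_spec_constant_vector(self):
        spec = DistributionSpec(kind="point", params={"value": 3.0})
        assert np.all(spec.sample(np.random.default_rng(0), 50) == 3.0)
        assert spec.central() == 3.0

    def test_degenerate_uniform_draws_exactly_one(self):
        spec = DistributionSpec(kind="uniform", params={"low": 1.0, "high": 1.0})
        assert np.all(spec.sample(np.random.default_rng(0), 100) == 1.0)

    def test_truncated_normal_all_positive_and_reproducible(self):
        spec = DistributionSpec(
            kind="normal", params={"mean": 15.0, "sd": 2.3}, truncation=(0.0, None)
        )
        a = spec.sample(np.random.default_rng(7), 10_000)
        b = spec.sample(np.random.default_rng(7), 10_000)
        assert (a > 0).all()
        np.testing.assert_array_equal(a, b)

    def test_untruncatable_bounds_error(self):
        spec = DistributionSpec(
            kind="normal", params={"mean": 0.0, "sd": 1.0}, truncation=(1e9, None)
        )
        with pytest.raises(ValueError, match="mass"):
            spec.sample(np.random.default_rng(0), 10)

    def test_invalid_parameter_sets_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec(kind="normal", params={"mean": 1.0, "sd": -1.0})
        with pytest.raises(ValueError):
            DistributionSpec(kind="triangular", params={"left": 2.0, "mode": 1.0, "right": 3.0})
        with pytest.raises(ValueError):
            DistributionSpec(kind="point", params={"wrong": 1.0})

    def test_lognormal_central_is_arithmetic_mean(self):
        spec = DistributionSpec(kind="lognormal", params={"mean": 200.0, "sd": 60.0})
        x = spec.sample(np.random.default_rng(1), 200_000)
        assert np.mean(x) == pytest.approx(200.0, rel=0.01)
        assert np.std(x, ddof=1) == pytest.approx(60.0, rel=0.02)


class TestReferenceBundle:
    def test_default_bundle_covers_all_elements_media_populations(self, refs):
        for el in pk.ELEMENTS:
            assert el in refs.toxicity
            assert el in refs.screening[Medium.surface_water]
            assert el in refs.screening[Medium.soil]
            assert Pathway.ingestion in refs.rfd[el]
        for pop in Population:
            for med in (Medium.surface_water, Medium.soil):
                specs = refs.exposure_specs(pop, med)
                assert {"r_ing", "ef", "ed", "bw", "sa", "af", "abs"} <= set(specs)

    def test_zero_screening_value_rejected(self):
        with pytest.raises(ValueError, match="Pb"):
            pk.ReferenceBundle(
                screening={"soil": {"Pb": 0.0}},
                toxicity={},
                rfd={},
                exposure={},
                unit_factor={"soil": 1e-6},
            )

    def test_elements_without_slope_factor_recorded_absent(self, refs):
        assert "Zn" not in refs.slope
        assert "V" not in refs.slope

    def test_missing_config_section_reports_key(self, tmp_path):
        path = tmp_path / "broken.yaml"
        path.write_text("screening: {}\ntoxicity: {}\n")
        with pytest.raises(ValueError, match="rfd|exposure|unit_factor"):
            pk.load_reference_bundle(path)


class TestValidate:
    def test_matching_table_and_bundle_passes(self, water_csv, refs):
        table = pk.load_samples(water_csv, "surface_water")
        report = pk.validate(table, refs)
        assert report.passed
        assert report.errors == []

    def test_element_without_screening_value_is_an_error(self, refs):
        df = pd.DataFrame({"Hg": [0.1, 0.2]}, index=["A", "B"])
        table = SampleTable(medium=Medium.soil, values=df)
        report = pk.validate(table, refs)
        assert not report.passed
        assert any("Hg" in msg for _, msg in report.errors)

    def test_validate_does_not_mutate_inputs(self, water_csv, refs):
        table = pk.load_samples(water_csv, "surface_water")
        before = table.values.copy()
        pk.validate(table, refs)
        pd.testing.assert_frame_equal(table.values, before)
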