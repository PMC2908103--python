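"""GAL/CSV readers and writers, and the layout consistency audit."""

import dataclasses

import pytest

from pmtcal import (FormatError, LayoutValidationError, Role, ScanObservation,
                    SimulationConfig, SlideColumn, SlideLayout,
                    check_layout_consistency, make_slide_layout,
                    parse_density, read_gal, read_intensity_table,
                    read_manual_table, simulate_scan, write_fixture_bundle,
                    write_gal, write_intensity_table, write_manual_table)
from tests.conftest import AGILENT_CY3_100

# GAL excerpt mirroring a vendor layout file whose concentration series
# starts at column 5 while columns 2-4 are blanks and column 1 a marker
VENDOR_GAL = "\n".join([
    "ATF\t1.0",
    "2\t5",
    '"Type=GenePix ArrayList V1.0"',
    '"BlockCount=1"',
    "Block\tColumn\tRow\tName\tID",
    "1\t1\t1\tMarker\tCy3",
    "1\t2\t1\t0\tCy3",
    "1\t3\t1\t0\tCy3",
    "1\t4\t1\t0\tCy3",
    "1\t5\t1\t1.10E-03\tCy3",
    "1\t6\t1\t2.19E-03\tCy3",
    "1\t7\t1\t4.38E-03\tCy3",
    "1\t8\t1\t8.76E-03\tCy3",
]) + "\n"


@pytest.fixture()
def bundle(tmp_path, layout, noisy_obs):
    return write_fixture_bundle(layout, noisy_obs, tmp_path / "bundle")


class TestParseDensity:
    @pytest.mark.parametrize("text, value", [
        ("1.47E+05", 1.47e5),
        ("1.47E + 05", 1.47e5),       # spaces inside the exponent
        ("1.47 e +05", 1.47e5),
        ("2.19e-03", 2.19e-3),
        ('"8.76E - 03"', 8.76e-3),
        ("0", 0.0),
    ])
    def test_accepted_spellings(self, text, value):
        assert parse_density(text) == value

    def test_non_numeric_rejected(self):
        with pytest.raises(ValueError):
            parse_density("Buffer")


class TestGal:
    def test_round_trip(self, tmp_path, layout):
        path = tmp_path / "slide.gal"
        write_gal(layout, path)
        back, records = read_gal(path)
        assert back == layout
        assert len(records) == layout.n_spots

    def test_vendor_excerpt_parses(self, tmp_path):
        path = tmp_path / "vendor.gal"
        path.write_text(VENDOR_GAL)
        parsed, records = read_gal(path)
        col5 = parsed.column(5)
        assert col5.role == Role.DILUTION
        assert col5.density == 1.10e-3
        assert col5.dye == "Cy3"
        assert parsed.column(1).role == Role.MARKER
        assert parsed.column(1).density is None
        assert parsed.column(2).role == Role.BLANK

    def test_malformed_header_reports_line(self, tmp_path):
        path = tmp_path / "bad.gal"
        path.write_text("GPR\t1.0\n1\t5\n")
        with pytest.raises(FormatError, match="line 1"):
            read_gal(path)

    def test_duplicate_coordinates_rejected(self, tmp_path):
        path = tmp_path / "dup.gal"
        path.write_text(
            "ATF\t1.0\n0\t5\nBlock\tColumn\tRow\tName\tID\n"
            "1\t1\t1\t0\tCy3\n1\t1\t1\t0\tCy3\n")
        with pytest.raises(LayoutValidationError, match="duplicate"):
            read_gal(path)


class TestIntensityTable:
    def test_round_trip(self, tmp_path, noisy_obs):
        path = tmp_path / "intens.csv"
        write_intensity_table(noisy_obs, None, path)
        assert read_intensity_table(path) == noisy_obs

    def test_empty_table_is_fine(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("spot_id,block,column,row,series,channel,pmt_gain,"
                        "x_nominal,signal,saturated\n")
        assert read_intensity_table(path) == []

    def test_signal_at_ceiling_is_saturated(self, tmp_path):
        path = tmp_path / "sat.csv"
        path.write_text("spot_id,block,column,row,series,channel,pmt_gain,"
                        "x_nominal,signal,saturated\n"
                        "s1,1,1,1,1,Cy3,100,147000.0,65535,0\n")
        [ob] = read_intensity_table(path, ceiling=65535)
        assert ob.saturated

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "missing.csv"
        path.write_text("spot_id,block,column,row,series,channel,pmt_gain,"
                        "x_nominal,saturated\n")
        with pytest.raises(FormatError, match="signal"):
            read_intensity_table(path)

    def test_negative_signal_reports_row(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("spot_id,block,column,row,series,channel,pmt_gain,"
                        "x_nominal,signal,saturated\n"
                        "s1,1,1,1,1,Cy3,100,1.0,-5,0\n")
        with pytest.raises(FormatError, match="row 2"):
            read_intensity_table(path)


class TestManualTable:
    def test_round_trip(self, tmp_path, layout):
        path = tmp_path / "manual.csv"
        write_manual_table(layout, path)
        back = read_manual_table(path, replicates_per_column=20)
        assert back == layout

    def test_spaced_exponents_accepted(self, tmp_path):
        path = tmp_path / "manual.csv"
        path.write_text("series,density_or_role\n1,1.47E + 05\n2,7.35E + 04\n"
                        "28,Buffer\n29,0\n32,Position Marker\n")
        parsed = read_manual_table(path)
        assert parsed.column(1).density == 1.47e5
        assert parsed.column(28).role == Role.BUFFER
        assert parsed.column(32).role == Role.MARKER


class TestConsistencyAudit:
    def test_layout_matches_itself(self, layout):
        report = check_layout_consistency(layout, layout)
        assert report.consistent
        assert report.n_match == 32

    def test_buffer_vs_concentration_conflict_flagged(self, layout):
        # manual declares column 28 "Buffer"; the layout file assigns a
        # numeric dye concentration to the same column
        gal_cols = tuple(
            SlideColumn(28, Role.DILUTION, c.dye, 1.10e-3)
            if c.index == 28 else c
            for c in layout.columns)
        gal = SlideLayout(gal_cols, layout.replicates_per_column)
        report = check_layout_consistency(layout, gal)
        assert not report.consistent
        [verdict] = [v for v in report.verdicts if v.verdict == "mismatch"]
        assert verdict.column == 28
        assert "buffer" in verdict.manual_value
        assert "0.0011" in verdict.gal_value or "1.1E-03" in verdict.gal_value.upper()
        assert "manual claims" in verdict.detail

    def test_densities_within_tolerance_match(self, layout):
        nudged_cols = tuple(
            dataclasses.replace(c, density=c.density * 1.005)
            if c.role == Role.DILUTION else c
            for c in layout.columns)
        nudged = SlideLayout(nudged_cols, layout.replicates_per_column)
        assert check_layout_consistency(layout, nudged,
                                        tolerance=0.01).consistent

    def test_density_comparison_is_symmetric(self, layout):
        nudged_cols = tuple(
            dataclasses.replace(c, density=c.density * 1.05)
            if c.role == Role.DILUTION else c
            for c in layout.columns)
        nudged = SlideLayout(nudged_cols, layout.replicates_per_column)
        ab = check_layout_consistency(layout, nudged)
        ba = check_layout_consistency(nudged, layout)
        assert ab.n_mismatch == ba.n_mismatch == 27

    def test_differing_column_counts_audits_overlap(self, layout):
        partial = SlideLayout(layout.columns[:10],
                              layout.replicates_per_column)
        report = check_layout_consistency(partial, layout)
        assert report.notes  # difference reported
        assert report.n_match == 10
        assert report.n_missing == 22

    def test_verdict_counts_sum_to_columns_audited(self, layout):
        report = check_layout_consistency(layout, layout)
        assert (report.n_match + report.n_mismatch + report.n_missing
                == len(report.verdicts))


class TestFixtureBundle:
    def test_bundle_round_trips(self, bundle, layout, noisy_obs):
        gal_layout, _ = read_gal(bundle["gal"])
        assert gal_layout == layout
        assert read_intensity_table(bundle["intensities"]) == noisy_obs
        manual = read_manual_table(bundle["manual"],
                                   replicates_per_column=20)
        assert manual == layout

    def test_bundle_is_self_consistent(self, bundle):
        manual = read_manual_table(bundle["manual"],
                                   replicates_per_column=20)
        gal_layout, _ = read_gal(bundle["gal"])
        report = check_layout_consistency(manual, gal_layout)
        assert report.consistent and not report.notes
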