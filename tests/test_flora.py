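"""Flowering-record model, midpoint/duration reduction, richness counting, I/O."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mdephen import (
    FloweringRecord,
    TableDialect,
    TemporalDomain,
    load_table1_fixture,
    observed_richness,
    read_climate_table,
    read_flora_table,
    to_range,
    truncated_durations,
    write_climate_table,
    write_flora_table,
)
from mdephen.flora import ValidationError

records_strategy = st.builds(
    FloweringRecord,
    species_id=st.text(
        alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd")), min_size=1, max_size=8
    ),
    region_id=st.sampled_from(["regA", "regB"]),
    growth_form=st.sampled_from(["woody", "herbaceous"]),
    first_month=st.integers(1, 12),
    last_month=st.integers(1, 12),
)


class TestFloweringRecord:
    def test_wrap_flag(self):
        assert not FloweringRecord("s", "r", "woody", 3, 7).wraps
        assert FloweringRecord("s", "r", "woody", 11, 2).wraps

    @pytest.mark.parametrize("first,last", [(0, 5), (3, 13), (1, 0)])
    def test_month_out_of_range_rejected(self, first, last):
        with pytest.raises(ValidationError):
            FloweringRecord("s", "r", "woody", first, last)

    def test_bad_growth_form_rejected(self):
        with pytest.raises(ValidationError):
            FloweringRecord("s", "r", "shrubby", 3, 7)


class TestToRange:
    @pytest.mark.parametrize(
        "first,last,duration,midpoint,wraps",
        [
            (3, 7, 5, 5.0, False),
            (4, 5, 2, 4.5, False),  # even duration -> half-month midpoint
            (11, 2, 4, 0.5, True),  # Nov..Feb linearizes to 11..14, mid 12.5 -> 0.5
            (1, 12, 12, 6.5, False),
            (12, 1, 2, 0.5, True),
            (7, 7, 1, 7.0, False),
        ],
    )
    def test_examples(self, first, last, duration, midpoint, wraps):
        r = to_range(FloweringRecord("s", "r", "woody", first, last))
        assert r.duration == duration
        assert r.midpoint == pytest.approx(midpoint)
        assert r.wraps is wraps

    @given(records_strategy)
    def test_duration_counts_calendar_months(self, rec):
        assert to_range(rec).duration == len(rec.months())

    @given(st.integers(1, 12), st.integers(1, 12))
    def test_midpoint_in_unit_interval(self, first, last):
        r = to_range(FloweringRecord("s", "r", "herbaceous", first, last))
        assert 0 < r.midpoint <= 12


class TestTemporalDomain:
    def test_linearized_wrap_domain(self):
        d = TemporalDomain(11, 14)  # Nov..Feb
        assert d.n_bins == 4
        assert d.months() == (11, 12, 1, 2)

    def test_period_string(self):
        assert str(TemporalDomain(4, 10)) == "4-10"

    def test_too_long_rejected(self):
        with pytest.raises(ValidationError):
            TemporalDomain(1, 13)


class TestObservedRichness:
    def test_overlap_counts(self):
        recs = [
            FloweringRecord("a", "r", "woody", 4, 6),
            FloweringRecord("b", "r", "woody", 5, 5),
        ]
        curve = observed_richness(recs, TemporalDomain(4, 6))
        assert curve.counts == (1, 2, 1)

    def test_full_domain_species(self):
        recs = [FloweringRecord("a", "r", "woody", 4, 10)]
        curve = observed_richness(recs, TemporalDomain(4, 10))
        assert curve.counts == (1,) * 7

    def test_nonoverlapping_species_dropped(self):
        recs = [FloweringRecord("a", "r", "woody", 1, 2)]
        curve = observed_richness(recs, TemporalDomain(4, 10))
        assert curve.counts == (0,) * 7
        assert curve.n_dropped == 1

    def test_empty_records_zero_curve(self):
        curve = observed_richness([], TemporalDomain(4, 6))
        assert curve.counts == (0, 0, 0)

    def test_wrap_species_in_wrap_domain(self, small_flora):
        curve = observed_richness(small_flora, TemporalDomain(11, 14))
        # only sp3 (Nov-Feb) overlaps Nov..Feb
        assert curve.counts == (1, 1, 1, 1)
        assert curve.n_dropped == 2

    @given(st.lists(records_strategy, max_size=20), st.integers(1, 12), st.integers(1, 12))
    def test_total_count_equals_total_overlap(self, recs, start, length):
        domain = TemporalDomain(start, start + min(length, 12) - 1)
        curve = observed_richness(recs, domain)
        assert sum(curve.counts) == sum(truncated_durations(recs, domain))


class TestIO:
    def test_flora_roundtrip(self, tmp_path, small_flora):
        path = tmp_path / "flora.csv"
        write_flora_table(small_flora, path)
        table = read_flora_table(path)
        assert list(table) == small_flora
        assert table.n_excluded == 0

    @given(st.lists(records_strategy, max_size=15))
    def test_flora_roundtrip_property(self, recs):
        import io, tempfile, os

        fd, path = tempfile.mkstemp(suffix=".csv")
        os.close(fd)
        try:
            write_flora_table(recs, path)
            assert list(read_flora_table(path)) == recs
        finally:
            os.unlink(path)

    def test_incomplete_rows_excluded_and_counted(self, tmp_path):
        path = tmp_path / "flora.csv"
        path.write_text(
            "species_id,region_id,growth_form,first_month,last_month\n"
            "sp1,Hainan,woody,3,7\n"
            "sp2,Hainan,woody,5,\n"
            "sp3,Hainan,herbaceous,,\n"
            "sp4,X,herbaceous,11,2\n"
        )
        table = read_flora_table(path)
        assert len(table) == 2
        assert table.n_excluded == 2
        assert table.records[1].wraps

    def test_bad_month_names_row(self, tmp_path):
        path = tmp_path / "flora.csv"
        path.write_text(
            "species_id,region_id,growth_form,first_month,last_month\nsp1,X,woody,13,7\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_flora_table(path)

    def test_custom_dialect(self, tmp_path):
        path = tmp_path / "flora.tsv"
        path.write_text("sp\tprov\tform\tstart\tend\nsp1\tHainan\twoody\t3\t7\n")
        dialect = TableDialect(
            delimiter="\t",
            species_col="sp",
            region_col="prov",
            growth_form_col="form",
            first_col="start",
            last_col="end",
        )
        table = read_flora_table(path, dialect)
        assert table.records[0] == FloweringRecord("sp1", "Hainan", "woody", 3, 7)

    def test_climate_roundtrip(self, tmp_path):
        from mdephen import ClimateRecord

        recs = [ClimateRecord("regA", m, -5.0 + m, 50.0 * m, 150.0) for m in range(1, 13)]
        path = tmp_path / "climate.csv"
        write_climate_table(recs, path)
        assert read_climate_table(path) == recs


class TestTable1Fixture:
    def test_has_27_provinces(self):
        assert len(load_table1_fixture()) == 27

    def test_spot_values(self):
        rows = {r.province: r for r in load_table1_fixture()}
        hainan = rows["Hainan"]
        assert hainan.latitude == pytest.approx(19.222)
        assert hainan.fit("all").r2 == pytest.approx(0.783)
        assert hainan.fit("woody").p == pytest.approx(0.003)
        assert str(rows["Heilongjiang"].fit("all").period) == "4-10"
        assert rows["Shanxi"].fit("all").r2 == pytest.approx(0.94)

    def test_censored_p_flagged(self):
        rows = {r.province: r for r in load_table1_fixture()}
        assert rows["Hainan"].fit("all").p_censored
        assert not rows["Hainan"].fit("woody").p_censored
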