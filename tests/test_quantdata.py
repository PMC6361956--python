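"""Spectrum-table IO, design validation and the minimum-spectra filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexdiff import (
    CHANNELS,
    FormatError,
    IntegrityError,
    SpectrumTable,
    filter_min_spectra,
    read_design,
    read_spectrum_table,
    validate_design,
    write_design,
    write_spectrum_table,
)


def _rows(n, protein="P1", run="plex1", base=10):
    rows = []
    for i in range(n):
        row = {
            "protein": protein,
            "peptide": f"{protein}_pep1",
            "run": run,
            "spectrum": f"{run}.s{i}",
        }
        row.update({f"ch{c}": base + i for c in CHANNELS})
        rows.append(row)
    return rows


def _write(tmp_path, rows, name="records.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


class TestReadSpectrumTable:
    def test_valid_rows_round_trip(self, tmp_path):
        path = _write(tmp_path, _rows(3))
        table, report = read_spectrum_table(path)
        assert len(table) == 3
        assert report.rejected == []
        assert report.n_rows == report.n_loaded == 3
        out = tmp_path / "again.tsv"
        write_spectrum_table(table, out)
        table2, _ = read_spectrum_table(out)
        assert table == table2

    def test_all_zero_spectrum_rejected_with_reason(self, tmp_path):
        rows = _rows(2)
        rows.append({**_rows(1, run="plex9")[0], **{f"ch{c}": 0 for c in CHANNELS}})
        table, report = read_spectrum_table(_write(tmp_path, rows))
        assert len(table) == 2
        assert len(report.rejected) == 1
        assert "all-zero" in report.rejected[0][1]
        # no row vanishes silently
        assert report.n_rows == report.n_loaded + len(report.rejected)

    def test_fractional_count_rounded_half_to_even(self, tmp_path):
        rows = _rows(1)
        rows[0]["ch114"] = "12.4"
        rows[0]["ch115"] = "12.5"  # rounds to 12, not 13
        table, report = read_spectrum_table(_write(tmp_path, rows))
        rec = next(table.records())
        assert rec.counts[114] == 12
        assert rec.counts[115] == 12
        assert report.rounded_rows == [0]

    def test_missing_column_names_the_column(self, tmp_path):
        rows = _rows(1)
        del rows[0]["ch121"]
        with pytest.raises(FormatError, match="ch121"):
            read_spectrum_table(_write(tmp_path, rows))

    def test_duplicate_run_spectrum_is_integrity_error(self, tmp_path):
        rows = _rows(1) + _rows(1)
        with pytest.raises(IntegrityError, match="duplicate"):
            read_spectrum_table(_write(tmp_path, rows))

    def test_negative_count_is_integrity_error(self, tmp_path):
        rows = _rows(1)
        rows[0]["ch116"] = -3
        with pytest.raises(IntegrityError, match="negative"):
            read_spectrum_table(_write(tmp_path, rows))

    def test_nonunique_peptide_rows_dropped(self, tmp_path):
        rows = _rows(3)
        for i, r in enumerate(rows):
            r["unique"] = "1" if i < 2 else "0"
        table, report = read_spectrum_table(_write(tmp_path, rows))
        assert len(table) == 2
        assert report.n_nonunique_dropped == 1

    def test_schema_renames_columns(self, tmp_path):
        rows = _rows(1)
        df = pd.DataFrame(rows).rename(columns={"protein": "Accession"})
        path = tmp_path / "r.tsv"
        df.to_csv(path, sep="\t", index=False)
        table, _ = read_spectrum_table(path, schema={"protein": "Accession"})
        assert table.proteins == ["P1"]


class TestDesign:
    def test_round_trip_and_lookup(self, tmp_path, small_study):
        _, design, _ = small_study
        path = tmp_path / "design.tsv"
        write_design(design, path)
        again = read_design(path)
        assert design == again
        row = again.sample_for("plex1", 113)
        assert row["group"] == "reference"

    def test_validate_flags_missing_run_as_fatal(self, small_study):
        table, design, _ = small_study
        sub = design.frame[design.frame["run"] != "plex3"]
        from plexdiff.quantdata import StudyDesign

        report = validate_design(StudyDesign(sub), table)
        assert any("plex3" in msg for msg in report.fatal)
        assert not report.ok

    def test_generator_design_is_clean(self, small_study):
        table, design, _ = small_study
        report = validate_design(design, table)
        assert report.ok
        assert report.warnings == []

    def test_layout_deviation_is_warning_not_fatal(self, small_study):
        table, design, _ = small_study
        frame = design.frame.copy()
        # recast one reference digest as an extra control sample
        i = frame[(frame["run"] == "plex1") & (frame["channel"] == 119)].index[0]
        frame.loc[i, ["group", "subject", "digest"]] = ["control", "x", "dx"]
        from plexdiff.quantdata import StudyDesign

        report = validate_design(StudyDesign(frame), table)
        assert report.ok
        assert any("plex1" in w for w in report.warnings)


class TestFilterMinSpectra:
    def test_default_threshold_drops_one_and_two_spectrum_proteins(self):
        rows = _rows(2, protein="A") + _rows(3, protein="B", run="plex2")
        table = SpectrumTable(pd.DataFrame(rows))
        kept, report = filter_min_spectra(table)
        assert report.dropped_proteins == {"A"}
        assert report.kept_proteins == {"B"}
        assert kept.proteins == ["B"]

    def test_threshold_one_keeps_everything(self):
        rows = _rows(1, protein="A") + _rows(2, protein="B", run="plex2")
        table = SpectrumTable(pd.DataFrame(rows))
        kept, report = filter_min_spectra(table, min_spectra=1)
        assert report.dropped_proteins == set()
        assert len(kept) == 3

    def test_counts_pool_across_runs(self):
        # 2 spectra in one run + 1 in another = 3 total -> kept at default
        rows = _rows(2, protein="A") + _rows(1, protein="A", run="plex2")
        table = SpectrumTable(pd.DataFrame(rows))
        kept, report = filter_min_spectra(table)
        assert report.kept_proteins == {"A"}

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=8),
        threshold=st.integers(min_value=1, max_value=7),
    )
    @settings(max_examples=25, deadline=None)
    def test_monotone_and_idempotent(self, counts, threshold):
        rows = []
        for i, n in enumerate(counts):
            rows += _rows(n, protein=f"P{i}", run=f"plex{i}")
        table = SpectrumTable(pd.DataFrame(rows))
        kept, report = filter_min_spectra(table, threshold)
        expected = {f"P{i}" for i, n in enumerate(counts) if n >= threshold}
        assert report.kept_proteins == expected
        # idempotent
        kept2, report2 = filter_min_spectra(kept, threshold)
        assert report2.kept_proteins == expected and len(kept2) == len(kept)
        # monotone: higher threshold never adds proteins
        kept3, report3 = filter_min_spectra(table, threshold + 1)
        assert report3.kept_proteins <= expected

    def test_partition_exact(self):
        rows = []
        for i, n in enumerate([1, 2, 3, 4, 5]):
            rows += _rows(n, protein=f"P{i}", run=f"plex{i}")
        table = SpectrumTable(pd.DataFrame(rows))
        _, report = filter_min_spectra(table)
        assert len(report.kept_proteins) == 3
        assert report.kept_proteins | report.dropped_proteins == set(
            report.spectra_per_protein
        )
        assert not report.kept_proteins & report.dropped_proteins
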