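"""Spectrum-level quantification tables and study designs.

The observational unit is one identified MS/MS spectrum carrying eight
iTRAQ reporter-ion counts (channels 113-119 and 121).  Time-of-flight
instruments record reporter intensities as discrete ion counts, which is
what makes a Poisson likelihood natural downstream.  This module owns the
on-disk TSV dialect, load-time validation, the study-design table mapping
(run, channel) -> sample -> {subject, group, digest}, and the
minimum-spectra quality filter applied before differential analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, IntegrityError

#: iTRAQ 8-plex reporter channels, in mass order.
CHANNELS: tuple[int, ...] = (113, 114, 115, 116, 117, 118, 119, 121)

#: Channel every within-run log ratio is taken against.
REFERENCE_CHANNEL: int = 113

#: Column names used for the counts in the TSV dialect.
COUNT_COLUMNS: tuple[str, ...] = tuple(f"ch{c}" for c in CHANNELS)

_ID_COLUMNS = ("protein", "peptide", "run", "spectrum")

#: Valid values of the design table's ``group`` column.
GROUPS = ("case", "control", "reference")


class SpectrumRecord(NamedTuple):
    """One identified spectrum's reporter-ion counts with provenance."""

    spectrum_id: str
    run_id: str
    protein_id: str
    peptide_id: str
    counts: dict[int, int]


@dataclass
class LoadReport:
    """What happened while reading a spectrum table."""

    n_rows: int = 0
    n_loaded: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)
    rounded_rows: list[int] = field(default_factory=list)
    n_nonunique_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_loaded": self.n_loaded,
            "rejected": [{"row": r, "reason": why} for r, why in self.rejected],
            "rounded_rows": list(self.rounded_rows),
            "n_nonunique_dropped": self.n_nonunique_dropped,
        }


class SpectrumTable:
    """A validated collection of spectrum records backed by a DataFrame.

    Columns: protein, peptide, run, spectrum, ch113..ch121 (int64).
    ``(run, spectrum)`` is unique; every row has at least one positive count.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in (*_ID_COLUMNS, *COUNT_COLUMNS) if c not in frame.columns]
        if missing:
            raise FormatError(f"spectrum table missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, [*_ID_COLUMNS, *COUNT_COLUMNS]].reset_index(drop=True)
        counts = frame[list(COUNT_COLUMNS)].to_numpy()
        if (counts < 0).any():
            raise IntegrityError("negative reporter-ion count")
        if (counts.sum(axis=1) == 0).any():
            raise IntegrityError("all-zero spectrum in table")
        dup = frame.duplicated(subset=["run", "spectrum"])
        if dup.any():
            pair = frame.loc[dup.idxmax(), ["run", "spectrum"]]
            raise IntegrityError(
                f"duplicate (run, spectrum): ({pair['run']}, {pair['spectrum']})"
            )
        frame[list(COUNT_COLUMNS)] = counts.astype(np.int64)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:  # order-insensitive content equality
        if not isinstance(other, SpectrumTable):
            return NotImplemented
        key = ["run", "spectrum"]
        a = self.frame.sort_values(key).reset_index(drop=True)
        b = other.frame.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.frame["protein"].unique())

    @property
    def runs(self) -> list[str]:
        return sorted(self.frame["run"].unique())

    def spectra_per_protein(self) -> dict[str, int]:
        return self.frame.groupby("protein").size().to_dict()

    def for_protein(self, protein_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["protein"] == protein_id]
        if sub.empty:
            raise KeyError(f"protein {protein_id!r} not present in table")
        return sub

    def records(self) -> Iterable[SpectrumRecord]:
        for row in self.frame.itertuples(index=False):
            yield SpectrumRecord(
                spectrum_id=row.spectrum,
                run_id=row.run,
                protein_id=row.protein,
                peptide_id=row.peptide,
                counts={c: int(getattr(row, f"ch{c}")) for c in CHANNELS},
            )


def read_spectrum_table(
    path, schema: Mapping[str, str] | None = None
) -> tuple[SpectrumTable, LoadReport]:
    """Read a tab-separated spectrum table, validating as we go.

    ``schema`` optionally maps logical column names (protein, peptide, run,
    spectrum, unique, ch113..ch121) to the file's actual header names.
    Rows are rejected (recorded in the report, never silently dropped) when
    all eight counts are zero; rows whose ``unique`` flag is falsy are
    dropped as shared-peptide evidence.  Non-integer reporter values are
    rounded half-to-even and flagged.  Duplicated (run, spectrum) pairs or
    negative counts abort the load.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path, sep="\t", dtype=str)
    rename = {schema.get(k, k): k for k in (*_ID_COLUMNS, "unique", *COUNT_COLUMNS)}
    raw = raw.rename(columns=rename)
    missing = [c for c in (*_ID_COLUMNS, *COUNT_COLUMNS) if c not in raw.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")

    report = LoadReport(n_rows=len(raw))

    if "unique" in raw.columns:
        uniq = raw["unique"].str.strip().str.lower().isin(["1", "true", "yes", "y"])
        report.n_nonunique_dropped = int((~uniq).sum())
        raw = raw[uniq]

    counts = raw[list(COUNT_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = counts.isna().any(axis=1)
    for row in raw.index[bad]:
        report.rejected.append((int(row), "unparseable count"))
    raw, counts = raw[~bad], counts[~bad]

    neg = (counts < 0).any(axis=1)
    if neg.any():
        raise IntegrityError(f"negative count at row {int(raw.index[neg][0])}")

    rounded = np.rint(counts.to_numpy())  # rint rounds half to even
    frac = np.abs(counts.to_numpy() - rounded) > 1e-9
    for row in raw.index[frac.any(axis=1)]:
        report.rounded_rows.append(int(row))

    allzero = rounded.sum(axis=1) == 0
    for row in raw.index[allzero]:
        report.rejected.append((int(row), "all-zero spectrum"))

    keep = ~allzero
    frame = raw.loc[keep, list(_ID_COLUMNS)].copy()
    frame[list(COUNT_COLUMNS)] = rounded[keep].astype(np.int64)

    dup = frame.duplicated(subset=["run", "spectrum"])
    if dup.any():
        pair = frame.loc[dup.idxmax(), ["run", "spectrum"]]
        raise IntegrityError(
            f"duplicate (run, spectrum): ({pair['run']}, {pair['spectrum']})"
        )

    table = SpectrumTable(frame.reset_index(drop=True))
    report.n_loaded = len(table)
    return table, report


def write_spectrum_table(table: SpectrumTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


class StudyDesign:
    """Plex/channel -> sample assignments plus sample metadata.

    Backed by a DataFrame with columns run, channel, sample, subject,
    group, digest.  Each run must assign all eight channels exactly once.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ("run", "channel", "sample", "subject", "group", "digest")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise FormatError(f"design missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, list(required)].reset_index(drop=True)
        frame["channel"] = frame["channel"].astype(int)
        bad_group = ~frame["group"].isin(GROUPS)
        if bad_group.any():
            raise FormatError(
                f"invalid group value {frame.loc[bad_group.idxmax(), 'group']!r}"
            )
        for run, sub in frame.groupby("run"):
            if sorted(sub["channel"]) != sorted(CHANNELS):
                raise DesignError(f"run {run!r} does not assign all 8 channels once")
        if frame.duplicated(subset=["sample"]).any():
            raise DesignError("sample identifiers must be unique across the design")
        self.frame = frame

    @property
    def runs(self) -> list[str]:
        return sorted(self.frame["run"].unique())

    @property
    def channels(self) -> tuple[int, ...]:
        return CHANNELS

    @property
    def reference_channel(self) -> int:
        return REFERENCE_CHANNEL

    def sample_for(self, run: str, channel: int) -> pd.Series:
        sub = self.frame[(self.frame["run"] == run) & (self.frame["channel"] == channel)]
        if sub.empty:
            raise KeyError(f"no sample assigned to ({run}, {channel})")
        return sub.iloc[0]

    def samples(self) -> pd.DataFrame:
        return self.frame.copy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyDesign):
            return NotImplemented
        key = ["run", "channel"]
        a = self.frame.sort_values(key).reset_index(drop=True)
        b = other.frame.sort_values(key).reset_index(drop=True)
        return a.equals(b)


def read_design(path) -> StudyDesign:
    return StudyDesign(pd.read_csv(path, sep="\t", dtype={"channel": int}))


def write_design(design: StudyDesign, path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


@dataclass
class DesignReport:
    """Outcome of cross-checking a design against a spectrum table."""

    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_design(design: StudyDesign, table: SpectrumTable) -> DesignReport:
    """Cross-check the design against the data.

    Runs present in the data but absent from the design, and channels left
    unassigned, are fatal.  A plex deviating from the canonical
    2-reference-digest + 3-case + 3-control layout is only a warning, since
    real designs may differ.
    """
    report = DesignReport()
    design_runs = set(design.runs)
    for run in table.runs:
        if run not in design_runs:
            report.fatal.append(f"run {run!r} present in data but absent from design")
    for run, sub in design.frame.groupby("run"):
        missing = set(CHANNELS) - set(sub["channel"])
        if missing:  # unreachable through StudyDesign, but guard raw frames
            report.fatal.append(f"run {run!r} leaves channels {sorted(missing)} unassigned")
        ref = sub[sub["group"] == "reference"]
        layout = sub["group"].value_counts().to_dict()
        if (
            layout.get("reference") != 2
            or layout.get("case") != 3
            or layout.get("control") != 3
        ):
            report.warnings.append(
                f"run {run!r} layout {layout} differs from 2 reference / 3 case / 3 control"
            )
        else:
            if ref["digest"].nunique() != 2 or ref["subject"].nunique() != 1:
                report.warnings.append(
                    f"run {run!r}: reference pool should be one subject in two digests"
                )
    return report


@dataclass
class FilterReport:
    """Result of the minimum-spectra quality filter."""

    kept_proteins: set[str]
    dropped_proteins: set[str]
    spectra_per_protein: dict[str, int]
    min_spectra: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "min_spectra": self.min_spectra,
                    "kept_proteins": sorted(self.kept_proteins),
                    "dropped_proteins": sorted(self.dropped_proteins),
                    "spectra_per_protein": dict(sorted(self.spectra_per_protein.items())),
                },
                fh,
                indent=1,
            )


def filter_min_spectra(
    table: SpectrumTable, min_spectra: int = 3
) -> tuple[SpectrumTable, FilterReport]:
    """Drop proteins quantified by fewer than ``min_spectra`` spectra.

    Counts are totals across all runs of the region.  Proteins below the
    threshold are removed entirely; both sets are enumerated in the report.
    The default of 3 retains only proteins whose quantification rests on at
    least three spectra.
    """
    if min_spectra < 1:
        raise ValueError("min_spectra must be >= 1")
    per = table.spectra_per_protein()
    kept = {p for p, n in per.items() if n >= min_spectra}
    dropped = set(per) - kept
    sub = table.frame[table.frame["protein"].isin(kept)].reset_index(drop=True)
    return SpectrumTable(sub), FilterReport(kept, dropped, per, min_spectra)
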