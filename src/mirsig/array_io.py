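"""Reading and writing the plain-text formats the pipeline touches.

All files are delimited text with a header row. Readers accept tab- or
comma-delimited input (sniffed from the header line); writers always emit
tabs. Missing values are written as the explicit token ``NA``, never as an
empty cell.

Formats
-------
scan table
    one array per file; columns ``probe_id``, ``spot_class`` (``probe`` |
    ``blank``), ``intensity`` (non-negative fluorescence, arbitrary units).
expression matrix
    miRNA rows x sample columns; first column ``miRNA_ID``. Sample-to-group
    mapping travels in a sidecar sample sheet, mirroring how a GEO series
    matrix pairs with its sample annotation.
sample sheet
    columns ``sample_id``, ``group`` (``FM`` | ``control``), optional
    clinical-score columns ``FIQ,GF,PF,MF,RA,RM`` and an optional
    ``small_rna_fraction`` column.
qPCR table
    columns ``sample_id``, ``miRNA_ID``, ``ct``, ``ct_reference``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

GROUPS = ("FM", "control")
SPOT_CLASSES = ("probe", "blank")
CLINICAL_COLUMNS = ("FIQ", "GF", "PF", "MF", "RA", "RM")
NA_TOKEN = "NA"


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class SpotRecord:
    """One spot on one array: a probe (named miRNA) or a blank feature."""

    probe_id: str
    spot_class: str
    intensity: float

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValidationError("probe_id must be non-empty")
        if self.spot_class not in SPOT_CLASSES:
            raise ValidationError(
                f"spot_class must be one of {SPOT_CLASSES}, got {self.spot_class!r}"
            )
        if not np.isfinite(self.intensity) or self.intensity < 0:
            raise ValidationError(
                f"intensity must be a finite non-negative real, got {self.intensity!r}"
            )


@dataclass
class ArrayScan:
    """Raw spot-level readings for one sample.

    ``spots`` is a DataFrame with columns ``probe_id``, ``spot_class``,
    ``intensity`` (a frame, not per-spot objects, so a 1212-probe array stays
    cheap to build and slice).
    """

    sample_id: str
    spots: pd.DataFrame
    group: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"probe_id", "spot_class", "intensity"}
        missing = required - set(self.spots.columns)
        if missing:
            raise FormatError(f"scan is missing column(s): {sorted(missing)}")
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.group is not None and self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        cls = self.spots["spot_class"]
        bad_cls = ~cls.isin(SPOT_CLASSES)
        if bad_cls.any():
            row = int(np.flatnonzero(bad_cls.to_numpy())[0]) + 1
            raise ValidationError(f"unknown spot_class at data row {row}")
        inten = pd.to_numeric(self.spots["intensity"], errors="coerce")
        bad = ~np.isfinite(inten.to_numpy(dtype=float)) | (inten.to_numpy(dtype=float) < 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValidationError(
                f"intensity must be non-negative at data row {row} "
                f"(value {self.spots['intensity'].iloc[row - 1]!r})"
            )
        n_blank = int((cls == "blank").sum())
        n_probe = int((cls == "probe").sum())
        if n_blank == 0:
            raise ValidationError(f"scan {self.sample_id}: no blank spots")
        if n_probe == 0:
            raise ValidationError(f"scan {self.sample_id}: no probe spots")
        probe_ids = self.spots.loc[cls == "probe", "probe_id"]
        if probe_ids.duplicated().any():
            dup = probe_ids[probe_ids.duplicated()].iloc[0]
            raise ValidationError(f"scan {self.sample_id}: duplicated probe_id {dup!r}")

    # convenience views -----------------------------------------------------
    @property
    def blank_intensities(self) -> np.ndarray:
        mask = self.spots["spot_class"] == "blank"
        return self.spots.loc[mask, "intensity"].to_numpy(dtype=float)

    @property
    def probe_ids(self) -> np.ndarray:
        mask = self.spots["spot_class"] == "probe"
        return self.spots.loc[mask, "probe_id"].to_numpy()

    @property
    def probe_intensities(self) -> np.ndarray:
        mask = self.spots["spot_class"] == "probe"
        return self.spots.loc[mask, "intensity"].to_numpy(dtype=float)

    def records(self) -> list[SpotRecord]:
        return [
            SpotRecord(r.probe_id, r.spot_class, float(r.intensity))
            for r in self.spots.itertuples(index=False)
        ]


@dataclass
class SampleSheet:
    """Sample annotation: group labels plus optional clinical columns."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns or "group" not in self.table.columns:
            raise FormatError("sample sheet needs 'sample_id' and 'group' columns")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicated sample_id {dup!r} in sample sheet")
        bad = ~self.table["group"].isin(GROUPS)
        if bad.any():
            raise ValidationError(
                f"sample sheet group labels must be in {GROUPS}; "
                f"got {sorted(self.table.loc[bad, 'group'].unique())}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["group"]))

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def clinical(self) -> pd.DataFrame:
        """Clinical-score columns indexed by sample, NaN where absent."""
        cols = [c for c in CLINICAL_COLUMNS if c in self.table.columns]
        return self.table.set_index("sample_id")[cols].astype(float)

    def small_rna_fractions(self) -> pd.Series | None:
        if "small_rna_fraction" not in self.table.columns:
            return None
        return self.table.set_index("sample_id")["small_rna_fraction"].astype(float)


@dataclass
class ExpressionMatrix:
    """Normalized miRNA x sample matrix with group labels and presence flags."""

    values: pd.DataFrame
    groups: Mapping[str, str]
    present: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValidationError("expression matrix must be non-empty")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicated miRNA row name {dup!r}")
        unknown = [s for s in self.values.columns if s not in self.groups]
        if unknown:
            raise ValidationError(f"samples without group label: {unknown}")
        bad_groups = {g for g in self.groups.values() if g not in GROUPS}
        if bad_groups:
            raise ValidationError(f"unknown group label(s): {sorted(bad_groups)}")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("expression values must be non-negative")
        if self.present is not None and not self.present.index.equals(self.values.index):
            raise ValidationError("presence flags must share the matrix row index")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


# ---------------------------------------------------------------------------
# delimiter sniffing
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path | str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: Path | str, required: set[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{what}: file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str,
                     na_values=[NA_TOKEN], keep_default_na=False)
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{what} {path.name}: missing column(s) {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# scan tables
# ---------------------------------------------------------------------------

def read_scan_table(path: Path | str, sample_id: str | None = None,
                    group: str | None = None) -> ArrayScan:
    """Parse one raw scan table into an :class:`ArrayScan`.

    Never drops rows silently: every data row becomes a spot or raises a
    :class:`ValidationError` naming the 1-based offending row.
    """
    path = Path(path)
    df = _read_table(path, {"probe_id", "spot_class", "intensity"}, "scan table")
    inten = pd.to_numeric(df["intensity"], errors="coerce")
    nonnum = inten.isna() & df["intensity"].notna()
    if nonnum.any():
        row = int(np.flatnonzero(nonnum.to_numpy())[0]) + 1
        raise ValidationError(f"{path.name}: non-numeric intensity at data row {row}")
    spots = pd.DataFrame({
        "probe_id": df["probe_id"].astype(str),
        "spot_class": df["spot_class"].astype(str),
        "intensity": inten.astype(float),
    })
    return ArrayScan(sample_id or path.stem, spots, group=group)


def write_scan_table(scan: ArrayScan, path: Path | str) -> None:
    scan.spots.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression_matrix(matrix: ExpressionMatrix, path: Path | str,
                            sample_sheet_path: Path | str | None = None) -> None:
    """Write a series-matrix-style TSV; group labels go to a sidecar sheet."""
    out = matrix.values.copy()
    out.index.name = "miRNA_ID"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)
    if sample_sheet_path is not None:
        sheet = pd.DataFrame({
            "sample_id": list(matrix.values.columns),
            "group": [matrix.groups[s] for s in matrix.values.columns],
        })
        sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_expression_matrix(path: Path | str,
                           sample_sheet: SampleSheet | Path | str) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), na_values=[NA_TOKEN],
                     keep_default_na=False)
    if "miRNA_ID" not in df.columns:
        raise FormatError(f"{path.name}: first column must be 'miRNA_ID'")
    df = df.set_index("miRNA_ID")
    df.index.name = None
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicated miRNA row name {dup!r}")
    if not isinstance(sample_sheet, SampleSheet):
        sample_sheet = read_sample_sheet(sample_sheet)
    return ExpressionMatrix(df.astype(float), sample_sheet.groups)


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: Path | str) -> SampleSheet:
    df = _read_table(path, {"sample_id", "group"}, "sample sheet")
    for col in df.columns:
        if col in CLINICAL_COLUMNS or col == "small_rna_fraction":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: Path | str) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def read_qpcr_table(path: Path | str) -> pd.DataFrame:
    """Ct measurements, one row per (sample, miRNA), with the reference Ct."""
    df = _read_table(path, {"sample_id", "miRNA_ID", "ct", "ct_reference"},
                     "qPCR table")
    for col in ("ct", "ct_reference"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValidationError(f"non-numeric {col} at data row {row}")
        df[col] = vals
    return df


def write_qpcr_table(df: pd.DataFrame, path: Path | str) -> None:
    cols = ["sample_id", "miRNA_ID", "ct", "ct_reference"]
    df[cols].to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)
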