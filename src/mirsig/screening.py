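"""Group summaries, fold-ratio census and signature selection.

The screen works on arithmetic group means of the normalized matrix (absent
calls contribute 0 to their group mean). The headline quantity is the
control/case ratio of group means — a ratio >= 2 means the miRNA lost at
least half its signal in patients. A case-group mean of exactly 0 with a
positive control mean yields an infinite ratio, which still counts as
downregulation at every threshold; 0/0 is undefined and excluded from
ratio-based statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .array_io import ExpressionMatrix
from .errors import ValidationError


@dataclass
class GroupSummary:
    """Per-miRNA control mean, case mean and control/case ratio."""

    table: pd.DataFrame  # columns: control_mean, fm_mean, ratio_c_over_fm
    n_control: int
    n_fm: int

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def ratios(self) -> pd.Series:
        return self.table["ratio_c_over_fm"]


@dataclass
class CensusReport:
    """Counts of down-/up-regulated miRNAs at the screening thresholds."""

    n_total: int
    n_down_2x: int
    n_down_4x: int
    n_up_1p5x: int
    max_induction: float

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_down_2x": self.n_down_2x,
            "n_down_4x": self.n_down_4x,
            "n_up_1p5x": self.n_up_1p5x,
            "max_induction": self.max_induction,
            "frac_down_2x": self.n_down_2x / self.n_total if self.n_total else 0.0,
        }


@dataclass
class SignatureReport:
    """miRNAs downregulated at least ``min_fold``-fold, strongest first."""

    min_fold: float
    members: list[tuple[str, float]]

    @property
    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]

    def as_dict(self) -> dict:
        return {
            "min_fold": self.min_fold,
            "members": [
                {"miRNA_ID": m, "ratio_c_over_fm": r} for m, r in self.members
            ],
        }


def summarize_groups(matrix: ExpressionMatrix) -> GroupSummary:
    """Arithmetic group means per miRNA and their control/case ratio."""
    ctrl = matrix.samples_in_group("control")
    fm = matrix.samples_in_group("FM")
    if not ctrl or not fm:
        raise ValidationError("both groups must be non-empty")
    c_mean = matrix.values[ctrl].mean(axis=1)
    f_mean = matrix.values[fm].mean(axis=1)
    c = c_mean.to_numpy(dtype=float)
    f = f_mean.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f > 0, c / f, np.where(c > 0, np.inf, np.nan))
    table = pd.DataFrame(
        {"control_mean": c_mean, "fm_mean": f_mean, "ratio_c_over_fm": ratio},
        index=matrix.values.index,
    )
    return GroupSummary(table, n_control=len(ctrl), n_fm=len(fm))


def census(summary: GroupSummary,
           down_thresholds: tuple[float, float] = (2.0, 4.0),
           up_threshold: float = 1.5) -> CensusReport:
    """Count miRNAs at the down-/up-regulation thresholds of the screen."""
    if summary.table.empty:
        raise ValidationError("empty group summary")
    lo, hi = sorted(down_thresholds)
    ratio = summary.ratios.to_numpy(dtype=float)
    c = summary.table["control_mean"].to_numpy(dtype=float)
    f = summary.table["fm_mean"].to_numpy(dtype=float)
    n_down_lo = int(np.sum(ratio >= lo))  # NaN compares False; inf counts
    n_down_hi = int(np.sum(ratio >= hi))
    with np.errstate(divide="ignore", invalid="ignore"):
        induction = np.where(c > 0, f / c, np.nan)
    n_up = int(np.nansum(induction > up_threshold))
    finite = induction[np.isfinite(induction)]
    max_induction = float(finite.max()) if finite.size else 0.0
    return CensusReport(
        n_total=len(ratio),
        n_down_2x=n_down_lo,
        n_down_4x=n_down_hi,
        n_up_1p5x=n_up,
        max_induction=max_induction,
    )


def select_signature(summary: GroupSummary, min_fold: float = 6.0) -> SignatureReport:
    """miRNAs whose control/case ratio reaches ``min_fold``, sorted descending.

    Only finite ratios qualify: a biomarker must be quantifiable in both
    groups, so an infinite sentinel (case group entirely absent-called) is a
    detection failure rather than a fold measurement, and 0/0 is undefined.
    Ties break by miRNA id for determinism.
    """
    if summary.table.empty:
        raise ValidationError("empty group summary")
    ratio = summary.ratios
    hits = ratio[np.isfinite(ratio) & (ratio >= min_fold)]
    ordered = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    return SignatureReport(min_fold, [(m, float(r)) for m, r in ordered])


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def write_group_summary(summary: GroupSummary, path: Path | str,
                        decimals: int = 2) -> None:
    """Tabular report in the published layout; ratios printed at 2 dp."""
    out = summary.table.copy()
    out["ratio_c_over_fm"] = out["ratio_c_over_fm"].round(decimals)
    out.index.name = "miRNA_ID"
    out.to_csv(path, sep="\t", na_rep="NA")


def write_census(report: CensusReport, path: Path | str) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")


def write_signature(report: SignatureReport, path: Path | str) -> None:
    def _jsonable(v: float) -> float | str:
        return v if np.isfinite(v) else "inf"

    payload = {
        "min_fold": report.min_fold,
        "members": [
            {"miRNA_ID": m, "ratio_c_over_fm": _jsonable(r)}
            for m, r in report.members
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
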