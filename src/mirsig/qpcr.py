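"""RT-qPCR validation: reference-gene relative quantification and group tests.

Expression relative to the U6 reference is ``2^-dCt`` with
``dCt = ct_target - ct_reference`` per sample (no calibrator sample, so this
is single-delta quantification; amplification efficiency is assumed to be
2.0 per cycle unless overridden). Group differences are tested with the
two-sided Mann-Whitney U test: exact enumeration when the pooled sample is
small (<= 12) with no ties, otherwise a normal approximation with tie and
continuity corrections. Significance is called at p < 0.05 without
multiplicity correction; Benjamini-Hochberg adjustment is available opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger(__name__)

MAX_CYCLES = 45.0


@dataclass
class QpcrRecord:
    """One Ct measurement with its same-sample reference-gene Ct."""

    sample_id: str
    mirna_id: str
    ct: float
    ct_reference: float
    max_cycles: float = MAX_CYCLES

    def __post_init__(self) -> None:
        for name, value in (("ct", self.ct), ("ct_reference", self.ct_reference)):
            if not (0 < value <= self.max_cycles):
                raise ValidationError(
                    f"{name}={value} outside (0, {self.max_cycles}] for "
                    f"{self.sample_id}/{self.mirna_id}"
                )


@dataclass
class ValidationResult:
    """Outcome of the group comparison for one miRNA."""

    mirna_id: str
    n_fm: int
    n_control: int
    u_statistic: float
    p_value: float
    significant: bool
    direction: str  # down_in_FM | up_in_FM | none


def relative_expression(ct: float, ct_reference: float,
                        efficiency: float = 2.0,
                        max_cycles: float = MAX_CYCLES) -> float:
    """Fold expression vs the reference gene: ``efficiency^-(ct - ct_ref)``."""
    for name, value in (("ct", ct), ("ct_reference", ct_reference)):
        if not (0 < value <= max_cycles):
            raise ValidationError(f"{name}={value} outside (0, {max_cycles}]")
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    return float(efficiency ** -(ct - ct_reference))


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   alternative: str = "two-sided",
                   exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Returns ``(U, p)`` where U is the smaller of the two U statistics (the
    convention most statistics packages print). The p-value is exact when
    ``len(a) + len(b) <= exact_max_n`` and there are no ties, otherwise a
    tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return u, float(res.pvalue)


def _records_frame(qpcr: pd.DataFrame | Iterable[QpcrRecord]) -> pd.DataFrame:
    if isinstance(qpcr, pd.DataFrame):
        df = qpcr.copy()
        df = df.rename(columns={"miRNA_ID": "mirna_id"})
    else:
        df = pd.DataFrame(
            [(r.sample_id, r.mirna_id, r.ct, r.ct_reference) for r in qpcr],
            columns=["sample_id", "mirna_id", "ct", "ct_reference"],
        )
    required = {"sample_id", "mirna_id", "ct", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"qPCR table missing column(s) {sorted(missing)}")
    return df


def relative_expression_table(qpcr: pd.DataFrame | Iterable[QpcrRecord],
                              efficiency: float = 2.0) -> pd.DataFrame:
    """Per-(sample, miRNA) relative expression, technical replicates averaged.

    Replicate Ct values for the same (sample, miRNA) are averaged on the Ct
    scale before the delta is taken.
    """
    df = _records_frame(qpcr)
    for _, row in df.iterrows():
        QpcrRecord(str(row["sample_id"]), str(row["mirna_id"]),
                   float(row["ct"]), float(row["ct_reference"]))
    agg = df.groupby(["sample_id", "mirna_id"], as_index=False)[
        ["ct", "ct_reference"]].mean()
    agg["rel_expr"] = efficiency ** -(agg["ct"] - agg["ct_reference"])
    return agg


def validate_mirnas(qpcr: pd.DataFrame | Iterable[QpcrRecord],
                    groups: Mapping[str, str],
                    alpha: float = 0.05,
                    efficiency: float = 2.0,
                    adjust: str | None = None) -> list[ValidationResult]:
    """Mann-Whitney group comparison of relative expression per miRNA.

    miRNAs with fewer than 2 samples in either group are skipped with a
    warning. ``adjust='bh'`` applies Benjamini-Hochberg across the tested
    miRNAs before calling significance.
    """
    rel = relative_expression_table(qpcr, efficiency=efficiency)
    rel["group"] = rel["sample_id"].map(dict(groups))
    unknown = rel.loc[rel["group"].isna(), "sample_id"].unique()
    if unknown.size:
        raise ValidationError(f"qPCR samples without group label: {list(unknown)}")

    tested: list[tuple[str, int, int, float, float, str]] = []
    for mirna, sub in rel.groupby("mirna_id", sort=True):
        fm = sub.loc[sub["group"] == "FM", "rel_expr"].to_numpy()
        ctrl = sub.loc[sub["group"] == "control", "rel_expr"].to_numpy()
        if fm.size < 2 or ctrl.size < 2:
            logger.warning(
                "skipping %s: need >= 2 samples per group (FM=%d, control=%d)",
                mirna, fm.size, ctrl.size)
            continue
        u, p = mann_whitney_u(fm, ctrl)
        med_diff = float(np.median(fm) - np.median(ctrl))
        direction = ("down_in_FM" if med_diff < 0
                     else "up_in_FM" if med_diff > 0 else "none")
        tested.append((str(mirna), fm.size, ctrl.size, u, p, direction))

    p_values = np.array([t[4] for t in tested], dtype=float)
    if adjust == "bh" and p_values.size:
        p_eff = sps.false_discovery_control(p_values, method="bh")
    elif adjust in (None, "none"):
        p_eff = p_values
    else:
        raise ValidationError(f"unknown p-value adjustment {adjust!r}")

    results = []
    for (mirna, n_fm, n_ctrl, u, p, direction), pe in zip(tested, p_eff):
        results.append(ValidationResult(
            mirna_id=mirna, n_fm=n_fm, n_control=n_ctrl,
            u_statistic=u, p_value=p, significant=bool(pe < alpha),
            direction=direction,
        ))
    return results


def validation_frame(results: Iterable[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "miRNA_ID": r.mirna_id,
            "n_fm": r.n_fm,
            "n_control": r.n_control,
            "U": r.u_statistic,
            "p_value": r.p_value,
            "significant": r.significant,
            "direction": r.direction,
        }
        for r in results
    ])


def write_validation(results: Iterable[ValidationResult], path: Path | str) -> None:
    validation_frame(results).to_csv(path, sep="\t", index=False)
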