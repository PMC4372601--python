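"""Clinical-score statistics: rank correlation, group descriptives, outliers.

Severity instruments: the Fibromyalgia Impact Questionnaire total (FIQ,
0-100) and the five Multidimensional Fatigue Inventory subscales (0-20):
general fatigue (GF), physical fatigue (PF), mental fatigue (MF), reduced
activity (RA), reduced motivation (RM). Correlations between miRNA levels
and scores are computed within the patient group only, with Spearman's rho
(midranks for ties), pairwise-complete over missing measurements.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .array_io import CLINICAL_COLUMNS, ExpressionMatrix, SampleSheet
from .errors import UndefinedCorrelationError, ValidationError
from .qpcr import mann_whitney_u

logger = logging.getLogger(__name__)

SCORE_RANGES: dict[str, tuple[float, float]] = {
    "FIQ": (0.0, 100.0),
    "GF": (0.0, 20.0),
    "PF": (0.0, 20.0),
    "MF": (0.0, 20.0),
    "RA": (0.0, 20.0),
    "RM": (0.0, 20.0),
}


@dataclass
class ClinicalScores:
    """One participant's severity scores; NaN marks a missing measurement."""

    sample_id: str
    fiq_total: float
    mfi_gf: float
    mfi_pf: float
    mfi_mf: float
    mfi_ra: float
    mfi_rm: float

    def __post_init__(self) -> None:
        values = {
            "FIQ": self.fiq_total, "GF": self.mfi_gf, "PF": self.mfi_pf,
            "MF": self.mfi_mf, "RA": self.mfi_ra, "RM": self.mfi_rm,
        }
        for name, value in values.items():
            lo, hi = SCORE_RANGES[name]
            if not np.isnan(value) and not (lo <= value <= hi):
                raise ValidationError(
                    f"{name}={value} outside [{lo}, {hi}] for {self.sample_id}"
                )


@dataclass
class CorrelationResult:
    mirna_id: str
    score_name: str
    n: int
    rho: float
    p_value: float
    computable: bool


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float],
                 exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    For n <= ``exact_max_n`` the p-value is exact: the proportion of the n!
    permutations of one variable whose |rho| reaches the observed |rho|.
    Larger n uses the usual t approximation. A constant input vector has no
    defined rank correlation and raises.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValidationError("need two equal-length vectors with n >= 3")
    if np.unique(xv).size == 1 or np.unique(yv).size == 1:
        raise UndefinedCorrelationError("constant vector: rho undefined")
    res = sps.spearmanr(xv, yv)
    rho = float(res.statistic)
    n = xv.size
    if n <= exact_max_n:
        rx = _midranks(xv)
        ry = _midranks(yv)
        rxc = rx - rx.mean()
        denom_x = np.sqrt((rxc ** 2).sum())
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        r_all = ry[perms]  # (n!, n)
        rc = r_all - r_all.mean(axis=1, keepdims=True)
        denom_y = np.sqrt((rc ** 2).sum(axis=1))
        rho_all = (rc @ rxc) / (denom_x * denom_y)
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    else:
        p = float(res.pvalue)
    return rho, p


def correlate_clinical(expr: pd.DataFrame | ExpressionMatrix,
                       sheet: SampleSheet,
                       mirna_ids: Iterable[str] | None = None,
                       min_pairs: int = 3,
                       group: str = "FM") -> list[CorrelationResult]:
    """Rank-correlate each miRNA with each score inside the patient group.

    ``expr`` is a miRNA x sample table (or ExpressionMatrix). Missing values
    (NaN in expression or score) are dropped pairwise, so each cell reports
    its own n. Cells with fewer than ``min_pairs`` complete pairs, or with a
    constant vector, are flagged not computable.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    clinical = sheet.clinical()
    group_samples = [s for s in sheet.samples_in_group(group) if s in values.columns]
    if not group_samples:
        raise ValidationError(f"no {group} samples shared by matrix and sheet")
    ids = list(mirna_ids) if mirna_ids is not None else list(values.index)
    score_cols = [c for c in CLINICAL_COLUMNS if c in clinical.columns]

    results: list[CorrelationResult] = []
    for mirna in ids:
        if mirna not in values.index:
            raise ValidationError(f"miRNA {mirna!r} not in expression table")
        levels = values.loc[mirna, group_samples].astype(float)
        for score in score_cols:
            sc = clinical.reindex(group_samples)[score]
            mask = levels.notna() & sc.notna()
            n = int(mask.sum())
            if n < min_pairs:
                results.append(CorrelationResult(mirna, score, n,
                                                 np.nan, np.nan, False))
                continue
            try:
                rho, p = spearman_rho(levels[mask].to_numpy(),
                                      sc[mask].to_numpy())
            except UndefinedCorrelationError:
                results.append(CorrelationResult(mirna, score, n,
                                                 np.nan, np.nan, False))
                continue
            results.append(CorrelationResult(mirna, score, n, rho, p, True))
    return results


def correlation_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"miRNA_ID": r.mirna_id, "score": r.score_name, "n": r.n,
         "rho": r.rho, "p_value": r.p_value, "computable": r.computable}
        for r in results
    ])


def write_correlations(results: Iterable[CorrelationResult],
                       path: Path | str) -> None:
    """Wide report: one block of rows (n / rho / p) per score, miRNA columns."""
    df = correlation_frame(results)
    blocks = []
    for score, sub in df.groupby("score", sort=False):
        sub = sub.set_index("miRNA_ID")
        for stat in ("n", "rho", "p_value"):
            row = sub[stat].rename(f"{score}:{stat}")
            blocks.append(row)
    wide = pd.DataFrame(blocks)
    wide.index.name = "score:statistic"
    wide.to_csv(path, sep="\t", na_rep="NA")


def compare_small_rna_fractions(fractions: Mapping[str, float] | pd.Series,
                                groups: Mapping[str, str]) -> dict:
    """Group means +/- SD of the small-RNA mass fraction, with a rank test.

    Checks whether an overall RNA-composition difference could explain a
    global shift in miRNA signal between the groups.
    """
    frac = pd.Series(dict(fractions), dtype=float) if not isinstance(fractions, pd.Series) else fractions.astype(float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValidationError("small-RNA fractions must lie in [0, 1]")
    grp = frac.index.map(dict(groups))
    fm = frac[grp == "FM"].to_numpy()
    ctrl = frac[grp == "control"].to_numpy()
    if fm.size == 0 or ctrl.size == 0:
        raise ValidationError("both groups must be non-empty")
    u, p = mann_whitney_u(fm, ctrl)
    return {
        "control_mean": float(ctrl.mean()),
        "control_sd": float(ctrl.std(ddof=1)) if ctrl.size > 1 else 0.0,
        "fm_mean": float(fm.mean()),
        "fm_sd": float(fm.std(ddof=1)) if fm.size > 1 else 0.0,
        "n_control": int(ctrl.size),
        "n_fm": int(fm.size),
        "u_statistic": u,
        "p_value": p,
    }


def flag_outlier_patient(expr: pd.DataFrame | ExpressionMatrix,
                         sheet: SampleSheet,
                         signature_ids: Sequence[str],
                         score: str = "MF") -> dict:
    """Report the patient with the lowest mental-fatigue score.

    For each signature miRNA the report states the flagged patient's level,
    whether it is the highest within the patient group, whether it exceeds
    the lowest control level, and the fold distance to that reference. Ties
    on the minimum score break by sample id (logged).
    """
    if not signature_ids:
        raise ValidationError("signature must be non-empty")
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    clinical = sheet.clinical()
    fm = [s for s in sheet.samples_in_group("FM") if s in values.columns]
    ctrl = [s for s in sheet.samples_in_group("control") if s in values.columns]
    if not fm or not ctrl:
        raise ValidationError("both groups must be represented in the matrix")
    scores = clinical.reindex(fm)[score]
    min_score = scores.min()
    tied = sorted(scores.index[scores == min_score])
    if len(tied) > 1:
        logger.info("score tie at %s=%s among %s; flagging %s",
                    score, min_score, tied, tied[0])
    flagged = tied[0]

    per_mirna = {}
    n_highest = 0
    n_exceed = 0
    for mirna in signature_ids:
        level = float(values.loc[mirna, flagged])
        fm_levels = values.loc[mirna, fm].astype(float)
        control_min = float(values.loc[mirna, ctrl].astype(float).min())
        highest = bool(level >= fm_levels.max())
        exceeds = bool(level > control_min)
        fold_to_ref = float(control_min / level) if level > 0 else float("inf")
        n_highest += highest
        n_exceed += exceeds
        per_mirna[mirna] = {
            "level": level,
            "highest_in_fm": highest,
            "exceeds_control_min": exceeds,
            "control_min": control_min,
            "fold_to_control_min": fold_to_ref,
        }
    return {
        "flagged_sample": flagged,
        "score": score,
        "score_value": float(min_score),
        "n_highest_in_fm": int(n_highest),
        "n_exceed_control_min": int(n_exceed),
        "per_mirna": per_mirna,
    }
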