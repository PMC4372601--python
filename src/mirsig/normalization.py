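"""Per-array signal processing for blank-calibrated miRNA microarrays.

The procedure, applied independently to every array:

1. rank the blank-spot intensities, discard the top and bottom 5%
   (``floor(trim_fraction * n)`` spots per tail) and compute the mean and
   sample SD of the remainder;
2. call a probe *present* iff its raw signal strictly exceeds
   ``mean + 2 * SD`` of the trimmed blanks;
3. subtract the trimmed blank mean from every present probe;
4. rescale all corrected signals so their median equals 25.

Absent probes are recorded as 0 (or missing, per ``absent_policy``) and are
never included in the normalization median. The whole procedure is invariant
under a global rescaling of the array, which is what makes arrays scanned at
different gains comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .array_io import ArrayScan, ExpressionMatrix
from .errors import (
    AbsentSpotError,
    DegenerateProfileError,
    EmptyProfileError,
    InsufficientBlanksError,
    ValidationError,
)

ABSENT_POLICIES = ("set_zero", "set_missing")


@dataclass
class NormalizationConfig:
    """Constants of the per-array procedure; defaults are the study's values."""

    trim_fraction: float = 0.05
    sd_multiplier: float = 2.0
    target_median: float = 25.0
    absent_policy: str = "set_zero"

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValidationError("trim_fraction must be in [0, 0.5)")
        if self.target_median <= 0:
            raise ValidationError("target_median must be positive")
        if self.absent_policy not in ABSENT_POLICIES:
            raise ValidationError(f"absent_policy must be one of {ABSENT_POLICIES}")


@dataclass
class BlankStats:
    """Trimmed blank-spot statistics and the derived detection threshold."""

    trimmed_mean: float
    trimmed_sd: float
    detection_threshold: float
    n_blanks_used: int


@dataclass
class NormalizedProfile:
    """One sample's normalized intensities and presence calls."""

    sample_id: str
    values: pd.Series
    present: pd.Series
    scale_factor: float
    target_median: float = 25.0

    @property
    def present_values(self) -> pd.Series:
        return self.values[self.present]


def trimmed_blank_stats(blank_intensities: Iterable[float],
                        trim_fraction: float = 0.05,
                        sd_multiplier: float = 2.0) -> BlankStats:
    """Mean/SD of the blanks after dropping ``floor(trim_fraction*n)`` per tail.

    SD is the sample standard deviation (n-1 denominator); with fewer than 20
    blanks a 5% trim removes nothing. Requires at least 3 retained blanks.
    """
    x = np.sort(np.asarray(list(blank_intensities), dtype=float))
    if x.size and (x < 0).any():
        raise ValidationError("blank intensities must be non-negative")
    k = math.floor(trim_fraction * x.size)
    kept = x[k:x.size - k] if k > 0 else x
    if kept.size < 3:
        raise InsufficientBlanksError(
            f"only {kept.size} blank(s) retained after trimming; need >= 3"
        )
    mean = float(kept.mean())
    sd = float(kept.std(ddof=1))
    return BlankStats(mean, sd, mean + sd_multiplier * sd, int(kept.size))


def call_presence(intensity: float, stats: BlankStats) -> bool:
    """Present iff the signal is strictly above the detection threshold."""
    return intensity > stats.detection_threshold


def subtract_background(intensity: float, stats: BlankStats) -> float:
    """Trimmed-blank-mean subtraction; only valid for present spots."""
    if not call_presence(intensity, stats):
        raise AbsentSpotError(
            f"background subtraction on an absent spot (intensity {intensity}, "
            f"threshold {stats.detection_threshold})"
        )
    return intensity - stats.trimmed_mean


def global_normalize(corrected: Mapping[str, float] | pd.Series,
                     target_median: float = 25.0,
                     sample_id: str = "") -> NormalizedProfile:
    """Rescale background-corrected present signals to a fixed median."""
    series = pd.Series(dict(corrected), dtype=float) if not isinstance(corrected, pd.Series) else corrected.astype(float)
    if series.size == 0:
        raise EmptyProfileError("no present miRNAs to normalize")
    if (series <= 0).any():
        raise ValidationError("corrected intensities of present miRNAs must be > 0")
    med = float(np.median(series.to_numpy()))
    if med <= 0:
        raise DegenerateProfileError("median of corrected signals is not positive")
    scale = target_median / med
    values = series * scale
    present = pd.Series(True, index=series.index)
    return NormalizedProfile(sample_id, values, present, scale, target_median)


def normalize_scan(scan: ArrayScan,
                   config: NormalizationConfig | None = None) -> NormalizedProfile:
    """Full per-array pipeline: blank stats, presence, background, median-25."""
    cfg = config or NormalizationConfig()
    stats = trimmed_blank_stats(scan.blank_intensities,
                                cfg.trim_fraction, cfg.sd_multiplier)
    ids = scan.probe_ids
    inten = scan.probe_intensities
    present = inten > stats.detection_threshold
    if not present.any():
        raise EmptyProfileError(f"scan {scan.sample_id}: no probe called present")
    corrected = inten[present] - stats.trimmed_mean
    med = float(np.median(corrected))
    if med <= 0:
        raise DegenerateProfileError(
            f"scan {scan.sample_id}: median corrected signal not positive"
        )
    scale = cfg.target_median / med
    absent_value = 0.0 if cfg.absent_policy == "set_zero" else np.nan
    values = np.full(ids.shape, absent_value, dtype=float)
    values[present] = corrected * scale
    return NormalizedProfile(
        scan.sample_id,
        pd.Series(values, index=ids),
        pd.Series(present, index=ids),
        scale,
        cfg.target_median,
    )


def build_expression_matrix(profiles: Iterable[NormalizedProfile],
                            groups: Mapping[str, str]) -> ExpressionMatrix:
    """Assemble per-sample profiles (identical probe sets) into one matrix."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles to assemble")
    index = profiles[0].values.index
    for p in profiles[1:]:
        if not p.values.index.equals(index):
            raise ValidationError(
                f"profile {p.sample_id} has a different probe set"
            )
    values = pd.DataFrame({p.sample_id: p.values for p in profiles}, index=index)
    present = pd.DataFrame({p.sample_id: p.present for p in profiles}, index=index)
    return ExpressionMatrix(values, dict(groups), present)


def heatmap_filter(matrix: ExpressionMatrix,
                   min_group_mean: float = 5.0) -> ExpressionMatrix:
    """Keep miRNAs whose control-group OR case-group mean exceeds the cutoff.

    The comparison is strict (> min_group_mean), matching the display filter
    used before heatmap drawing. Idempotent.
    """
    fm = matrix.samples_in_group("FM")
    ctrl = matrix.samples_in_group("control")
    if not fm or not ctrl:
        raise ValidationError("both groups must have at least one sample")
    fm_mean = matrix.values[fm].mean(axis=1)
    c_mean = matrix.values[ctrl].mean(axis=1)
    keep = (fm_mean > min_group_mean) | (c_mean > min_group_mean)
    if not keep.any():
        raise EmptyProfileError("no miRNA passes the heatmap filter")
    present = matrix.present.loc[keep] if matrix.present is not None else None
    return ExpressionMatrix(matrix.values.loc[keep], dict(matrix.groups), present)
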