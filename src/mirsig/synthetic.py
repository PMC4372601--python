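"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-arm PBMC miRNA study: 11 patients vs 10
controls profiled on 1212-probe arrays carrying a blank-spot population,
followed by qPCR assays on a handful of targets and questionnaire-based
severity scores for every participant.

Generative model (all randomness from one seed):

* blank spots: log-normal fluorescence, shared by every array up to a
  per-sample scale factor;
* expressed probes: per-probe log-normal baseline with a detectability
  floor (species that the platform cannot detect belong to the explicit
  absent class instead), multiplied in patients by 1/fold for the implanted
  signature (five miRNAs, 6.31-13.47x), the mild qPCR-control miRNAs and a
  broad ~20% slab of 2-4.5x downregulated probes; per-measurement
  multiplicative log-normal noise on top. The default noise models array
  technical variability (5% CV), calibrated so the recovered ratio of the
  weakest signature member (6.31x against the 6x selection threshold, a 5%
  margin) identifies the implanted set reliably; inter-subject biological
  spread is deliberately not modeled (see the methods note). The broad slab
  is implanted in below-median probes only: median-25 normalization is
  compositional, and keeping the downregulated mass on one side of the
  array median leaves the present-probe median — and therefore every
  recovered ratio — unbiased. Spot intensity is the signal plus an
  additive nonspecific background drawn from the blank distribution, so
  blank-mean subtraction recovers the signal without bias (exactly, in the
  zero-noise limit);
* absent probes: zero signal with the nonspecific background attenuated by
  a fixed factor, keeping them just below the detection threshold while
  the presence boundary stays stochastic;
* Ct values: reference Ct per sample plus a fixed offset minus log2 of the
  sample's true expression relative to its probe baseline, plus cycle noise
  — so relative quantification recovers the implanted folds;
* clinical scores: normal draws at the cohort means/SDs, truncated to the
  instrument ranges by resampling; patients additionally carry a small-RNA
  mass fraction drawn at each group's reported mean/SD.

The returned cohort carries a ``truth`` record (implanted folds, baselines,
absent set) for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .array_io import (
    ArrayScan,
    SampleSheet,
    write_qpcr_table,
    write_sample_sheet,
    write_scan_table,
)
from .clinical_stats import SCORE_RANGES
from .errors import ValidationError

# Signature miRNAs with their downregulation folds, and the anchor levels of
# the control group on the normalized (median-25) scale.
SIGNATURE_FOLDS: dict[str, float] = {
    "hsa-miR-223-3p": 6.31,
    "hsa-miR-451a": 13.47,
    "hsa-miR-338-3p": 11.62,
    "hsa-miR-143-3p": 11.15,
    "hsa-miR-145-5p": 10.39,
}

# Mildly affected miRNAs carried along as qPCR comparison assays.
CONTROL_FOLDS: dict[str, float] = {
    "hsa-miR-21-5p": 3.88,
    "hsa-miR-1908-5p": 1.15,
    "hsa-miR-1260b": 1.36,
}

CONTROL_GROUP_LEVELS: dict[str, float] = {
    "hsa-miR-223-3p": 66736.98,
    "hsa-miR-451a": 4830.07,
    "hsa-miR-338-3p": 374.20,
    "hsa-miR-143-3p": 506.26,
    "hsa-miR-145-5p": 546.05,
    "hsa-miR-21-5p": 5470.04,
    "hsa-miR-1908-5p": 762.60,
    "hsa-miR-1260b": 23676.19,
}

# Patient-group clinical instrument means/SDs; controls are unaffected
# blood donors, set at low severity.
FM_CLINICAL: dict[str, tuple[float, float]] = {
    "FIQ": (74.11, 13.32),
    "GF": (18.64, 1.63),
    "PF": (17.64, 1.50),
    "MF": (14.27, 2.90),
    "RA": (15.0, 3.0),
    "RM": (13.0, 3.5),
}
CONTROL_CLINICAL: dict[str, tuple[float, float]] = {
    "FIQ": (12.0, 8.0),
    "GF": (8.0, 2.5),
    "PF": (7.5, 2.5),
    "MF": (7.0, 2.5),
    "RA": (7.0, 2.5),
    "RM": (6.5, 2.5),
}

SMALL_RNA: dict[str, tuple[float, float]] = {
    "control": (0.140, 0.034),
    "FM": (0.161, 0.102),
}


@dataclass
class SimulationConfig:
    """Cohort-level parameters; defaults reproduce the study conditions."""

    n_fm: int = 11
    n_control: int = 10
    n_mirna: int = 1212
    n_blank: int = 100
    blank_log_mean: float = math.log(10.0)
    blank_log_sd: float = 0.15
    probe_log_mean: float = math.log(1000.0)
    probe_log_sd: float = 1.2
    probe_floor: float = 300.0     # detectability floor for expressed probes
    absent_fraction: float = 0.30
    absent_attenuation: float = 0.7
    broad_down_fraction: float = 0.20
    broad_fold_range: tuple[float, float] = (2.0, 4.5)
    signature: dict[str, float] = field(default_factory=lambda: dict(SIGNATURE_FOLDS))
    control_folds: dict[str, float] = field(default_factory=lambda: dict(CONTROL_FOLDS))
    noise_cv: float = 0.05         # log-scale SD of per-measurement noise
    sample_scale_sd: float = 0.25  # log-scale SD of per-array gain
    fm_clinical: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(FM_CLINICAL))
    control_clinical: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(CONTROL_CLINICAL))
    small_rna: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(SMALL_RNA))
    qpcr_targets: tuple[str, ...] | None = None
    qpcr_ct_ref_mean: float = 20.0
    qpcr_ct_ref_sd: float = 0.5
    qpcr_delta_ct_base: float = 5.0
    qpcr_ct_sd: float = 0.8
    max_cycles: float = 45.0
    target_median: float = 25.0
    seed: int = 0

    @property
    def implanted_folds(self) -> dict[str, float]:
        return {**self.signature, **self.control_folds}

    def validate(self) -> None:
        if self.n_fm < 1 or self.n_control < 1:
            raise ValidationError("both groups need at least one sample")
        if self.n_mirna < len(self.implanted_folds):
            raise ValidationError("n_mirna smaller than the implanted fold map")
        if not 0 <= self.absent_fraction < 1:
            raise ValidationError("absent_fraction must be in [0, 1)")
        if self.broad_down_fraction < 0:
            raise ValidationError("broad_down_fraction must be >= 0")
        for name, (_, sd) in {**self.fm_clinical, **self.control_clinical}.items():
            if sd < 0:
                raise ValidationError(f"negative SD for clinical score {name}")
        overlap = set(self.signature) & set(self.control_folds)
        if overlap:
            raise ValidationError(f"miRNA in both fold maps: {sorted(overlap)}")


@dataclass
class SyntheticCohort:
    """A full simulated study plus the ground truth that generated it."""

    scans: list[ArrayScan]
    sample_sheet: SampleSheet
    qpcr: pd.DataFrame
    truth: dict
    config: SimulationConfig


def _mirna_ids(config: SimulationConfig) -> list[str]:
    implanted = list(config.implanted_folds)
    n_extra = config.n_mirna - len(implanted)
    extra = [f"hsa-miR-sim-{i:04d}" for i in range(1, n_extra + 1)]
    return implanted + extra


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Normal draws truncated to [lo, hi] by resampling."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort; deterministic for a fixed config (incl. seed)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    ids = _mirna_ids(cfg)
    n = cfg.n_mirna
    implanted = cfg.implanted_folds
    n_implanted = len(implanted)

    # qPCR targets must be expressed probes
    targets = list(cfg.qpcr_targets) if cfg.qpcr_targets is not None else (
        list(implanted) if implanted else ids[: min(5, n)]
    )
    unknown = [t for t in targets if t not in ids]
    if unknown:
        raise ValidationError(f"qPCR target(s) not on the array: {unknown}")

    # baselines: implanted probes anchored so the control group sits near its
    # published normalized level; the rest log-normal above the
    # detectability floor (sub-threshold species go to the absent class)
    baselines = np.empty(n)
    anchor = math.exp(cfg.probe_log_mean) / cfg.target_median
    free = []
    for i, m in enumerate(ids):
        if m in implanted:
            level = CONTROL_GROUP_LEVELS.get(m)
            if level is None:
                level = cfg.target_median * 40.0  # unanchored custom implant
            baselines[i] = level * anchor
        else:
            free.append(i)
    if free:
        draws = rng.lognormal(cfg.probe_log_mean, cfg.probe_log_sd, len(free))
        low = draws < cfg.probe_floor
        while low.any():
            draws[low] = rng.lognormal(cfg.probe_log_mean, cfg.probe_log_sd,
                                       int(low.sum()))
            low = draws < cfg.probe_floor
        baselines[np.array(free)] = draws

    # absent and broadly-downregulated sets (never implanted or qPCR targets)
    protected = set(implanted) | set(targets)
    eligible = np.array([i for i, m in enumerate(ids) if m not in protected])
    n_absent = min(math.floor(cfg.absent_fraction * n), eligible.size)
    absent_idx = rng.choice(eligible, size=n_absent, replace=False) if n_absent else np.array([], dtype=int)
    absent_mask = np.zeros(n, dtype=bool)
    absent_mask[absent_idx] = True

    # broad downregulation lives below the array median so the median-25
    # rescaling stays comparable between the groups (order statistics)
    remaining = np.array([i for i in eligible if not absent_mask[i]])
    n_broad = min(math.floor(cfg.broad_down_fraction * n), remaining.size)
    if n_broad:
        expressed = np.array([i for i in range(n) if not absent_mask[i]])
        cap = np.percentile(baselines[expressed], 45.0)
        low_pool = remaining[baselines[remaining] < cap]
        if low_pool.size < n_broad:
            low_pool = remaining[np.argsort(baselines[remaining])[:max(n_broad, 1)]]
        broad_idx = rng.choice(low_pool, size=n_broad, replace=False)
    else:
        broad_idx = np.array([], dtype=int)
    lo, hi = cfg.broad_fold_range
    broad_folds = np.exp(rng.uniform(math.log(lo), math.log(hi), n_broad))

    folds = np.ones(n)
    for i, m in enumerate(ids):
        if m in implanted:
            folds[i] = implanted[m]
    folds[broad_idx] = broad_folds

    # samples
    fm_samples = [f"FM{i}" for i in range(1, cfg.n_fm + 1)]
    ctrl_samples = [f"C{i}" for i in range(1, cfg.n_control + 1)]
    samples = fm_samples + ctrl_samples
    groups = {s: ("FM" if s in fm_samples else "control") for s in samples}
    is_fm = np.array([groups[s] == "FM" for s in samples])
    n_samples = len(samples)

    # true per-sample expression of expressed probes (biology shared between
    # the array and the qPCR assay)
    group_factor = np.where(is_fm[:, None], 1.0 / folds[None, :], 1.0)
    bio_noise = rng.lognormal(0.0, cfg.noise_cv, (n_samples, n))
    expr_true = baselines[None, :] * group_factor * bio_noise

    sample_scale = rng.lognormal(0.0, cfg.sample_scale_sd, n_samples)

    scans: list[ArrayScan] = []
    blank_ids = [f"BLANK_{j:04d}" for j in range(1, cfg.n_blank + 1)]
    for s_i, s in enumerate(samples):
        background = rng.lognormal(cfg.blank_log_mean, cfg.blank_log_sd, n)
        signal = expr_true[s_i].copy()
        if absent_mask.any():
            signal[absent_mask] = 0.0
            background[absent_mask] *= cfg.absent_attenuation
        intensity = (signal + background) * sample_scale[s_i]
        blanks = rng.lognormal(cfg.blank_log_mean, cfg.blank_log_sd,
                               cfg.n_blank) * sample_scale[s_i]
        spots = pd.DataFrame({
            "probe_id": ids + blank_ids,
            "spot_class": ["probe"] * n + ["blank"] * cfg.n_blank,
            "intensity": np.concatenate([intensity, blanks]),
        })
        scans.append(ArrayScan(s, spots, group=groups[s]))

    # clinical scores and small-RNA fractions
    sheet_rows: dict[str, list] = {"sample_id": samples,
                                   "group": [groups[s] for s in samples]}
    for score in ("FIQ", "GF", "PF", "MF", "RA", "RM"):
        lo_s, hi_s = SCORE_RANGES[score]
        fm_mean, fm_sd = cfg.fm_clinical[score]
        c_mean, c_sd = cfg.control_clinical[score]
        fm_vals = _truncated_normal(rng, fm_mean, fm_sd, lo_s, hi_s, cfg.n_fm)
        c_vals = _truncated_normal(rng, c_mean, c_sd, lo_s, hi_s, cfg.n_control)
        if score == "FIQ":
            vals = np.round(np.concatenate([fm_vals, c_vals]), 2)
        else:  # MFI subscales are integer-valued instruments
            vals = np.clip(np.round(np.concatenate([fm_vals, c_vals])), lo_s, hi_s)
        sheet_rows[score] = list(vals)
    fm_frac = _truncated_normal(rng, *cfg.small_rna["FM"], 0.0, 1.0, cfg.n_fm)
    c_frac = _truncated_normal(rng, *cfg.small_rna["control"], 0.0, 1.0,
                               cfg.n_control)
    sheet_rows["small_rna_fraction"] = list(np.concatenate([fm_frac, c_frac]))
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    # qPCR: ct = ct_ref + base_offset - log2(expr / baseline) + cycle noise
    qpcr_rows = []
    ct_ref = rng.normal(cfg.qpcr_ct_ref_mean, cfg.qpcr_ct_ref_sd, n_samples)
    id_index = {m: i for i, m in enumerate(ids)}
    for t in targets:
        ti = id_index[t]
        delta = cfg.qpcr_delta_ct_base - np.log2(expr_true[:, ti] / baselines[ti])
        ct = ct_ref + delta + rng.normal(0.0, cfg.qpcr_ct_sd, n_samples)
        ct = np.clip(ct, 1.0, cfg.max_cycles)
        for s_i, s in enumerate(samples):
            qpcr_rows.append((s, t, float(ct[s_i]), float(ct_ref[s_i])))
    qpcr = pd.DataFrame(qpcr_rows,
                        columns=["sample_id", "miRNA_ID", "ct", "ct_reference"])

    truth = {
        "folds": {ids[i]: float(folds[i]) for i in range(n)
                  if folds[i] != 1.0},
        "signature": dict(cfg.signature),
        "absent": [ids[i] for i in np.flatnonzero(absent_mask)],
        "baselines": {ids[i]: float(baselines[i]) for i in range(n)},
        "qpcr_targets": targets,
    }
    return SyntheticCohort(scans, sheet, qpcr, truth, cfg)


def simulate_null_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """A cohort with no group effect anywhere: exchangeable arms."""
    cfg = config or SimulationConfig()
    null_cfg = dataclasses.replace(
        cfg, signature={}, control_folds={}, broad_down_fraction=0.0)
    return simulate_cohort(null_cfg)


def write_cohort(cohort: SyntheticCohort, outdir: Path | str) -> None:
    """Write scans/, sample_sheet.tsv, qpcr.tsv and truth.json."""
    outdir = Path(outdir)
    scan_dir = outdir / "scans"
    scan_dir.mkdir(parents=True, exist_ok=True)
    for scan in cohort.scans:
        write_scan_table(scan, scan_dir / f"{scan.sample_id}.tsv")
    write_sample_sheet(cohort.sample_sheet, outdir / "sample_sheet.tsv")
    write_qpcr_table(cohort.qpcr, outdir / "qpcr.tsv")
    (outdir / "truth.json").write_text(
        json.dumps(cohort.truth, indent=2) + "\n")
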