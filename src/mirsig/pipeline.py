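"""End-to-end orchestration: scans in, reports out.

``run_all`` normalizes every scan, assembles the expression matrix, runs the
fold-change census on the full matrix (published denominators count every
probe) while selecting the signature among reliably detected miRNAs (the >5
group-mean display filter), validates the screened miRNAs on the qPCR
table, correlates signature members with clinical scores inside the patient
group, and writes every stage artifact plus a JSON run report. A stage
failure aborts the run, removes the partial outputs written so far, and
re-raises with the stage named.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .array_io import (
    ExpressionMatrix,
    SampleSheet,
    read_qpcr_table,
    read_sample_sheet,
    read_scan_table,
    write_expression_matrix,
)
from .clinical_stats import (
    compare_small_rna_fractions,
    correlate_clinical,
    correlation_frame,
    flag_outlier_patient,
    write_correlations,
)
from .errors import FormatError, MirsigError, PipelineError
from .normalization import (
    NormalizationConfig,
    build_expression_matrix,
    heatmap_filter,
    normalize_scan,
)
from .qpcr import relative_expression_table, validate_mirnas, write_validation
from .screening import (
    census,
    select_signature,
    summarize_groups,
    write_census,
    write_group_summary,
    write_signature,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults are the study values."""

    scan_dir: Path | str = "scans"
    sample_sheet: Path | str = "sample_sheet.tsv"
    qpcr_table: Path | str | None = "qpcr.tsv"
    out_dir: Path | str = "out"
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    down_thresholds: tuple[float, float] = (2.0, 4.0)
    up_threshold: float = 1.5
    signature_min_fold: float = 6.0
    heatmap_min_group_mean: float = 5.0
    alpha: float = 0.05
    p_adjust: str | None = None
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        norm = NormalizationConfig(**raw.pop("normalization", {}))
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        if "down_thresholds" in raw:
            raw["down_thresholds"] = tuple(raw["down_thresholds"])
        return cls(normalization=norm, **raw)


@dataclass
class RunReport:
    """Stage-by-stage record of a pipeline run."""

    n_scans: int
    n_mirna: int
    n_present_filtered: int
    census: dict
    signature: dict
    validation: list[dict]
    correlations: list[dict]
    small_rna: dict | None
    outlier: dict | None
    warnings: list[str]
    config: dict
    version: str = __version__

    def as_dict(self) -> dict:
        return {
            "version": self.version,
            "n_scans": self.n_scans,
            "n_mirna": self.n_mirna,
            "n_present_filtered": self.n_present_filtered,
            "census": self.census,
            "signature": self.signature,
            "validation": self.validation,
            "correlations": self.correlations,
            "small_rna": self.small_rna,
            "outlier": self.outlier,
            "warnings": self.warnings,
            "config": self.config,
        }


def _jsonable(obj):
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_all(config: PipelineConfig) -> RunReport:
    cfg = config
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings: list[str] = []

    def _emit(name: str, writer, *args) -> Path:
        path = out_dir / name
        writer(*args, path)
        written.append(path)
        return path

    stage = "input"
    try:
        sheet_path = Path(cfg.sample_sheet)
        if not sheet_path.exists():
            raise FormatError(f"sample sheet not found: {sheet_path}")
        sheet = read_sample_sheet(sheet_path)
        scan_dir = Path(cfg.scan_dir)
        scans = []
        for sample_id in sheet.sample_ids:
            path = scan_dir / f"{sample_id}.tsv"
            if not path.exists():
                raise FormatError(f"missing scan table for sample {sample_id}: {path}")
            scans.append(read_scan_table(path, sample_id=sample_id,
                                         group=sheet.groups[sample_id]))
        logger.info("input: %d scans, %d spots each", len(scans),
                    len(scans[0].spots) if scans else 0)

        stage = "normalization"
        profiles = [normalize_scan(s, cfg.normalization) for s in scans]
        matrix = build_expression_matrix(profiles, sheet.groups)
        _emit("expression_matrix.tsv",
              lambda m, p: write_expression_matrix(m, p), matrix)
        logger.info("normalization: %d miRNAs x %d samples",
                    *matrix.values.shape)

        stage = "screening"
        summary = summarize_groups(matrix)
        census_report = census(summary, cfg.down_thresholds, cfg.up_threshold)
        # the census keeps the full probe denominator; the signature is
        # selected among reliably detected miRNAs (display filter)
        filtered = heatmap_filter(matrix, cfg.heatmap_min_group_mean)
        signature = select_signature(summarize_groups(filtered),
                                     cfg.signature_min_fold)
        _emit("group_summary.tsv", write_group_summary, summary)
        _emit("census.json", write_census, census_report)
        _emit("signature.json", write_signature, signature)
        logger.info("screening: %d/%d miRNAs pass the display filter; "
                    "signature size %d", filtered.values.shape[0],
                    matrix.values.shape[0], len(signature.members))
        if cfg.make_plots:
            from .plots import expression_heatmap
            _emit("heatmap.png",
                  lambda m, p: expression_heatmap(m, p), filtered)

        stage = "qpcr"
        validation_dicts: list[dict] = []
        if cfg.qpcr_table is not None and Path(cfg.qpcr_table).exists():
            qpcr_df = read_qpcr_table(cfg.qpcr_table)
            results = validate_mirnas(qpcr_df, sheet.groups, alpha=cfg.alpha,
                                      adjust=cfg.p_adjust)
            _emit("validation.tsv", write_validation, results)
            validation_dicts = [vars(r) for r in results]
            if cfg.make_plots:
                from .plots import qpcr_boxplots
                rel = relative_expression_table(qpcr_df)
                _emit("qpcr_boxplots.png",
                      lambda r, p: qpcr_boxplots(r, sheet.groups, p), rel)
        else:
            warnings.append("no qPCR table; validation stage skipped")

        stage = "clinical"
        correlations: list[dict] = []
        outlier = None
        if sheet.clinical().shape[1] and signature.members:
            corr = correlate_clinical(matrix, sheet,
                                      mirna_ids=signature.member_ids)
            _emit("correlations.tsv", write_correlations, corr)
            correlations = correlation_frame(corr).to_dict("records")
            outlier = flag_outlier_patient(matrix, sheet,
                                           signature.member_ids)
            _emit("outlier_report.json",
                  lambda o, p: Path(p).write_text(
                      json.dumps(_jsonable(o), indent=2) + "\n"), outlier)
        else:
            warnings.append("no clinical scores or empty signature; "
                            "correlation stage skipped")

        small_rna = None
        fractions = sheet.small_rna_fractions()
        if fractions is not None:
            small_rna = compare_small_rna_fractions(fractions, sheet.groups)

        stage = "report"
        report = RunReport(
            n_scans=len(scans),
            n_mirna=matrix.values.shape[0],
            n_present_filtered=filtered.values.shape[0],
            census=census_report.as_dict(),
            signature=signature.as_dict(),
            validation=validation_dicts,
            correlations=correlations,
            small_rna=small_rna,
            outlier=outlier,
            warnings=warnings,
            config={
                "normalization": vars(cfg.normalization),
                "down_thresholds": list(cfg.down_thresholds),
                "up_threshold": cfg.up_threshold,
                "signature_min_fold": cfg.signature_min_fold,
                "heatmap_min_group_mean": cfg.heatmap_min_group_mean,
                "alpha": cfg.alpha,
                "p_adjust": cfg.p_adjust,
                "seed": cfg.seed,
            },
        )
        (out_dir / "run_report.json").write_text(
            json.dumps(_jsonable(report.as_dict()), indent=2) + "\n")
        return report
    except MirsigError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
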