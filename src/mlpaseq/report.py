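"""Cohort pipeline: manifest handling, per-sample processing, and reports.

A cohort manifest lists one row per sample with its detection and
confirmation inputs (FASTQ or precomputed count tables), sample kind
(blood, tumour, ascites, control, ntc) and blood-tumour pairing.  The
pipeline builds (or loads) the control baseline, then for each sample runs
counting, QC, depth normalization, ratioing against the baseline,
exon pooling, classification, origin assignment and region merging.
Failures are isolated per sample: one bad input never aborts the cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .calling import (
    ClassificationConfig,
    CNVCall,
    ExonCall,
    SampleKind,
    assign_origin,
    classify_exon,
    merge_contiguous,
)
from .probe_design import Mix, ProbeDesign
from .quantify import (
    Baseline,
    ExonSummary,
    build_baseline,
    compute_ratios,
    depth_normalize,
    summarize_exons,
)
from .read_counting import (
    LibraryCounts,
    QCMetrics,
    QCThresholds,
    count_probes,
    load_counts,
    qc_library,
)

log = logging.getLogger("mlpaseq")

__all__ = [
    "ManifestError",
    "ManifestRow",
    "CohortManifest",
    "PipelineConfig",
    "SampleReport",
    "load_manifest",
    "run_pipeline",
    "write_summary_report",
    "export_ratio_plot_data",
]

_FASTQ_SUFFIXES = (".fastq", ".fq", ".fastq.gz", ".fq.gz")

_SAMPLE_KINDS = ("blood", "tumour", "ascites", "control", "ntc")


class ManifestError(ValueError):
    pass


@dataclass
class ManifestRow:
    sample_id: str
    kind: str  # blood | tumour | ascites | control | ntc
    detection_path: str = ""
    confirmation_path: str = ""
    paired_with: str = ""

    @property
    def sample_kind(self) -> SampleKind:
        """Calling mode: ascites behaves like tumour; controls like blood."""
        return SampleKind.tumour if self.kind in ("tumour", "ascites") else SampleKind.blood


@dataclass
class CohortManifest:
    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ManifestError(f"duplicate sample_id(s): {dupes}")
        known = set(ids)
        for r in self.rows:
            if r.kind not in _SAMPLE_KINDS:
                raise ManifestError(
                    f"sample {r.sample_id}: unknown kind {r.kind!r}"
                )
            if r.paired_with and r.paired_with not in known:
                raise ManifestError(
                    f"sample {r.sample_id}: paired_with references unknown "
                    f"sample {r.paired_with!r}"
                )

    def controls(self) -> list[ManifestRow]:
        return [r for r in self.rows if r.kind == "control"]

    def ntc(self) -> Optional[ManifestRow]:
        ntcs = [r for r in self.rows if r.kind == "ntc"]
        return ntcs[0] if ntcs else None

    def samples(self) -> list[ManifestRow]:
        return [r for r in self.rows if r.kind not in ("control", "ntc")]


def load_manifest(path: str | Path) -> CohortManifest:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "kind", "detection_path"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest column(s): {missing}")
    rows = [
        ManifestRow(
            sample_id=r.sample_id,
            kind=r.kind,
            detection_path=r.detection_path,
            confirmation_path=getattr(r, "confirmation_path", ""),
            paired_with=getattr(r, "paired_with", ""),
        )
        for r in table.itertuples(index=False)
    ]
    return CohortManifest(rows)


@dataclass
class PipelineConfig:
    qc: QCThresholds = field(default_factory=QCThresholds)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    match_mode: str = "exact"
    min_controls: int = 3
    baseline_cv_cap: float = 0.30
    #: apply QC verdicts as hard gates (failed libraries still produce
    #: reports; their calls are flagged)
    require_qc_pass: bool = False


@dataclass
class SampleReport:
    """Per-sample summary: coverage per library, on-target totals, NTC mean
    coverage, every design exon's pooled ratio, and the resulting calls."""

    sample_id: str
    kind: str
    mean_probe_coverage: dict[str, float]
    median_probe_coverage: dict[str, float]
    total_on_target_reads: int
    ntc_mean_coverage: Optional[float]
    qc: dict[str, QCMetrics]
    qc_passed: bool
    exon_summaries: list[ExonSummary]
    exon_calls: list[ExonCall]
    calls: list[CNVCall]
    excluded_probes: dict[str, str]
    error: str = ""


def _load_library(
    row_path: str,
    design: ProbeDesign,
    mix: Mix,
    sample_id: str,
    cfg: PipelineConfig,
    is_control: bool = False,
    is_ntc: bool = False,
) -> LibraryCounts:
    path = Path(row_path)
    if not path.exists():
        raise FileNotFoundError(f"sample {sample_id}: input not found: {path}")
    if path.name.endswith(_FASTQ_SUFFIXES):
        return count_probes(
            path, design, mix, sample_id=sample_id,
            match_mode=cfg.match_mode, is_control=is_control, is_ntc=is_ntc,
        )
    return load_counts(path, is_control=is_control, is_ntc=is_ntc)


def _libraries_for_row(
    row: ManifestRow, design: ProbeDesign, cfg: PipelineConfig
) -> dict[Mix, LibraryCounts]:
    libs: dict[Mix, LibraryCounts] = {}
    libs[Mix.detection] = _load_library(
        row.detection_path, design, Mix.detection, row.sample_id, cfg,
        is_control=row.kind == "control", is_ntc=row.kind == "ntc",
    )
    if row.confirmation_path:
        libs[Mix.confirmation] = _load_library(
            row.confirmation_path, design, Mix.confirmation, row.sample_id,
            cfg, is_control=row.kind == "control", is_ntc=row.kind == "ntc",
        )
    return libs


def _process_sample(
    sample_id: str,
    kind: str,
    libs: dict[Mix, LibraryCounts],
    design: ProbeDesign,
    baselines: dict[Mix, Baseline],
    cfg: PipelineConfig,
    ntc_libs: Optional[dict[Mix, LibraryCounts]],
) -> SampleReport:
    qc: dict[str, QCMetrics] = {}
    ratio_matrices = {}
    excluded: dict[str, str] = {}
    for mix, lib in libs.items():
        ntc = ntc_libs.get(mix) if ntc_libs else None
        qc[mix.value] = qc_library(lib, ntc, cfg.qc)
        normalized = depth_normalize(lib, design)
        matrix = compute_ratios(normalized, baselines[mix])
        ratio_matrices[mix] = matrix
        excluded.update(
            {f"{mix.value}:{pid}": why for pid, why in matrix.excluded.items()}
        )
    summaries = summarize_exons(
        ratio_matrices[Mix.detection],
        ratio_matrices.get(Mix.confirmation),
        design,
    )
    sample_kind = (
        SampleKind.tumour if kind in ("tumour", "ascites") else SampleKind.blood
    )
    exon_calls = [
        ExonCall(
            gene=s.gene,
            exon_label=s.exon_label,
            category=classify_exon(s, cfg.classification, sample_kind),
            mean_ratio=s.mean_ratio,
            sd_ratio=s.sd_ratio,
            n_probes=s.n_probes,
        )
        for s in summaries
    ]
    calls = merge_contiguous(exon_calls, design)
    ntc_means = [
        m.ntc_mean_coverage for m in qc.values() if m.ntc_mean_coverage is not None
    ]
    return SampleReport(
        sample_id=sample_id,
        kind=kind,
        mean_probe_coverage={
            mix.value: lib.mean_coverage() for mix, lib in libs.items()
        },
        median_probe_coverage={
            mix.value: lib.median_coverage() for mix, lib in libs.items()
        },
        total_on_target_reads=sum(lib.on_target_reads for lib in libs.values()),
        ntc_mean_coverage=(
            sum(ntc_means) / len(ntc_means) if ntc_means else None
        ),
        qc=qc,
        qc_passed=all(m.passed for m in qc.values()),
        exon_summaries=summaries,
        exon_calls=exon_calls,
        calls=calls,
        excluded_probes=excluded,
    )


def run_pipeline(
    manifest: CohortManifest,
    design: ProbeDesign,
    cfg: PipelineConfig = PipelineConfig(),
    baselines: Optional[dict[Mix, Baseline]] = None,
) -> dict[str, SampleReport]:
    """Process a cohort end to end.

    Baselines are taken from *baselines* when supplied, otherwise built
    from the manifest's control rows (below-floor control probes are marked
    unusable in the baseline).  Missing NTC degrades to a warning and an
    absent report field.
    """
    ntc_row = manifest.ntc()
    ntc_libs = None
    if ntc_row is None:
        log.warning("manifest has no NTC row; contamination check skipped")
    else:
        ntc_libs = _libraries_for_row(ntc_row, design, cfg)
    control_libs = [
        _libraries_for_row(row, design, cfg) for row in manifest.controls()
    ]
    if baselines is None:
        baselines = build_baselines_from_controls(control_libs, design, cfg)
    reports: dict[str, SampleReport] = {}
    for row in manifest.controls() + manifest.samples():
        try:
            libs = (
                control_libs[[c.sample_id for c in manifest.controls()].index(row.sample_id)]
                if row.kind == "control"
                else _libraries_for_row(row, design, cfg)
            )
            reports[row.sample_id] = _process_sample(
                row.sample_id, row.kind, libs, design, baselines, cfg, ntc_libs
            )
        except Exception as exc:  # per-sample isolation
            log.error("sample %s failed: %s", row.sample_id, exc)
            reports[row.sample_id] = SampleReport(
                sample_id=row.sample_id, kind=row.kind,
                mean_probe_coverage={}, median_probe_coverage={},
                total_on_target_reads=0, ntc_mean_coverage=None, qc={},
                qc_passed=False, exon_summaries=[], exon_calls=[], calls=[],
                excluded_probes={}, error=str(exc),
            )
    # paired origin assignment
    for row in manifest.samples():
        if row.sample_kind is not SampleKind.tumour:
            continue
        rep = reports.get(row.sample_id)
        if rep is None or rep.error:
            continue
        blood_rep = reports.get(row.paired_with) if row.paired_with else None
        blood_calls = blood_rep.exon_calls if blood_rep and not blood_rep.error else None
        rep.exon_calls = assign_origin(blood_calls, rep.exon_calls)
        rep.calls = merge_contiguous(rep.exon_calls, design)
    return reports


def build_baselines_from_controls(
    control_libs: Sequence[dict[Mix, LibraryCounts]],
    design: ProbeDesign,
    cfg: PipelineConfig = PipelineConfig(),
) -> dict[Mix, Baseline]:
    """One baseline per reaction mix from control libraries; control probes
    under the raw-coverage floor are flagged unusable."""
    baselines: dict[Mix, Baseline] = {}
    for mix in (Mix.detection, Mix.confirmation):
        per_mix = [libs[mix] for libs in control_libs if mix in libs]
        if not per_mix:
            continue
        unusable: dict[str, str] = {}
        for lib in per_mix:
            for pid, count in lib.counts.items():
                if count < cfg.qc.coverage_floor:
                    unusable.setdefault(
                        pid,
                        f"below {cfg.qc.coverage_floor}x floor in control "
                        f"{lib.sample_id}",
                    )
        normalized = [depth_normalize(lib, design) for lib in per_mix]
        baselines[mix] = build_baseline(
            normalized, design, min_controls=cfg.min_controls,
            cv_cap=cfg.baseline_cv_cap, unusable=unusable,
        )
    return baselines


# -- reports ---------------------------------------------------------------

def _report_payload(rep: SampleReport) -> dict:
    return {
        "sample_id": rep.sample_id,
        "kind": rep.kind,
        "mean_probe_coverage": rep.mean_probe_coverage,
        "median_probe_coverage": rep.median_probe_coverage,
        "total_on_target_reads": rep.total_on_target_reads,
        "ntc_mean_coverage": rep.ntc_mean_coverage,
        "qc_passed": rep.qc_passed,
        "qc": {mix: m.to_dict() for mix, m in rep.qc.items()},
        "exons": [
            {
                "gene": s.gene,
                "exon_label": s.exon_label,
                "mean_ratio": None if s.missing else round(s.mean_ratio, 4),
                "sd": None if s.missing else round(s.sd_ratio, 4),
                "n_probes": s.n_probes,
                "category": c.category.value,
            }
            for s, c in zip(rep.exon_summaries, rep.exon_calls)
        ],
        "calls": [
            {
                "gene": call.gene,
                "exons": call.exon_span(),
                "category": call.category.value,
                "mean_ratio": round(call.mean_ratio, 4),
                "copies": round(call.copies, 4),
                "origin": call.origin.value,
                "amplification_level": call.amplification_level,
            }
            for call in rep.calls
        ],
        "excluded_probes": rep.excluded_probes,
        "error": rep.error,
    }


def write_summary_report(
    rep: SampleReport,
    text_path: Optional[str | Path] = None,
    json_path: Optional[str | Path] = None,
) -> str:
    """Serialize one sample's summary; returns the text rendering."""
    lines = [
        f"Sample: {rep.sample_id} ({rep.kind})",
        *(
            f"Mean probe coverage [{mix}]: {cov:.1f}"
            for mix, cov in sorted(rep.mean_probe_coverage.items())
        ),
        f"Total aligned reads on target: {rep.total_on_target_reads}",
        "NTC mean coverage: "
        + (f"{rep.ntc_mean_coverage:.2f}" if rep.ntc_mean_coverage is not None
           else "not available"),
        f"QC: {'PASS' if rep.qc_passed else 'FAIL'}",
        "",
        "gene\texon\tmean_ratio\tsd\tn_probes\tcategory",
    ]
    for s, c in zip(rep.exon_summaries, rep.exon_calls):
        ratio = "NA" if s.missing else f"{s.mean_ratio:.3f}"
        sd = "NA" if s.missing else f"{s.sd_ratio:.3f}"
        lines.append(
            f"{s.gene}\t{s.exon_label}\t{ratio}\t{sd}\t{s.n_probes}\t"
            f"{c.category.value}"
        )
    lines.append("")
    if rep.calls:
        lines.append("Calls:")
        for call in rep.calls:
            level = f" ({call.amplification_level})" if call.amplification_level else ""
            lines.append(
                f"  {call.gene} {call.exon_span()}: {call.category.value}"
                f"{level}, mean ratio {call.mean_ratio:.3f}, "
                f"{call.copies:.2f} copies, origin {call.origin.value}"
            )
    else:
        lines.append("Calls: none")
    text = "\n".join(lines) + "\n"
    if text_path is not None:
        Path(text_path).write_text(text)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(_report_payload(rep), indent=2) + "\n"
        )
    return text


def export_ratio_plot_data(
    rep: SampleReport,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> pd.DataFrame:
    """Per-exon series for ratio plots, with the normal-band limits (0.7
    lower, 1.3 upper) as constant columns.  Rendering is left to the caller."""
    rows = [
        {
            "order": i,
            "gene": s.gene,
            "exon_label": s.exon_label,
            "mean_ratio": s.mean_ratio,
            "sd": s.sd_ratio,
            "band_lower": cfg.normal_low,
            "band_upper": cfg.normal_high,
        }
        for i, s in enumerate(rep.exon_summaries)
    ]
    columns = ["order", "gene", "exon_label", "mean_ratio", "sd",
               "band_lower", "band_upper"]
    return pd.DataFrame(rows, columns=columns)
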