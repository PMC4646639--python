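"""Dosage quantification: depth normalization, control baseline, exon pooling.

The quantification chain is, per probe k of sample i:

    x'_ik  = x_ik / X_i           within-library depth normalization,
                                  X_i = mean raw count over probes of genes
                                  not assayed for amplification
    x''_ik = x'_ik / xbar'_k      copy-number ratio against the per-probe
                                  mean over accumulated control samples

and per targeted exon j the mean and sample SD of x'' pooled over the
detection and confirmation libraries (and replicate probes within a
library).  A ratio of 1 corresponds to the diploid two-copy state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .probe_design import Mix, ProbeDesign, design_checksum
from .read_counting import LibraryCounts

__all__ = [
    "QuantifyError",
    "DepthNormalized",
    "Baseline",
    "RatioMatrix",
    "ExonSummary",
    "depth_normalize",
    "build_baseline",
    "compute_ratios",
    "summarize_exons",
    "write_baseline",
    "load_baseline",
]


class QuantifyError(ValueError):
    pass


@dataclass
class DepthNormalized:
    """Depth-normalised probe values x' for one library; their mean over
    non-amplification probes is 1 by construction."""

    sample_id: str
    mix: Mix
    values: dict[str, float]
    normalizer: float  # X_i, mean raw coverage over non-amplification probes


@dataclass
class Baseline:
    """Per-probe control means (the ratio denominator) for one mix.

    Accumulated over control samples, possibly across runs.  A probe is
    unusable when its control coverage was unreliable (below the raw floor
    in some control) or its between-control CV exceeds the cap.
    """

    mix: Mix
    per_probe_mean: dict[str, float]
    per_probe_cv: dict[str, float]
    n_controls: int
    unusable: dict[str, str] = field(default_factory=dict)  # probe -> reason
    design_checksum: str = ""


@dataclass
class RatioMatrix:
    """Copy-number ratios x'' for one library; 1 = two copies."""

    sample_id: str
    mix: Mix
    ratios: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)  # probe -> reason


@dataclass
class ExonSummary:
    """Pooled per-exon dosage: mean and sample SD (n-1 denominator) over all
    usable probe ratios from both libraries."""

    gene: str
    exon_label: str
    mean_ratio: float
    sd_ratio: float
    n_probes: int
    missing: bool = False


def depth_normalize(lib: LibraryCounts, design: ProbeDesign) -> DepthNormalized:
    """Divide every probe's raw count by X_i, the arithmetic mean of raw
    counts over probes whose gene is not assayed for amplification.

    Amplification-gene probes are excluded from the mean (a genuine
    amplification would inflate X_i and mask itself) but still receive
    normalised values.
    """
    probes = design.probes_in_mix(lib.mix)
    non_amp = [p for p in probes if p.gene not in design.amplification_genes]
    if not non_amp:
        raise QuantifyError("no non-amplification probes to normalise against")
    x_i = sum(lib.counts.get(p.probe_id, 0) for p in non_amp) / len(non_amp)
    if x_i == 0:
        raise QuantifyError(
            f"library {lib.sample_id}/{lib.mix.value}: zero mean coverage, "
            "unusable"
        )
    values = {p.probe_id: lib.counts.get(p.probe_id, 0) / x_i for p in probes}
    return DepthNormalized(
        sample_id=lib.sample_id, mix=lib.mix, values=values, normalizer=x_i
    )


def build_baseline(
    controls: Sequence[DepthNormalized],
    design: ProbeDesign | None = None,
    min_controls: int = 3,
    cv_cap: float = 0.30,
    unusable: Optional[dict[str, str]] = None,
) -> Baseline:
    """Average depth-normalised control values per probe.

    *unusable* carries upstream flags (e.g. probes under the raw-coverage
    floor in a control library); probes whose between-control coefficient of
    variation exceeds *cv_cap* are additionally marked unusable.
    """
    if len(controls) < min_controls:
        raise QuantifyError(
            f"need at least {min_controls} control samples, got {len(controls)}"
        )
    mixes = {c.mix for c in controls}
    if len(mixes) != 1:
        raise QuantifyError("controls mix reaction mixes; build one baseline per mix")
    (mix,) = mixes
    probe_ids = list(controls[0].values)
    means: dict[str, float] = {}
    cvs: dict[str, float] = {}
    flagged = dict(unusable or {})
    n = len(controls)
    for pid in probe_ids:
        vals = [c.values.get(pid, 0.0) for c in controls]
        m = sum(vals) / n
        means[pid] = m
        if m > 0 and n > 1:
            var = sum((v - m) ** 2 for v in vals) / (n - 1)
            cv = math.sqrt(var) / m
        else:
            cv = float("inf") if m == 0 else 0.0
        cvs[pid] = cv
        if m == 0:
            flagged.setdefault(pid, "zero mean in controls")
        elif cv > cv_cap:
            flagged.setdefault(pid, f"control CV {cv:.3f} above cap {cv_cap}")
    return Baseline(
        mix=mix,
        per_probe_mean=means,
        per_probe_cv=cvs,
        n_controls=n,
        unusable=flagged,
        design_checksum=design_checksum(design) if design is not None else "",
    )


def compute_ratios(sample: DepthNormalized, baseline: Baseline) -> RatioMatrix:
    """Copy-number ratio per probe: x' divided by its control baseline mean.

    Probes marked unusable in the baseline (or with a zero baseline mean)
    are excluded with the reason recorded, never silently dropped.
    """
    if sample.mix is not baseline.mix:
        raise QuantifyError(
            f"baseline is for {baseline.mix.value} mix, sample library is "
            f"{sample.mix.value}"
        )
    ratios: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for pid, value in sample.values.items():
        if pid in baseline.unusable:
            excluded[pid] = baseline.unusable[pid]
            continue
        mean = baseline.per_probe_mean.get(pid)
        if mean is None:
            excluded[pid] = "absent from baseline"
        elif mean == 0:
            excluded[pid] = "zero baseline mean"
        else:
            ratios[pid] = value / mean
    return RatioMatrix(
        sample_id=sample.sample_id, mix=sample.mix, ratios=ratios,
        excluded=excluded,
    )


def summarize_exons(
    det: RatioMatrix,
    conf: Optional[RatioMatrix],
    design: ProbeDesign,
) -> list[ExonSummary]:
    """Pool probe ratios per exon across the detection and confirmation
    libraries and compute mean and sample SD.

    Probes carried in both mixes contribute one measurement per library
    (they are separate reactions).  An exon with no usable probe is emitted
    with the missing flag rather than dropped.
    """
    matrices = [(Mix.detection, det)]
    if conf is not None:
        matrices.append((Mix.confirmation, conf))
    summaries: list[ExonSummary] = []
    for gene in design.genes():
        for exon in design.exon_order(gene):
            pooled: list[float] = []
            for mix, matrix in matrices:
                for probe in design.probes_for_exon(exon, mix):
                    r = matrix.ratios.get(probe.probe_id)
                    if r is not None:
                        pooled.append(r)
            if not pooled:
                summaries.append(
                    ExonSummary(gene, exon, float("nan"), float("nan"), 0, True)
                )
                continue
            n = len(pooled)
            mean = sum(pooled) / n
            sd = (
                math.sqrt(sum((r - mean) ** 2 for r in pooled) / (n - 1))
                if n > 1
                else 0.0
            )
            summaries.append(ExonSummary(gene, exon, mean, sd, n))
    return summaries


# -- baseline persistence --------------------------------------------------

def write_baseline(baseline: Baseline, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# design_checksum={baseline.design_checksum}\t"
            f"mix={baseline.mix.value}\tn_controls={baseline.n_controls}\n"
        )
        fh.write("probe_id\tmean\tcv\tusable\treason\n")
        for pid in sorted(baseline.per_probe_mean):
            reason = baseline.unusable.get(pid, "")
            fh.write(
                f"{pid}\t{baseline.per_probe_mean[pid]:.10g}\t"
                f"{baseline.per_probe_cv[pid]:.10g}\t"
                f"{0 if reason else 1}\t{reason}\n"
            )


def load_baseline(
    path: str | Path, design: ProbeDesign | None = None
) -> Baseline:
    """Read a persisted baseline; if *design* is given, refuse a checksum
    mismatch (baselines never cross design versions)."""
    with open(path) as fh:
        header = fh.readline()
    meta = {}
    for part in header.lstrip("#").strip().split("\t"):
        key, _, value = part.partition("=")
        meta[key] = value
    if design is not None and meta.get("design_checksum"):
        expected = design_checksum(design)
        if meta["design_checksum"] != expected:
            raise QuantifyError(
                f"{path}: baseline was built for design "
                f"{meta['design_checksum']}, current design is {expected}"
            )
    import pandas as pd

    table = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    means = {}
    cvs = {}
    unusable = {}
    for row in table.itertuples(index=False):
        pid = str(row.probe_id)
        means[pid] = float(row.mean)
        cvs[pid] = float(row.cv)
        if not int(row.usable):
            unusable[pid] = str(row.reason) or "flagged unusable"
    return Baseline(
        mix=Mix(meta["mix"]),
        per_probe_mean=means,
        per_probe_cv=cvs,
        n_controls=int(meta.get("n_controls", 0)),
        unusable=unusable,
        design_checksum=meta.get("design_checksum", ""),
    )
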