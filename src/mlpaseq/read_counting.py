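"""Per-probe read counting from demultiplexed FASTQ, plus library-level QC.

Reads are assigned to probes by exact (optionally 1-mismatch) matching of
the 20-base ligation-junction key, searched on both strands after 3'
adapter trimming.  Counting uses read 1 only: amplicon inserts are ~60 bp,
so both mates contain the full key and counting both would double-count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Optional, Sequence

import pandas as pd
import pysam

from .probe_design import (
    DEFAULT_ADAPTERS,
    DesignError,
    Mix,
    ProbeDesign,
    reverse_complement,
)

__all__ = [
    "LibraryCounts",
    "QCThresholds",
    "QCMetrics",
    "FastqFormatError",
    "extract_insert",
    "count_probes",
    "qc_library",
    "write_counts",
    "load_counts",
]


class FastqFormatError(ValueError):
    pass


@dataclass
class LibraryCounts:
    """Raw per-probe read counts for one reaction library.

    ``counts`` holds the raw coverage value of every probe present in the
    library's mix (absent probes count 0).  Bookkeeping reconciles exactly:
    total_reads = on_target_reads + ambiguous_reads + off-target, and
    on_target_reads equals the sum of counts.
    """

    sample_id: str
    mix: Mix
    counts: dict[str, int]
    total_reads: int = 0
    on_target_reads: int = 0
    ambiguous_reads: int = 0
    is_control: bool = False
    is_ntc: bool = False

    def __post_init__(self) -> None:
        if self.total_reads == 0 and self.on_target_reads == 0:
            self.on_target_reads = sum(self.counts.values())
            self.total_reads = self.on_target_reads + self.ambiguous_reads
        if sum(self.counts.values()) > self.on_target_reads:
            raise ValueError("sum of counts exceeds on-target reads")
        if self.on_target_reads + self.ambiguous_reads > self.total_reads:
            raise ValueError("on-target + ambiguous exceeds total reads")

    @property
    def off_target_reads(self) -> int:
        return self.total_reads - self.on_target_reads - self.ambiguous_reads

    def mean_coverage(self) -> float:
        return sum(self.counts.values()) / len(self.counts) if self.counts else 0.0

    def median_coverage(self) -> float:
        return float(median(self.counts.values())) if self.counts else 0.0


@dataclass(frozen=True)
class QCThresholds:
    """Coverage gates for accepting a library.

    A library needs 1000-fold median probe coverage; individual probes under
    the 500-fold floor are flagged.  The no-template control's mean probe
    coverage must stay below ``ntc_fraction`` of the sample's mean (the
    contamination check).
    """

    coverage_floor: int = 500
    median_coverage_requirement: int = 1000
    ntc_fraction: float = 0.01


@dataclass
class QCMetrics:
    sample_id: str
    mix: Mix
    median_probe_coverage: float
    mean_probe_coverage: float
    n_probes_below_floor: int
    probes_below_floor: list[str]
    coverage_floor: int
    median_coverage_requirement: int
    ntc_mean_coverage: Optional[float]
    ntc_ok: bool
    passed: bool

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["mix"] = self.mix.value
        return d


def _check_fastq_header(path: str | Path) -> None:
    """A 4-line FASTQ file must open with '@'; anything else is garbled."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    try:
        with opener(path, "rt") as fh:
            first = fh.read(1)
    except OSError as exc:
        raise FastqFormatError(f"{path}: unreadable: {exc}") from exc
    if first and first != "@":
        raise FastqFormatError(
            f"{path}: garbled FASTQ record 1: expected '@' header, "
            f"found {first!r}"
        )


def extract_insert(
    read: str,
    adapter: str = DEFAULT_ADAPTERS[1],
    min_overlap: int = 10,
) -> str:
    """Trim a 3' suffix of *read* that matches the start of the downstream
    adapter (>= min_overlap bases).  No-op when no adapter is found."""
    idx = read.find(adapter)
    if idx >= 0:
        return read[:idx]
    # partial adapter at the very end of the read
    max_len = min(len(adapter), len(read)) - 1
    for length in range(max_len, min_overlap - 1, -1):
        if read.endswith(adapter[:length]):
            return read[: len(read) - length]
    return read


def _key_index(
    design: ProbeDesign, mix: Mix, match_mode: str
) -> tuple[dict[str, str], int]:
    """Map every acceptable k-mer (both strands, optionally the 1-mismatch
    neighbourhood) to its probe_id."""
    probes = design.probes_in_mix(mix)
    if not probes:
        raise DesignError(f"no probes in {mix.value} mix")
    k = len(probes[0].middle_key)
    index: dict[str, str] = {}

    def add(kmer: str, probe_id: str) -> None:
        other = index.get(kmer)
        if other is not None and other != probe_id:
            raise DesignError(
                f"key collision in {mix.value} mix between {other} and "
                f"{probe_id} (mode {match_mode})"
            )
        index[kmer] = probe_id

    for p in probes:
        for key in (p.middle_key, reverse_complement(p.middle_key)):
            add(key, p.probe_id)
            if match_mode == "one_mismatch":
                for i, base in enumerate(key):
                    for sub in "ACGT":
                        if sub != base:
                            add(key[:i] + sub + key[i + 1:], p.probe_id)
    return index, k


def count_probes(
    fastq_paths: Sequence[str | Path] | str | Path,
    design: ProbeDesign,
    mix: Mix,
    sample_id: str = "",
    match_mode: str = "exact",
    adapters: tuple[str, str] = DEFAULT_ADAPTERS,
    is_control: bool = False,
    is_ntc: bool = False,
) -> LibraryCounts:
    """Assign reads to probes by middle-key matching.

    A read matching exactly one probe key (either strand) increments that
    probe and the on-target counter; zero matches is off-target; matches to
    two or more distinct probes (chimera signature) are discarded as
    ambiguous and counted separately.
    """
    if match_mode not in ("exact", "one_mismatch"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    index, k = _key_index(design, mix, match_mode)
    counts = {p.probe_id: 0 for p in design.probes_in_mix(mix)}
    total = on_target = ambiguous = 0
    for path in fastq_paths:
        _check_fastq_header(path)
        record_idx = 0
        try:
            with pysam.FastxFile(str(path)) as fh:
                for record_idx, rec in enumerate(fh, start=1):
                    if rec.quality is None or not rec.sequence:
                        raise FastqFormatError(
                            f"{path}: garbled FASTQ record {record_idx}"
                            f" ({rec.name!r})"
                        )
                    total += 1
                    seq = extract_insert(rec.sequence.upper(), adapters[1])
                    hits: set[str] = set()
                    for i in range(len(seq) - k + 1):
                        probe = index.get(seq[i : i + k])
                        if probe is not None:
                            hits.add(probe)
                            if len(hits) > 1:
                                break
                    if len(hits) == 1:
                        counts[hits.pop()] += 1
                        on_target += 1
                    elif len(hits) > 1:
                        ambiguous += 1
        except OSError as exc:
            raise FastqFormatError(
                f"{path}: unreadable FASTQ near record {record_idx + 1}: {exc}"
            ) from exc
    return LibraryCounts(
        sample_id=sample_id,
        mix=mix,
        counts=counts,
        total_reads=total,
        on_target_reads=on_target,
        ambiguous_reads=ambiguous,
        is_control=is_control,
        is_ntc=is_ntc,
    )


def qc_library(
    lib: LibraryCounts,
    ntc: Optional[LibraryCounts] = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCMetrics:
    """Library acceptance: median probe coverage against the requirement,
    per-probe floor flags, and the NTC contamination check."""
    med = lib.median_coverage()
    mean = lib.mean_coverage()
    below = sorted(
        pid for pid, c in lib.counts.items() if c < thresholds.coverage_floor
    )
    ntc_mean = ntc.mean_coverage() if ntc is not None else None
    ntc_ok = True
    if ntc_mean is not None and mean > 0:
        ntc_ok = ntc_mean < thresholds.ntc_fraction * mean
    return QCMetrics(
        sample_id=lib.sample_id,
        mix=lib.mix,
        median_probe_coverage=med,
        mean_probe_coverage=mean,
        n_probes_below_floor=len(below),
        probes_below_floor=below,
        coverage_floor=thresholds.coverage_floor,
        median_coverage_requirement=thresholds.median_coverage_requirement,
        ntc_mean_coverage=ntc_mean,
        ntc_ok=ntc_ok,
        passed=(med >= thresholds.median_coverage_requirement) and ntc_ok,
    )


def write_counts(lib: LibraryCounts, path: str | Path) -> None:
    """Counts TSV (probe_id, count) with library totals in comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id={lib.sample_id}\tmix={lib.mix.value}\n")
        fh.write(
            f"# total_reads={lib.total_reads}\t"
            f"on_target_reads={lib.on_target_reads}\t"
            f"ambiguous_reads={lib.ambiguous_reads}\n"
        )
        fh.write("probe_id\tcount\n")
        for pid in sorted(lib.counts):
            fh.write(f"{pid}\t{lib.counts[pid]}\n")


def load_counts(
    path: str | Path,
    is_control: bool = False,
    is_ntc: bool = False,
) -> LibraryCounts:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        for part in line[1:].strip().split("\t"):
            key, _, value = part.partition("=")
            meta[key] = value
    table = pd.read_csv(path, sep="\t", comment="#")
    counts = dict(zip(table["probe_id"].astype(str), table["count"].astype(int)))
    on_target = sum(counts.values())
    return LibraryCounts(
        sample_id=meta.get("sample_id", Path(path).stem),
        mix=Mix(meta.get("mix", "detection")),
        counts=counts,
        total_reads=int(meta.get("total_reads", on_target)),
        on_target_reads=int(meta.get("on_target_reads", on_target)),
        ambiguous_reads=int(meta.get("ambiguous_reads", 0)),
        is_control=is_control,
        is_ntc=is_ntc,
    )
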