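"""Synthetic MLPA-seq data with known truth.

The generator emulates the statistical structure of the assay: fixed
per-probe amplification efficiencies shared by all libraries (they cancel
against the control baseline exactly as real probe biases do), multiplicative
ratio-scale noise (lognormal, default SD 0.103 — the empirical per-probe
ratio spread of control samples), Poisson counting at a 1000x target depth,
and optional zero-inflated dropout for degraded/low-input libraries.  A
"table1"-style preset reproduces the published panel structure (157 probes
over 11 target genes, PTEN-flank/pseudogene confirmation targets and 7
reference genes).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .calling import Category, ExonCall, _GAINS, _LOSSES
from .probe_design import (
    DEFAULT_ADAPTERS,
    Mix,
    ProbeDesign,
    ProbePair,
    Role,
)
from .read_counting import LibraryCounts

__all__ = [
    "SimulationConfig",
    "QUALITY_TIERS",
    "CNEvent",
    "TruthSet",
    "simulate_design",
    "table1_design",
    "simulate_efficiencies",
    "simulate_counts",
    "simulate_ntc",
    "simulate_fastq",
    "simulate_case_truth",
    "simulate_cohort",
    "CohortSim",
    "Evaluation",
    "evaluate_calls",
    "pooled_noise_sd",
]

#: Quality tier -> (ratio-noise multiplier, dropout rate).  Tiers mirror the
#: gel-based amplifiable-fragment grading of FFPE DNA; the numeric mapping is
#: this package's own, since the grading is qualitative.
QUALITY_TIERS: dict[str, tuple[float, float]] = {
    "very_good": (1.0, 0.0),
    "good": (1.1, 0.0),
    "moderate": (1.3, 0.02),
    "poor": (1.6, 0.05),
    "very_poor": (2.0, 0.10),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    target_depth is reads per probe at two copies; probe_noise_sd is the
    ratio-scale SD of the multiplicative per-measurement noise;
    probe_efficiency_spread is the lognormal sigma of the fixed per-probe
    efficiency multipliers; dropout_rate zero-inflates probe counts
    (FFPE/low-input failure mode).  The quality tier scales noise and
    dropout on top of the base values.
    """

    seed: int
    n_controls: int = 8
    target_depth: float = 1000.0
    probe_noise_sd: float = 0.103
    probe_efficiency_spread: float = 0.25
    dropout_rate: float = 0.0
    quality_tier: str = "very_good"
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.quality_tier not in QUALITY_TIERS:
            raise ValueError(f"unknown quality tier {self.quality_tier!r}")
        for name in ("probe_noise_sd", "probe_efficiency_spread", "dropout_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be a probability")

    @property
    def effective_noise_sd(self) -> float:
        return self.probe_noise_sd * QUALITY_TIERS[self.quality_tier][0]

    @property
    def effective_dropout(self) -> float:
        return min(1.0, self.dropout_rate + QUALITY_TIERS[self.quality_tier][1])


@dataclass(frozen=True)
class CNEvent:
    """One true copy-number event: integer copies over a run of exons."""

    gene: str
    exon_labels: tuple[str, ...]
    copies: int
    germline: bool = True

    def __post_init__(self) -> None:
        if self.copies < 0 or self.copies != int(self.copies):
            raise ValueError("pure-clone copies must be a non-negative integer")

    @property
    def is_loss(self) -> bool:
        return self.copies < 2


@dataclass
class TruthSet:
    """Ground truth for one simulated specimen.

    Somatic events are diluted by tumour purity (the non-neoplastic
    remainder is diploid); germline events apply to every cell.
    """

    events: list[CNEvent] = field(default_factory=list)
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")

    def copies_for(self, gene: str, exon_label: str) -> float:
        for ev in self.events:
            if ev.gene == gene and exon_label in ev.exon_labels:
                if ev.germline:
                    return float(ev.copies)
                return self.purity * ev.copies + (1 - self.purity) * 2.0
        return 2.0

    def expected_ratio(self, gene: str, exon_label: str) -> float:
        return self.copies_for(gene, exon_label) / 2.0


# -- design generation -----------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_arm(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _make_probe(
    rng: np.random.Generator,
    probe_id: str,
    gene: str,
    exon_label: str,
    mix: Mix,
    role: Role,
    used_keys: set[str],
    arm_length: int = 30,
    max_tries: int = 100,
) -> ProbePair:
    left_adapter, right_adapter = DEFAULT_ADAPTERS
    for _ in range(max_tries):
        left = _random_arm(rng, arm_length)
        right = _random_arm(rng, arm_length)
        key = left[-10:] + right[:10]
        if key not in used_keys:
            used_keys.add(key)
            return ProbePair(
                probe_id=probe_id,
                gene=gene,
                exon_label=exon_label,
                mix=mix,
                role=role,
                left_seq=left_adapter + left,
                right_seq=right + right_adapter,
            )
    raise RuntimeError(f"could not draw a collision-free key for {probe_id}")


def simulate_design(
    n_genes: int = 6,
    exons_per_gene: int = 8,
    probes_per_exon: int = 2,
    n_reference: int = 7,
    seed: int = 0,
    n_amplification: int = 0,
    arm_length: int = 30,
) -> ProbeDesign:
    """Random synthetic panel.

    Target (deletion) genes get ``probes_per_exon`` probes per exon,
    alternating detection/confirmation mix so each exon is covered in both
    reaction libraries.  Amplification genes get one single-exon probe each
    in both mixes; reference genes likewise.  Probe arm sequences are random
    and middle keys are collision-checked.
    """
    if min(n_genes, exons_per_gene, probes_per_exon) < 1 or n_reference < 1:
        raise ValueError("all design dimensions must be positive")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    probes: list[ProbePair] = []
    for g in range(n_genes):
        gene = f"GENE{g + 1}"
        for e in range(exons_per_gene):
            exon = f"{gene}_ex{e + 1}"
            for r in range(probes_per_exon):
                mix = Mix.detection if r % 2 == 0 else Mix.confirmation
                suffix = chr(ord("a") + r)
                probes.append(
                    _make_probe(
                        rng, f"{exon}{suffix}", gene, exon, mix,
                        Role.target_deletion, used, arm_length,
                    )
                )
    for a in range(n_amplification):
        gene = f"AMP{a + 1}"
        exon = f"{gene}_ex1"
        probes.append(
            _make_probe(rng, f"{exon}a", gene, exon, Mix.both,
                        Role.target_amplification, used, arm_length)
        )
    for r in range(n_reference):
        gene = f"REF{r + 1}"
        exon = f"{gene}_ex1"
        probes.append(
            _make_probe(rng, f"{exon}a", gene, exon, Mix.both,
                        Role.reference, used, arm_length)
        )
    return ProbeDesign(probes)


#: Rows (gene, n_exons, {mix: n_probes}, role) of the published panel
#: structure; per-gene probe totals sum to 157.  'both'-mix probes are
#: single physical probes present in each reaction.  The detection/
#: confirmation split within the multi-probe genes is this package's own.
_TABLE1_LAYOUT: list[tuple[str, int, dict[Mix, int], Role]] = [
    ("BRCA1", 23, {Mix.detection: 26, Mix.confirmation: 26}, Role.target_deletion),
    ("BRCA2", 27, {Mix.detection: 31, Mix.confirmation: 33}, Role.target_deletion),
    ("PTEN", 9, {Mix.detection: 20}, Role.target_deletion),
    ("ERBB2", 2, {Mix.both: 2}, Role.target_amplification),
    ("MYC", 1, {Mix.both: 1}, Role.target_amplification),
    ("MET", 1, {Mix.both: 1}, Role.target_amplification),
    ("CCNE1", 2, {Mix.both: 2}, Role.target_amplification),
    ("NF1", 1, {Mix.both: 1}, Role.target_deletion),
    ("RB1", 1, {Mix.both: 1}, Role.target_deletion),
    ("AURKA", 1, {Mix.both: 1}, Role.target_amplification),
    ("EMSY", 1, {Mix.both: 1}, Role.target_amplification),
    ("ITIH5", 1, {Mix.confirmation: 1}, Role.pten_flank),
    ("ANXA7", 1, {Mix.confirmation: 1}, Role.pten_flank),
    ("HTRA1", 1, {Mix.confirmation: 1}, Role.pten_flank),
    ("PTENP1", 1, {Mix.confirmation: 1}, Role.pten_pseudogene),
    ("CFTR", 1, {Mix.both: 1}, Role.reference),
    ("GCH1", 1, {Mix.both: 1}, Role.reference),
    ("JAG1", 1, {Mix.both: 1}, Role.reference),
    ("OPTN", 1, {Mix.both: 1}, Role.reference),
    ("GPC3", 1, {Mix.both: 1}, Role.reference),
    ("PANK2", 1, {Mix.both: 1}, Role.reference),
    ("FLCN", 1, {Mix.both: 1}, Role.reference),
]


def table1_design(seed: int = 0, arm_length: int = 30) -> ProbeDesign:
    """Synthetic 157-probe panel reproducing the published per-gene probe
    counts (sequences are random stand-ins, never the vendor's)."""
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    probes: list[ProbePair] = []
    for gene, n_exons, mix_counts, role in _TABLE1_LAYOUT:
        for mix, count in mix_counts.items():
            per_exon: dict[int, int] = {}
            for i in range(count):
                per_exon[i % n_exons] = per_exon.get(i % n_exons, 0) + 1
            for e in range(n_exons):
                exon = f"{gene}_ex{e + 1}"
                for rep in range(per_exon.get(e, 0)):
                    suffix = chr(ord("a") + rep)
                    tag = "" if mix is Mix.both else f"_{mix.value[:3]}"
                    probes.append(
                        _make_probe(
                            rng, f"{exon}{suffix}{tag}", gene, exon,
                            mix, role, used, arm_length,
                        )
                    )
    return ProbeDesign(probes)


# -- count generation ------------------------------------------------------

def _lognormal_noise(
    rng: np.random.Generator, sd: float, size: int
) -> np.ndarray:
    """Multiplicative noise with mean 1 and ratio-scale SD *sd*."""
    if sd == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(sd * sd))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def simulate_efficiencies(
    design: ProbeDesign, cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Fixed per-probe amplification efficiency multipliers, drawn once per
    design and shared by every simulated library (so they cancel against the
    control baseline, as real probe biases do).

    Draws are renormalised to median 1 so that ``target_depth`` is the
    median probe coverage of a diploid library — the scale on which the
    assay's coverage requirement is stated.
    """
    if cfg.probe_efficiency_spread == 0:
        return {p.probe_id: 1.0 for p in design.probes}
    sigma = cfg.probe_efficiency_spread
    draws = rng.lognormal(mean=0.0, sigma=sigma, size=len(design.probes))
    draws /= np.median(draws)
    return {p.probe_id: float(x) for p, x in zip(design.probes, draws)}


def simulate_counts(
    design: ProbeDesign,
    truth: TruthSet,
    cfg: SimulationConfig,
    mix: Mix,
    rng: np.random.Generator,
    efficiencies: Optional[dict[str, float]] = None,
    sample_id: str = "sim",
    is_control: bool = False,
) -> LibraryCounts:
    """Draw one library's raw probe counts.

    Expected count of probe k = depth * efficiency_k * (local copies / 2) *
    lognormal noise, then Poisson-sampled (optional) and zero-inflated by
    the dropout rate.  Local copies come from the truth's purity/mixture
    model.
    """
    probes = design.probes_in_mix(mix)
    if efficiencies is None:
        efficiencies = {p.probe_id: 1.0 for p in probes}
    noise = _lognormal_noise(rng, cfg.effective_noise_sd, len(probes))
    counts: dict[str, int] = {}
    for p, eta in zip(probes, noise):
        dosage = truth.copies_for(p.gene, p.exon_label) / 2.0
        lam = cfg.target_depth * efficiencies.get(p.probe_id, 1.0) * dosage * eta
        if cfg.effective_dropout and rng.random() < cfg.effective_dropout:
            counts[p.probe_id] = 0
        elif cfg.poisson:
            counts[p.probe_id] = int(rng.poisson(lam))
        else:
            counts[p.probe_id] = int(round(lam))
    return LibraryCounts(
        sample_id=sample_id, mix=mix, counts=counts, is_control=is_control,
    )


def simulate_ntc(
    design: ProbeDesign,
    mix: Mix,
    rng: np.random.Generator,
    mean_background: float = 0.0,
    sample_id: str = "NTC",
) -> LibraryCounts:
    """No-template control: zero (or trace background) probe counts."""
    probes = design.probes_in_mix(mix)
    counts = {
        p.probe_id: int(rng.poisson(mean_background)) if mean_background else 0
        for p in probes
    }
    return LibraryCounts(
        sample_id=sample_id, mix=mix, counts=counts, is_ntc=True,
    )


def simulate_fastq(
    lib: LibraryCounts,
    design: ProbeDesign,
    path: str | Path,
    read_length: int = 150,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> None:
    """Write read-1 FASTQ for a library: each probe contributes ``count``
    reads of its ligated insert followed by the downstream adapter, padded
    to the read length.  Round-trips through the counter exactly."""
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    adapter = DEFAULT_ADAPTERS[1]
    templates: list[str] = []
    multiplicities: list[int] = []
    for p in design.probes_in_mix(lib.mix):
        c = lib.counts.get(p.probe_id, 0)
        if c <= 0:
            continue
        seq = (p.ligated_sequence() + adapter).ljust(read_length, "A")
        templates.append(seq[:read_length])
        multiplicities.append(c)
    order = rng.permutation(int(np.sum(multiplicities))) if templates else []
    reads = np.repeat(np.arange(len(templates)), multiplicities)
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, tmpl_idx in enumerate(reads[order] if len(templates) else []):
            seq = templates[int(tmpl_idx)]
            fh.write(f"@{lib.sample_id}_read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# -- cohorts and truth generation -----------------------------------------

def simulate_case_truth(
    design: ProbeDesign,
    rng: np.random.Generator,
    min_exons: int = 3,
    max_exons: int = 6,
    copies_choices: Sequence[int] = (1, 3),
    germline: bool = True,
    purity: float = 1.0,
) -> TruthSet:
    """One random multi-exon single-copy-change event on a deletion-target
    gene (copies 1 = heterozygous deletion, 3 = duplication)."""
    target_genes = sorted(
        gene
        for gene in {p.gene for p in design.probes
                     if p.role is Role.target_deletion}
        if len(design.exon_order(gene)) >= min_exons
    )
    if not target_genes:
        raise ValueError(
            f"no deletion-target gene has >= {min_exons} exons"
        )
    gene = target_genes[int(rng.integers(len(target_genes)))]
    exons = design.exon_order(gene)
    span = int(rng.integers(min_exons, min(max_exons, len(exons)) + 1))
    start = int(rng.integers(0, len(exons) - span + 1))
    copies = int(copies_choices[int(rng.integers(len(copies_choices)))])
    event = CNEvent(
        gene=gene,
        exon_labels=tuple(exons[start : start + span]),
        copies=copies,
        germline=germline,
    )
    return TruthSet(events=[event], purity=purity)


@dataclass
class CohortSim:
    """A simulated cohort: control and case libraries plus per-case truth."""

    design: ProbeDesign
    config: SimulationConfig
    controls: list[dict[Mix, LibraryCounts]]
    cases: list[tuple[TruthSet, dict[Mix, LibraryCounts]]]
    ntc: dict[Mix, LibraryCounts]
    efficiencies: dict[str, float]


def simulate_cohort(
    design: ProbeDesign,
    cfg: SimulationConfig,
    n_cases: int,
    min_exons: int = 3,
    max_exons: int = 6,
    copies_choices: Sequence[int] = (1, 3),
) -> CohortSim:
    """Controls (diploid) plus cases each carrying one germline multi-exon
    event, both reaction mixes per sample, one shared efficiency draw."""
    rng = np.random.default_rng(cfg.seed)
    eff = simulate_efficiencies(design, cfg, rng)
    diploid = TruthSet()
    controls = []
    for i in range(cfg.n_controls):
        libs = {}
        for mix in (Mix.detection, Mix.confirmation):
            libs[mix] = simulate_counts(
                design, diploid, cfg, mix, rng, eff,
                sample_id=f"control{i + 1}", is_control=True,
            )
        controls.append(libs)
    cases = []
    for i in range(n_cases):
        truth = simulate_case_truth(
            design, rng, min_exons, max_exons, copies_choices
        )
        libs = {}
        for mix in (Mix.detection, Mix.confirmation):
            libs[mix] = simulate_counts(
                design, truth, cfg, mix, rng, eff, sample_id=f"case{i + 1}",
            )
        cases.append((truth, libs))
    ntc = {
        mix: simulate_ntc(design, mix, rng)
        for mix in (Mix.detection, Mix.confirmation)
    }
    return CohortSim(design, cfg, controls, cases, ntc, eff)


# -- truth-aware evaluation ------------------------------------------------

@dataclass
class Evaluation:
    n_events: int
    n_detected: int
    n_negative_exons: int
    n_false_positive: int
    missed_events: list[tuple[str, CNEvent]]

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.n_detected / self.n_events if self.n_events else 100.0

    @property
    def specificity_pct(self) -> float:
        if not self.n_negative_exons:
            return 100.0
        return 100.0 * (
            (self.n_negative_exons - self.n_false_positive)
            / self.n_negative_exons
        )


def evaluate_calls(
    exon_calls_by_sample: dict[str, Sequence[ExonCall]],
    truth_by_sample: dict[str, TruthSet],
) -> Evaluation:
    """Score calls against truth.

    An event is detected when at least one of its exons is called in the
    correct direction.  Specificity is exon-level over truly two-copy exons
    across all samples: the fraction classified normal (equivocal gains,
    which are reported but not called, still count against specificity).
    """
    n_events = n_detected = 0
    n_neg = n_fp = 0
    missed: list[tuple[str, CNEvent]] = []
    for sample_id, calls in exon_calls_by_sample.items():
        truth = truth_by_sample.get(sample_id, TruthSet())
        by_exon = {(c.gene, c.exon_label): c for c in calls}
        for ev in truth.events:
            n_events += 1
            want = _LOSSES if ev.is_loss else _GAINS
            hit = any(
                (c := by_exon.get((ev.gene, exon))) is not None
                and c.category in want
                for exon in ev.exon_labels
            )
            n_detected += hit
            if not hit:
                missed.append((sample_id, ev))
        for call in calls:
            if truth.copies_for(call.gene, call.exon_label) == 2.0:
                if call.category is Category.missing:
                    continue
                n_neg += 1
                if call.category is not Category.normal:
                    n_fp += 1
    return Evaluation(n_events, n_detected, n_neg, n_fp, missed)


def pooled_noise_sd(
    n_exons: int = 100_000,
    probes_per_exon: int = 2,
    probe_sd: float = 0.103,
    seed: int = 0,
) -> float:
    """SD of exon-mean ratios when each exon pools independent probe ratios
    drawn from the generator's noise law (mean 1, ratio-scale SD probe_sd)."""
    rng = np.random.default_rng(seed)
    draws = _lognormal_noise(rng, probe_sd, n_exons * probes_per_exon)
    means = draws.reshape(n_exons, probes_per_exon).mean(axis=1)
    return float(means.std(ddof=1))
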