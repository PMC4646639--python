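"""CNV classification, germline/somatic origin, and the dosage mixture model.

Classification acts on the per-exon mean copy-number ratio alone (1 = two
copies).  Band boundaries, all dimensionless ratios:

    ratio <= 0.3          homozygous deletion (0 copies)
    0.3 < ratio < 0.7     heterozygous deletion (~1 copy)
    0.7 <= ratio <= 1.3   normal diploid variation, not called
    ratio > 1.3 (blood)   duplication
    ratio > 1.5 (tumour)  amplification (>3 average copies)
    1.3 < ratio <= 1.5 in tumour: equivocal gain, reported for review but
    not called — tumour genomic instability makes this band unreliable.

The mixture model converts cellularity to expected dosage: a specimen that
is a mixture of cell populations with ``fraction_c`` of cells carrying
``copies_c`` copies shows ratio sum_c fraction_c * copies_c / 2.  Tumour
purity is the two-component special case (neoplastic vs normal diploid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .probe_design import ProbeDesign
from .quantify import ExonSummary

__all__ = [
    "Category",
    "Origin",
    "SampleKind",
    "ClassificationConfig",
    "DosageComponent",
    "ExonCall",
    "CNVCall",
    "classify_ratio",
    "classify_exon",
    "ratio_to_copies",
    "expected_mixture_ratio",
    "somatic_detection_limit",
    "assign_origin",
    "merge_contiguous",
    "amplification_level",
]


class Category(str, Enum):
    normal = "normal"
    het_deletion = "het_deletion"
    hom_deletion = "hom_deletion"
    duplication = "duplication"
    amplification = "amplification"
    equivocal_gain = "equivocal_gain"
    missing = "missing"


#: Categories counting as a loss / as a gain when comparing blood vs tumour.
_LOSSES = {Category.het_deletion, Category.hom_deletion}
_GAINS = {Category.duplication, Category.amplification, Category.equivocal_gain}


class Origin(str, Enum):
    germline = "germline"
    somatic = "somatic"
    germline_with_LOH = "germline_with_LOH"
    undetermined = "undetermined"


class SampleKind(str, Enum):
    blood = "blood"
    tumour = "tumour"


@dataclass(frozen=True)
class ClassificationConfig:
    """Ratio band boundaries.  Both edges of the normal band belong to the
    normal category (conservative calling); 0.3 belongs to the homozygous
    deletion ("0.3 or less"); amplification requires strictly above 1.5."""

    normal_low: float = 0.7
    normal_high: float = 1.3
    amplification_min: float = 1.5
    hom_del_max: float = 0.3
    reference_ploidy: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.hom_del_max < self.normal_low
                < self.normal_high < self.amplification_min):
            raise ValueError(
                "band boundaries must satisfy hom_del_max < normal_low "
                "< normal_high < amplification_min"
            )


def classify_ratio(
    ratio: float,
    cfg: ClassificationConfig = ClassificationConfig(),
    sample_kind: SampleKind = SampleKind.blood,
) -> Category:
    """Map one mean ratio to its CNV category; the bands partition [0, inf)."""
    if math.isnan(ratio):
        return Category.missing
    if ratio < 0:
        raise ValueError("ratios are non-negative")
    if ratio <= cfg.hom_del_max:
        return Category.hom_deletion
    if ratio < cfg.normal_low:
        return Category.het_deletion
    if ratio <= cfg.normal_high:
        return Category.normal
    if sample_kind is SampleKind.blood:
        return Category.duplication
    if ratio > cfg.amplification_min:
        return Category.amplification
    return Category.equivocal_gain


def classify_exon(
    summary: ExonSummary,
    cfg: ClassificationConfig = ClassificationConfig(),
    sample_kind: SampleKind = SampleKind.blood,
) -> Category:
    if summary.missing:
        return Category.missing
    return classify_ratio(summary.mean_ratio, cfg, sample_kind)


def ratio_to_copies(mean_ratio: float, reference_ploidy: int = 2) -> float:
    """Average copies implied by a dosage ratio against a diploid reference."""
    if mean_ratio < 0:
        raise ValueError("ratio must be non-negative")
    return reference_ploidy * mean_ratio


@dataclass(frozen=True)
class DosageComponent:
    """One cell population in a mixture: its proportion and its copy number
    at the locus of interest."""

    fraction: float
    copies: float

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        if self.copies < 0:
            raise ValueError("copies must be non-negative")


def _as_components(
    components: Iterable[DosageComponent | tuple[float, float]],
) -> list[DosageComponent]:
    return [
        c if isinstance(c, DosageComponent) else DosageComponent(*c)
        for c in components
    ]


def expected_mixture_ratio(
    components: Iterable[DosageComponent | tuple[float, float]],
) -> float:
    """Expected dosage ratio of a cell mixture: sum(fraction * copies) / 2."""
    comps = _as_components(components)
    total = sum(c.fraction for c in comps)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"component fractions sum to {total}, expected 1")
    return sum(c.fraction * c.copies for c in comps) / 2.0


def somatic_detection_limit(
    purity: float,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> Optional[int]:
    """Smallest somatic copy loss detectable at the given tumour purity.

    Returns the least integer loss d (1 = heterozygous, 2 = homozygous)
    whose expected mixture ratio, with the non-neoplastic remainder diploid,
    falls below the normal band; None when even a homozygous deletion stays
    within normal variation (undetectable).
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    for loss in (1, 2):
        ratio = expected_mixture_ratio(
            [(purity, 2 - loss), (1.0 - purity, 2)]
        )
        if ratio < cfg.normal_low:
            return loss
    return None


# -- calls -----------------------------------------------------------------

@dataclass
class ExonCall:
    """Classification of a single exon in a single sample."""

    gene: str
    exon_label: str
    category: Category
    mean_ratio: float
    sd_ratio: float
    n_probes: int
    origin: Origin = Origin.undetermined

    @property
    def copies(self) -> float:
        return ratio_to_copies(self.mean_ratio)


@dataclass
class CNVCall:
    """A reported event: a maximal run of same-category exons in one gene."""

    gene: str
    exon_labels: list[str]
    category: Category
    mean_ratio: float
    origin: Origin = Origin.undetermined
    amplification_level: Optional[str] = None

    @property
    def copies(self) -> float:
        return ratio_to_copies(self.mean_ratio)

    def exon_span(self) -> str:
        if len(self.exon_labels) == 1:
            return self.exon_labels[0]
        return f"{self.exon_labels[0]}-{self.exon_labels[-1]}"


def amplification_level(copies: float) -> Optional[str]:
    """Qualitative amplification strata on the estimated average copies:
    low (>3 to 6), medium (>6 to 12), high (>12)."""
    if copies > 12:
        return "high"
    if copies > 6:
        return "medium"
    if copies > 3:
        return "low"
    return None


def assign_origin(
    blood_calls: Optional[Sequence[ExonCall]],
    tumour_calls: Sequence[ExonCall],
) -> list[ExonCall]:
    """Annotate tumour exon calls with germline/somatic origin from the
    paired blood sample.

    A loss or gain seen in both samples is germline; seen only in tumour,
    somatic.  A tumour homozygous deletion over a blood heterozygous
    deletion is a germline deletion with loss of heterozygosity of the
    remaining allele.  Without a paired blood sample the origin stays
    undetermined, except that a tumour homozygous deletion is reported as
    germline-with-LOH (the interpretation applied to unpaired tumours).
    """
    blood_by_exon: dict[tuple[str, str], ExonCall] = {}
    if blood_calls is not None:
        blood_by_exon = {(c.gene, c.exon_label): c for c in blood_calls}
    annotated: list[ExonCall] = []
    for call in tumour_calls:
        origin = Origin.undetermined
        if call.category in _LOSSES | _GAINS:
            blood = blood_by_exon.get((call.gene, call.exon_label))
            if blood is None and blood_calls is not None:
                origin = Origin.undetermined
            elif blood_calls is None:
                if call.category is Category.hom_deletion:
                    origin = Origin.germline_with_LOH
            elif (call.category is Category.hom_deletion
                    and blood.category is Category.het_deletion):
                origin = Origin.germline_with_LOH
            elif call.category in _LOSSES and blood.category in _LOSSES:
                origin = Origin.germline
            elif call.category in _GAINS and blood.category in _GAINS:
                origin = Origin.germline
            else:
                origin = Origin.somatic
        annotated.append(
            ExonCall(
                gene=call.gene,
                exon_label=call.exon_label,
                category=call.category,
                mean_ratio=call.mean_ratio,
                sd_ratio=call.sd_ratio,
                n_probes=call.n_probes,
                origin=origin,
            )
        )
    return annotated


def merge_contiguous(
    calls: Sequence[ExonCall],
    design: ProbeDesign,
    annotate_amplification: bool = True,
) -> list[CNVCall]:
    """Merge per-exon calls into region-level events.

    Within each gene, in design exon order, maximal runs of the same
    non-normal category (and origin) become one call whose mean ratio is
    the mean of its member exons.  Normal and missing exons break runs and
    are not reported.
    """
    by_exon = {(c.gene, c.exon_label): c for c in calls}
    merged: list[CNVCall] = []
    for gene in design.genes():
        run: list[ExonCall] = []

        def flush() -> None:
            if not run:
                return
            mean = sum(c.mean_ratio for c in run) / len(run)
            call = CNVCall(
                gene=gene,
                exon_labels=[c.exon_label for c in run],
                category=run[0].category,
                mean_ratio=mean,
                origin=run[0].origin,
            )
            if annotate_amplification and call.category is Category.amplification:
                call.amplification_level = amplification_level(call.copies)
            merged.append(call)
            run.clear()

        for exon in design.exon_order(gene):
            call = by_exon.get((gene, exon))
            if (call is None
                    or call.category in (Category.normal, Category.missing)):
                flush()
                continue
            if run and (run[0].category is not call.category
                        or run[0].origin is not call.origin):
                flush()
            run.append(call)
        flush()
    return merged
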