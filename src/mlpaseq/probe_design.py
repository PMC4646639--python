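"""MLPA-seq probe designs: domain types, validation, TSV I/O and key derivation.

An MLPA probe pair is a left and a right oligonucleotide that hybridise
adjacently on genomic DNA and are ligated only on perfect juxtaposition.
After PCR the amplicon abundance tracks target copy number.  In the
sequence-resolved variant each amplified pair is recognised in reads by a
short *middle key*: the k-mer (default 20 bases) spanning the ligation
junction, which is unique to the probe within its reaction mix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "Mix",
    "Role",
    "ProbePair",
    "ProbeDesign",
    "DesignError",
    "derive_middle_key",
    "load_design",
    "write_design",
    "write_suspects",
    "load_suspects",
    "design_summary",
    "design_checksum",
    "reverse_complement",
    "NEXTERA_READ1_ADAPTER",
    "NEXTERA_READ2_ADAPTER",
    "DEFAULT_ADAPTERS",
]

# Illumina Nextera transposase adapter sequences added to the probe oligos as
# PCR/sequencing overhangs.  The left oligo carries the read-1 adapter as a 5'
# prefix; the right oligo carries the reverse complement of the read-2 adapter
# as a 3' suffix, so that read 1 runs left arm -> right arm -> adapter.
NEXTERA_READ1_ADAPTER = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
NEXTERA_READ2_ADAPTER = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_DNA_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: (left-oligo 5' prefix, right-oligo 3' suffix) stripped before key derivation.
DEFAULT_ADAPTERS: tuple[str, str] = (
    NEXTERA_READ1_ADAPTER,
    reverse_complement(NEXTERA_READ2_ADAPTER),
)


class DesignError(ValueError):
    """Raised for malformed or internally inconsistent probe designs."""


class Mix(str, Enum):
    """Reaction mix membership of a probe pair."""

    detection = "detection"
    confirmation = "confirmation"
    both = "both"

    def includes(self, library_mix: "Mix") -> bool:
        """Whether a probe with this membership is present in *library_mix*."""
        if library_mix is Mix.both:
            raise ValueError("a library is either detection or confirmation")
        return self is Mix.both or self is library_mix


class Role(str, Enum):
    """Functional role of the gene a probe targets."""

    target_deletion = "target_deletion"
    target_amplification = "target_amplification"
    reference = "reference"
    pten_flank = "pten_flank"
    pten_pseudogene = "pten_pseudogene"


@dataclass(frozen=True)
class ProbePair:
    """One ligation probe pair.

    ``left_seq``/``right_seq`` are stored *with* their adapter overhangs;
    ``middle_key`` is derived from the adapter-stripped hybridising arms and
    spans the ligation junction.  ``coords`` (1-based inclusive) are
    annotation only and never enter any computation.
    """

    probe_id: str
    gene: str
    exon_label: str
    mix: Mix
    role: Role
    left_seq: str
    right_seq: str
    middle_key: str = ""
    coords: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if not self.middle_key:
            object.__setattr__(self, "middle_key", derive_middle_key(self))
        if len(self.middle_key) != 20:
            raise DesignError(
                f"probe {self.probe_id}: middle_key must be 20 bases, "
                f"got {len(self.middle_key)}"
            )
        for name, seq in (("left_seq", self.left_seq),
                          ("right_seq", self.right_seq),
                          ("middle_key", self.middle_key)):
            if not set(seq) <= _DNA_ALPHABET:
                bad = sorted(set(seq) - _DNA_ALPHABET)
                raise DesignError(
                    f"probe {self.probe_id}: {name} contains non-ACGT "
                    f"characters {bad}"
                )
        if self.middle_key not in self.ligated_sequence():
            raise DesignError(
                f"probe {self.probe_id}: middle_key does not span the "
                "ligation junction of the adapter-stripped arms"
            )

    def arms(self, adapters: tuple[str, str] = DEFAULT_ADAPTERS) -> tuple[str, str]:
        """Adapter-stripped (left, right) hybridising arms."""
        left_adapter, right_adapter = adapters
        left = self.left_seq
        if left.startswith(left_adapter):
            left = left[len(left_adapter):]
        right = self.right_seq
        if right_adapter and right.endswith(right_adapter):
            right = right[: len(right) - len(right_adapter)]
        return left, right

    def ligated_sequence(self, adapters: tuple[str, str] = DEFAULT_ADAPTERS) -> str:
        """Adapter-free sequence of the ligated probe pair (the insert)."""
        left, right = self.arms(adapters)
        return left + right


def derive_middle_key(
    pair: ProbePair,
    k: int = 20,
    adapters: tuple[str, str] = DEFAULT_ADAPTERS,
) -> str:
    """k-mer centred on the ligation junction: k/2 bases from the 3' end of
    the left arm plus k/2 bases from the 5' start of the right arm.

    Centring on the junction makes the key ligation specific: it can only
    occur in reads from a successfully ligated (and therefore copy-number
    informative) probe pair, never from either unligated oligo alone.
    """
    if k % 2:
        raise ValueError("key length k must be even")
    left, right = pair.arms(adapters)
    half = k // 2
    if len(left) < half or len(right) < half:
        raise DesignError(
            f"probe {pair.probe_id}: arms too short for a {k}-base key "
            f"(left {len(left)}, right {len(right)})"
        )
    return left[-half:] + right[:half]


@dataclass
class ProbeDesign:
    """A validated assay definition: probes plus the gene role partition.

    ``amplification_genes`` (genes assayed for somatic amplification) are
    excluded from the within-library depth-normalisation mean, since a true
    amplification would otherwise drag the normaliser and suppress its own
    signal.  ``reference_genes`` are copy-number-stable genes carried for
    normalisation.  Both sets are derived from probe roles.
    """

    probes: list[ProbePair]
    amplification_genes: frozenset[str] = field(init=False)
    reference_genes: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.amplification_genes = frozenset(
            p.gene for p in self.probes if p.role is Role.target_amplification
        )
        self.reference_genes = frozenset(
            p.gene for p in self.probes if p.role is Role.reference
        )
        self.validate()

    def validate(self) -> None:
        ids = [p.probe_id for p in self.probes]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise DesignError(f"duplicate probe_id(s): {dupes}")
        gene_roles: dict[str, set[Role]] = {}
        for p in self.probes:
            gene_roles.setdefault(p.gene, set()).add(p.role)
        mixed = {g: sorted(r.value for r in roles)
                 for g, roles in gene_roles.items() if len(roles) > 1}
        if mixed:
            raise DesignError(f"genes with conflicting roles: {mixed}")
        if self.amplification_genes & self.reference_genes:
            raise DesignError("amplification and reference gene sets overlap")
        for mix in (Mix.detection, Mix.confirmation):
            keys: dict[str, str] = {}
            for p in self.probes_in_mix(mix):
                if p.middle_key in keys:
                    raise DesignError(
                        f"middle_key collision in {mix.value} mix: "
                        f"{keys[p.middle_key]} vs {p.probe_id}"
                    )
                keys[p.middle_key] = p.probe_id

    # -- lookups -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.probes)

    def __getitem__(self, probe_id: str) -> ProbePair:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def probes_in_mix(self, mix: Mix) -> list[ProbePair]:
        return [p for p in self.probes if p.mix.includes(mix)]

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.probes:
            seen.setdefault(p.gene, None)
        return list(seen)

    def exon_order(self, gene: str) -> list[str]:
        """Exon labels of *gene* in design (genomic) order."""
        seen: dict[str, None] = {}
        for p in self.probes:
            if p.gene == gene:
                seen.setdefault(p.exon_label, None)
        return list(seen)

    def exon_labels(self) -> list[str]:
        """All exon labels, design order, gene-major."""
        out: list[str] = []
        for gene in self.genes():
            out.extend(self.exon_order(gene))
        return out

    def probes_for_exon(self, exon_label: str, mix: Mix) -> list[ProbePair]:
        return [p for p in self.probes_in_mix(mix) if p.exon_label == exon_label]


# -- TSV I/O ---------------------------------------------------------------

_REQUIRED_COLUMNS = ["probe_id", "gene", "exon_label", "mix", "role",
                     "left_seq", "right_seq"]
_OPTIONAL_COLUMNS = ["chrom", "start", "end"]


def load_design(path: str | Path) -> ProbeDesign:
    """Read a probe design from a tab-separated file.

    Required columns: probe_id, gene, exon_label, mix, role, left_seq,
    right_seq.  Optional: chrom, start, end (1-based inclusive).
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DesignError(f"{path}: missing required column(s): {missing}")
    probes = []
    for row in table.itertuples(index=False):
        try:
            mix = Mix(row.mix)
        except ValueError:
            raise DesignError(
                f"{path}: probe {row.probe_id}: unknown mix {row.mix!r}"
            ) from None
        try:
            role = Role(row.role)
        except ValueError:
            raise DesignError(
                f"{path}: probe {row.probe_id}: unknown role {row.role!r}"
            ) from None
        coords = None
        if "chrom" in table.columns and getattr(row, "chrom", ""):
            coords = (row.chrom, int(row.start), int(row.end))
        probes.append(
            ProbePair(
                probe_id=row.probe_id,
                gene=row.gene,
                exon_label=row.exon_label,
                mix=mix,
                role=role,
                left_seq=row.left_seq,
                right_seq=row.right_seq,
                coords=coords,
            )
        )
    return ProbeDesign(probes)


def write_design(design: ProbeDesign, path: str | Path) -> None:
    rows = []
    for p in design.probes:
        chrom, start, end = p.coords if p.coords else ("", "", "")
        rows.append(
            {
                "probe_id": p.probe_id,
                "gene": p.gene,
                "exon_label": p.exon_label,
                "mix": p.mix.value,
                "role": p.role.value,
                "left_seq": p.left_seq,
                "right_seq": p.right_seq,
                "chrom": chrom,
                "start": start,
                "end": end,
            }
        )
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS + _OPTIONAL_COLUMNS).to_csv(
        Path(path), sep="\t", index=False
    )


def write_suspects(design: ProbeDesign, mix: Mix, path: str | Path) -> None:
    """Write the key list for one mix: headerless TSV (probe_id, 20-mer),
    ordered by probe_id."""
    if mix is Mix.both:
        raise ValueError("suspects files are written per reaction mix")
    probes = sorted(design.probes_in_mix(mix), key=lambda p: p.probe_id)
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.middle_key}\n")


def load_suspects(path: str | Path) -> dict[str, str]:
    """Read a suspects file back as probe_id -> key."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            probe_id, key = line.rstrip("\n").split("\t")
            out[probe_id] = key
    return out


def design_summary(design: ProbeDesign) -> pd.DataFrame:
    """Per-gene probe counts with a TOTAL row (total = number of probes)."""
    rows = []
    for gene in design.genes():
        gene_probes = [p for p in design.probes if p.gene == gene]
        rows.append(
            {
                "gene": gene,
                "role": gene_probes[0].role.value,
                "n_probes": len(gene_probes),
                "n_detection": sum(
                    p.mix.includes(Mix.detection) for p in gene_probes
                ),
                "n_confirmation": sum(
                    p.mix.includes(Mix.confirmation) for p in gene_probes
                ),
            }
        )
    rows.append(
        {
            "gene": "TOTAL",
            "role": "",
            "n_probes": len(design.probes),
            "n_detection": len(design.probes_in_mix(Mix.detection)),
            "n_confirmation": len(design.probes_in_mix(Mix.confirmation)),
        }
    )
    return pd.DataFrame(rows)


def design_checksum(design: ProbeDesign) -> str:
    """Stable fingerprint of the assay definition (probe ids + keys).

    Baselines record it and refuse to be applied across design versions.
    """
    payload = "\n".join(
        sorted(f"{p.probe_id}\t{p.middle_key}\t{p.mix.value}" for p in design.probes)
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
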