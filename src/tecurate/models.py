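"""Core domain types shared across the curation pipeline.

The type system mirrors the objects a curator manipulates: a library of
consensus sequences with Wicker-style classifications, local-alignment and
protein-domain hits, structural feature sets, and genomic TE annotations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class TEClass(str, enum.Enum):
    """Top-level TE class: retrotransposons (I), DNA transposons (II)."""

    CLASS_I = "ClassI"
    CLASS_II = "ClassII"
    UNCLASSIFIED = "Unclassified"


class Order(str, enum.Enum):
    """Wicker-style TE orders (MITE kept as a pragmatic extra order)."""

    LTR = "LTR"
    LINE = "LINE"
    SINE = "SINE"
    DIRS = "DIRS"
    PLE = "PLE"
    TIR = "TIR"
    HELITRON = "Helitron"
    MAVERICK = "Maverick"
    CRYPTON = "Crypton"
    MITE = "MITE"
    UNCLASSIFIED = "Unclassified"


#: Orders that replicate through an RNA intermediate.
CLASS_I_ORDERS = frozenset({Order.LTR, Order.LINE, Order.SINE, Order.DIRS, Order.PLE})
#: DNA-intermediate orders.
CLASS_II_ORDERS = frozenset(
    {Order.TIR, Order.HELITRON, Order.MAVERICK, Order.CRYPTON, Order.MITE}
)


def class_of_order(order: Order) -> TEClass:
    if order in CLASS_I_ORDERS:
        return TEClass.CLASS_I
    if order in CLASS_II_ORDERS:
        return TEClass.CLASS_II
    return TEClass.UNCLASSIFIED


@dataclass(frozen=True)
class TEClassification:
    """A (class, order, superfamily) triple plus the optional Wicker code.

    ``order == Unclassified`` with a known ``te_class`` encodes the generic
    "Class I"/"Class II" labels that structural classification can emit when
    only coding domains are recognisable.
    """

    order: Order = Order.UNCLASSIFIED
    superfamily: str = ""
    wicker_code: str = ""
    te_class: TEClass = TEClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.order is not Order.UNCLASSIFIED:
            object.__setattr__(self, "te_class", class_of_order(self.order))
        if self.order is Order.UNCLASSIFIED and self.superfamily:
            raise ValueError("unclassified order cannot carry a superfamily")

    @property
    def label(self) -> str:
        """Header label after the '#': ``Order/Superfamily`` (or class-only)."""
        if self.order is Order.UNCLASSIFIED:
            if self.te_class is not TEClass.UNCLASSIFIED:
                return self.te_class.value
            return Order.UNCLASSIFIED.value
        if self.superfamily:
            return f"{self.order.value}/{self.superfamily}"
        return self.order.value

    def is_generic_class(self) -> bool:
        return (
            self.order is Order.UNCLASSIFIED
            and self.te_class is not TEClass.UNCLASSIFIED
        )


UNCLASSIFIED = TEClassification()


class Status(str, enum.Enum):
    RAW = "raw"
    KEPT = "kept"
    REMOVED = "removed"
    INCOMPLETE = "incomplete"


class RemovalReason(str, enum.Enum):
    NONE = "none"
    EXCLUDED_NOMENCLATURE = "excluded_nomenclature"
    SATELLITE_OR_RNA = "satellite_or_rna"
    REDUNDANT = "redundant"
    FEW_FLF = "few_flf"
    GENE_OR_RRNA = "gene_or_rrna"
    SSR = "ssr"


@dataclass
class ConsensusRecord:
    """One library entry: sequence, classification, curation fate."""

    id: str
    sequence: str
    classification: TEClassification = UNCLASSIFIED
    status: Status = Status.RAW
    removal_reason: RemovalReason = RemovalReason.NONE
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "#" in self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def note(self, stage: str, message: str) -> None:
        self.provenance.append((stage, message))

    def remove(self, reason: RemovalReason, stage: str, message: str) -> None:
        self.status = Status.REMOVED
        self.removal_reason = reason
        self.note(stage, message)

    def mark_incomplete(self, stage: str, message: str) -> None:
        self.status = Status.INCOMPLETE
        if not self.id.endswith("_inc"):
            self.id = self.id + "_inc"
        self.note(stage, message)

    @property
    def header(self) -> str:
        return f"{self.id}#{self.classification.label}"

    def is_kept(self) -> bool:
        return self.status in (Status.RAW, Status.KEPT, Status.INCOMPLETE)


@dataclass
class LibraryDocument:
    """An ordered TE library plus the log of excluded entries."""

    records: list[ConsensusRecord] = field(default_factory=list)
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def kept(self) -> list[ConsensusRecord]:
        return [r for r in self.records if r.is_kept()]

    def removed(self) -> list[ConsensusRecord]:
        return [r for r in self.records if r.status is Status.REMOVED]

    def get(self, record_id: str) -> ConsensusRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)


@dataclass(frozen=True)
class AlignmentHit:
    """A local-similarity match, 0-based half-open, subject forward strand."""

    query_id: str
    subject_id: str
    identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    aln_length: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError("bad query interval")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError("bad subject interval")
        if self.aln_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


class ProfileRole(str, enum.Enum):
    RT = "RT"
    INT = "INT"
    GAG = "GAG"
    PROT = "PROT"
    RNASEH = "RNaseH"
    EN = "EN"
    TRANSPOSASE = "Transposase"
    HELICASE = "Helicase"
    RRNA = "rRNA"
    HOST_GENE = "HostGene"


#: Roles diagnostic of retrotransposon (Class I) coding capacity.
RETRO_ROLES = frozenset(
    {ProfileRole.RT, ProfileRole.INT, ProfileRole.GAG, ProfileRole.PROT,
     ProfileRole.RNASEH, ProfileRole.EN}
)
#: Roles diagnostic of DNA-transposon (Class II) coding capacity.
DNA_ROLES = frozenset({ProfileRole.TRANSPOSASE, ProfileRole.HELICASE})


@dataclass(frozen=True)
class DomainHit:
    """A protein-profile match on one translated frame of a nucleotide query."""

    profile_name: str
    profile_role: ProfileRole
    q_start: int  # amino-acid coords on the translated frame
    q_end: int
    frame: int  # 1..3 forward, -1..-3 reverse
    evalue: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end):
            raise ValueError("bad domain interval")
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if self.frame not in (-3, -2, -1, 1, 2, 3):
            raise ValueError("frame out of range")


@dataclass
class StructuralFeatureSet:
    """Detected terminal repeats, poly(A) tail and coding domains."""

    ltr: Optional[tuple[tuple[int, int], tuple[int, int], float]] = None
    tir: Optional[tuple[tuple[int, int], tuple[int, int], float]] = None
    polya: Optional[tuple[tuple[int, int], float]] = None
    domains: list[DomainHit] = field(default_factory=list)

    def roles(self) -> set[ProfileRole]:
        return {d.profile_role for d in self.domains}

    def has_role(self, *roles: ProfileRole) -> bool:
        present = self.roles()
        return any(r in present for r in roles)


@dataclass(frozen=True)
class AnnotationRecord:
    """One genomic TE copy (post-defragmentation)."""

    contig: str
    start: int
    end: int
    strand: str
    consensus_id: str
    order: Order = Order.UNCLASSIFIED

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("annotation start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (book-ended intervals are merged)."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def covered_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
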