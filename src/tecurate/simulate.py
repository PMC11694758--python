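"""Synthetic genomes, TE families and degraded raw libraries.

The generator plants known TE families (with terminal repeats, poly(A)
tails and back-translated coding-domain motifs) into a uniform-composition
background genome, records every insertion in a truth table, and emits a
degraded "raw library" exhibiting the pathologies a curation pipeline must
fix: redundant near-duplicates, central fragments, SSR decoys, host-gene
decoys, single-copy decoys, blanked classifications and chimeric
concatenations.  All outputs are bit-reproducible under a fixed seed.

The default mutation model is substitution-only (transitions:transversions
2:1); an indel rate option exists for stress tests but is off by default so
that oracle alignments stay unambiguous.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import (
    ConsensusRecord,
    LibraryDocument,
    Order,
    ProfileRole,
    TEClassification,
)
from .profiles import (
    Profile,
    back_translate,
    builtin_te_profiles,
    make_decoy_profiles,
    role_peptide,
)
from .search import revcomp

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class FamilySpec:
    """Blueprint of one synthetic TE family."""

    family_id: str
    order: Order
    length: int
    ltr_length: int = 0
    tir_length: int = 0
    has_polya: bool = False
    planted_domains: tuple[ProfileRole, ...] = ()
    gc_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.order is Order.LTR and self.ltr_length < 100:
            raise ValueError("LTR families need ltr_length >= 100")
        if self.order in (Order.TIR, Order.MITE) and self.tir_length < 10:
            raise ValueError("TIR/MITE families need tir_length >= 10")
        if self.order is Order.LTR and self.tir_length:
            raise ValueError("LTR family cannot carry a TIR length")
        if self.order in (Order.TIR, Order.MITE) and self.ltr_length:
            raise ValueError("TIR/MITE family cannot carry an LTR length")


@dataclass(frozen=True)
class Insertion:
    family_id: str
    contig: str
    start: int
    end: int
    strand: str
    divergence: float
    completeness: float


@dataclass
class TruthTable:
    insertions: list[Insertion] = field(default_factory=list)

    def for_family(self, family_id: str) -> list[Insertion]:
        return [i for i in self.insertions if i.family_id == family_id]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["family_id", "contig", "start", "end", "strand", "divergence", "completeness"]
            )
            for ins in self.insertions:
                writer.writerow(
                    [ins.family_id, ins.contig, ins.start, ins.end, ins.strand,
                     f"{ins.divergence:.4f}", f"{ins.completeness:.4f}"]
                )
        return path


@dataclass(frozen=True)
class DegradationSpec:
    """How to corrupt a perfect library into a raw one."""

    redundancy_factor: int = 1
    fragment_fraction: float = 0.0
    fragment_window: float = 0.5
    ssr_decoy_count: int = 0
    gene_decoy_count: int = 0
    singleton_decoy_count: int = 0
    unlabel_fraction: float = 0.0
    chimera_count: int = 0

    def __post_init__(self) -> None:
        for name in ("fragment_fraction", "fragment_window", "unlabel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def make_family(spec: FamilySpec, seed: int) -> str:
    """Deterministic ancestral consensus with the requested structure."""
    rng = np.random.default_rng(seed)
    # each family carries its own diverged variant of the domain consensus:
    # domains are conserved at the protein level across families, not
    # identical at the nucleotide level
    domain_seq = mutate(
        "".join(
            back_translate(role_peptide(role.value)) for role in spec.planted_domains
        ),
        0.15,
        rng,
    )
    reserved = 2 * spec.ltr_length + 2 * spec.tir_length + len(domain_seq)
    if spec.has_polya:
        reserved += 15
    internal_len = spec.length - reserved
    if internal_len < 0:
        raise ValueError(
            f"family {spec.family_id}: structural features exceed length {spec.length}"
        )
    internal = random_dna(rng, internal_len, spec.gc_fraction)
    # coding domains sit at the start of the internal region
    body = domain_seq + internal
    parts = []
    if spec.ltr_length:
        ltr = random_dna(rng, spec.ltr_length, spec.gc_fraction)
        parts = [ltr, body, ltr]
    elif spec.tir_length:
        tir = random_dna(rng, spec.tir_length, spec.gc_fraction)
        parts = [tir, body, revcomp(tir)]
    else:
        parts = [body]
    if spec.has_polya:
        parts.append("A" * 15)
    return "".join(parts)


def mutate(
    seq: str,
    divergence: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> str:
    """Per-site substitutions at the given divergence, ts:tv = 2:1."""
    chars = list(seq)
    n_sub = rng.binomial(len(chars), divergence)
    sites = rng.choice(len(chars), size=n_sub, replace=False)
    for s in sites:
        base = chars[s]
        if base not in _TRANSITION:
            continue
        if rng.random() < 2.0 / 3.0:
            chars[s] = _TRANSITION[base]
        else:
            chars[s] = _TRANSVERSIONS[base][rng.integers(0, 2)]
    if indel_rate > 0:
        out = []
        for ch in chars:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(ch)
            if r > 1 - indel_rate / 2:
                out.append("ACGT"[rng.integers(0, 4)])
        chars = out
    return "".join(chars)


def _truncate(
    seq: str, rng: np.random.Generator, prob: float, min_completeness: float
) -> tuple[str, float]:
    if prob <= 0 or rng.random() >= prob:
        return seq, 1.0
    completeness = float(rng.uniform(min_completeness, 1.0))
    keep = max(1, int(round(completeness * len(seq))))
    if rng.random() < 0.5:  # 5' truncation
        return seq[len(seq) - keep :], keep / len(seq)
    return seq[:keep], keep / len(seq)


def build_genome(
    families: dict[str, str],
    n_copies: dict[str, int],
    divergence: dict[str, float],
    background_bp: int,
    seed: int,
    truncation_prob: float = 0.0,
    truncation_min_completeness: float = 0.3,
    indel_rate: float = 0.0,
    contig_name: str = "chr1",
) -> tuple[dict[str, str], TruthTable]:
    """Insert mutated family copies into uniform random background."""
    rng = np.random.default_rng(seed)
    copies: list[tuple[str, str, float, float]] = []
    for fid in families:
        for _ in range(n_copies.get(fid, 0)):
            seq = mutate(families[fid], divergence.get(fid, 0.0), rng, indel_rate)
            seq, completeness = _truncate(
                seq, rng, truncation_prob, truncation_min_completeness
            )
            strand = "+" if rng.random() < 0.5 else "-"
            copies.append((fid, seq, divergence.get(fid, 0.0), completeness)
                          if strand == "+"
                          else (fid, revcomp(seq), divergence.get(fid, 0.0), -completeness))
    order = rng.permutation(len(copies))
    background = random_dna(rng, background_bp)
    cut_points = np.sort(rng.choice(background_bp, size=len(copies), replace=False))
    pieces = []
    truth = TruthTable()
    pos = 0
    genome_pos = 0
    for cut, idx in zip(cut_points, order):
        fid, seq, div, completeness = copies[idx]
        strand = "+" if completeness > 0 else "-"
        pieces.append(background[pos:cut])
        genome_pos += cut - pos
        truth.insertions.append(
            Insertion(
                family_id=fid,
                contig=contig_name,
                start=genome_pos,
                end=genome_pos + len(seq),
                strand=strand,
                divergence=div,
                completeness=abs(completeness),
            )
        )
        pieces.append(seq)
        genome_pos += len(seq)
        pos = cut
    pieces.append(background[pos:])
    return {contig_name: "".join(pieces)}, truth


def make_ssr_decoy(rng: np.random.Generator, length: int = 400) -> str:
    """A consensus dominated (>60%) by a short tandem repeat."""
    period = int(rng.integers(2, 6))
    unit = random_dna(rng, period)
    tract_len = int(length * 0.85)
    tract = (unit * (tract_len // period + 1))[:tract_len]
    pad = random_dna(rng, length - tract_len)
    return tract + pad


def make_gene_decoy(profile: Profile, rng: np.random.Generator) -> str:
    """A consensus that is mostly host-gene coding sequence."""
    coding = back_translate(profile.consensus)
    pad = random_dna(rng, max(20, len(coding) // 4))
    return coding + pad + coding  # two exon copies, >50% coding overall


def degrade_library(
    ancestors: list[ConsensusRecord],
    spec: DegradationSpec,
    seed: int,
    gene_profiles: list[Profile] | None = None,
) -> tuple[LibraryDocument, dict[str, str]]:
    """Emit a raw library with planted pathologies and its hidden truth map.

    The truth map assigns every raw record a tag: ``family:<id>``,
    ``redundant:<id>``, ``fragment:<id>``, ``ssr``, ``gene``, ``singleton``
    or ``chimera``.  Fragmentation is applied to family-derived records
    after duplication; decoys are appended; finally a fraction of records
    loses its classification.
    """
    rng = np.random.default_rng(seed)
    doc = LibraryDocument()
    truth: dict[str, str] = {}

    family_records: list[tuple[ConsensusRecord, str]] = []
    for anc in ancestors:
        family_records.append(
            (ConsensusRecord(anc.id, anc.sequence, anc.classification), f"family:{anc.id}")
        )
        for k in range(2, spec.redundancy_factor + 1):
            dup = mutate(anc.sequence, 0.03, rng)
            family_records.append(
                (
                    ConsensusRecord(f"{anc.id}_r{k}", dup, anc.classification),
                    f"redundant:{anc.id}",
                )
            )
    n_frag = int(round(spec.fragment_fraction * len(family_records)))
    frag_idx = set(rng.choice(len(family_records), size=n_frag, replace=False).tolist())
    for i, (rec, tag) in enumerate(family_records):
        if i in frag_idx:
            w = max(50, int(len(rec.sequence) * spec.fragment_window))
            start = (len(rec.sequence) - w) // 2
            rec.sequence = rec.sequence[start : start + w]
            tag = "fragment:" + tag.split(":", 1)[1]
        doc.records.append(rec)
        truth[rec.id] = tag

    for i in range(spec.ssr_decoy_count):
        rec = ConsensusRecord(f"ssr_decoy_{i + 1}", make_ssr_decoy(rng))
        doc.records.append(rec)
        truth[rec.id] = "ssr"
    gene_profiles = gene_profiles or []
    for i in range(spec.gene_decoy_count):
        profile = gene_profiles[i % len(gene_profiles)] if gene_profiles else None
        seq = (
            make_gene_decoy(profile, rng)
            if profile is not None
            else random_dna(rng, 600)
        )
        rec = ConsensusRecord(f"gene_decoy_{i + 1}", seq)
        doc.records.append(rec)
        truth[rec.id] = "gene"
    for i in range(spec.singleton_decoy_count):
        rec = ConsensusRecord(f"singleton_decoy_{i + 1}", random_dna(rng, 800))
        doc.records.append(rec)
        truth[rec.id] = "singleton"
    for i in range(spec.chimera_count):
        if len(ancestors) < 2:
            break
        a = ancestors[i % len(ancestors)]
        # chimeras join segments from two distinct orders
        partners = [
            x for x in ancestors
            if x.classification.order is not a.classification.order
        ]
        b = partners[i % len(partners)] if partners else ancestors[(i + 1) % len(ancestors)]
        rec = ConsensusRecord(f"chimera_{i + 1}", a.sequence + b.sequence, a.classification)
        doc.records.append(rec)
        truth[rec.id] = "chimera"

    n_unlabel = int(round(spec.unlabel_fraction * len(doc.records)))
    unlabel_idx = rng.choice(len(doc.records), size=n_unlabel, replace=False)
    for i in sorted(unlabel_idx.tolist()):
        doc.records[i].classification = TEClassification()
        doc.records[i].note("degrade", "classification blanked")
    return doc, truth


# ---------------------------------------------------------------------------
# the standard end-to-end scenario


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    truth: TruthTable
    raw_library: LibraryDocument
    library_truth: dict[str, str]
    ancestors: LibraryDocument
    family_specs: list[FamilySpec]
    gene_profiles: list[Profile]
    rrna_profiles: list[Profile]
    reference_db: LibraryDocument
    divergence: dict[str, float]
    n_copies: dict[str, int]


def default_family_specs() -> list[FamilySpec]:
    """Six families spanning the orders the curation rules distinguish."""
    return [
        FamilySpec("fam_ltr1", Order.LTR, 2000, ltr_length=300,
                   planted_domains=(ProfileRole.RT, ProfileRole.INT)),
        FamilySpec("fam_ltr2", Order.LTR, 1800, ltr_length=250,
                   planted_domains=(ProfileRole.RT, ProfileRole.INT)),
        FamilySpec("fam_tir1", Order.TIR, 1200, tir_length=30,
                   planted_domains=(ProfileRole.TRANSPOSASE,)),
        FamilySpec("fam_tir2", Order.TIR, 1000, tir_length=25,
                   planted_domains=(ProfileRole.TRANSPOSASE,)),
        FamilySpec("fam_line1", Order.LINE, 1800, has_polya=True,
                   planted_domains=(ProfileRole.RT, ProfileRole.EN)),
        FamilySpec("fam_mite1", Order.MITE, 500, tir_length=30),
    ]


_SUPERFAMILY = {
    "fam_ltr1": "Copia", "fam_ltr2": "Gypsy", "fam_tir1": "hAT",
    "fam_tir2": "Tc1-Mariner", "fam_line1": "L1", "fam_mite1": "",
}


def simulate_dataset(
    seed: int = 42,
    background_bp: int = 320_000,
    copy_range: tuple[int, int] = (15, 25),
    divergence_range: tuple[float, float] = (0.03, 0.08),
    degradation: DegradationSpec | None = None,
    reference_families: tuple[str, ...] = ("fam_ltr1", "fam_tir1"),
    truncation_prob: float = 0.3,
) -> SimulatedDataset:
    """The standard study conditions for end-to-end curation tests.

    Six families (2 LTR, 2 TIR, 1 LINE, 1 MITE) at 15-25 copies each and
    3-8% divergence in a uniform background; decoy families (SSR, host
    gene, single copy) are also planted so every false-positive filter sees
    genomic reality.  The reference database carries two of the six
    families plus unrelated classified entries, leaving the rest to the
    structural classification path.
    """
    rng = np.random.default_rng(seed)
    if degradation is None:
        degradation = DegradationSpec(
            redundancy_factor=3,
            fragment_fraction=0.4,
            fragment_window=0.5,
            ssr_decoy_count=3,
            gene_decoy_count=2,
            singleton_decoy_count=3,
            unlabel_fraction=0.3,
            chimera_count=1,
        )
    specs = default_family_specs()
    ancestors = LibraryDocument()
    sequences: dict[str, str] = {}
    for spec in specs:
        seq = make_family(spec, seed=int(rng.integers(0, 2**31 - 1)))
        sequences[spec.family_id] = seq
        ancestors.records.append(
            ConsensusRecord(
                spec.family_id,
                seq,
                TEClassification(
                    order=spec.order, superfamily=_SUPERFAMILY[spec.family_id]
                ),
            )
        )

    gene_profiles = make_decoy_profiles(ProfileRole.HOST_GENE, 3, seed=seed)
    rrna_profiles = make_decoy_profiles(ProfileRole.RRNA, 1, seed=seed)

    n_copies = {
        spec.family_id: int(rng.integers(copy_range[0], copy_range[1] + 1))
        for spec in specs
    }
    divergence = {
        spec.family_id: float(
            np.round(rng.uniform(divergence_range[0], divergence_range[1]), 3)
        )
        for spec in specs
    }

    # decoy families present in the genome: SSR and gene decoys are
    # multicopy (so they reach the filters that name them), singletons have
    # exactly one copy.
    decoy_seqs: dict[str, str] = {}
    drng = np.random.default_rng(seed + 1)
    for i in range(degradation.ssr_decoy_count):
        decoy_seqs[f"ssr_decoy_{i + 1}"] = make_ssr_decoy(drng)
    for i in range(degradation.gene_decoy_count):
        profile = gene_profiles[i % len(gene_profiles)]
        decoy_seqs[f"gene_decoy_{i + 1}"] = make_gene_decoy(profile, drng)
    for i in range(degradation.singleton_decoy_count):
        decoy_seqs[f"singleton_decoy_{i + 1}"] = random_dna(drng, 800)

    genome, truth = build_genome(
        sequences,
        n_copies,
        divergence,
        background_bp=background_bp,
        seed=seed + 2,
        truncation_prob=truncation_prob,
    )
    decoy_copies = {
        name: 1 if name.startswith("singleton") else 3 for name in decoy_seqs
    }
    decoy_genome, decoy_truth = build_genome(
        decoy_seqs,
        decoy_copies,
        {name: 0.01 for name in decoy_seqs},
        background_bp=max(20_000, background_bp // 10),
        seed=seed + 6,
        truncation_prob=0.0,  # decoy copies stay full length
        contig_name="chr2",
    )
    genome.update(decoy_genome)
    truth.insertions.extend(decoy_truth.insertions)

    # raw library: degrade the true families; decoys are re-generated with
    # the same rng stream used for the genome decoys so raw records match
    # the planted copies.
    raw, truth_map = degrade_library(
        [r for r in ancestors.records],
        DegradationSpec(
            redundancy_factor=degradation.redundancy_factor,
            fragment_fraction=degradation.fragment_fraction,
            fragment_window=degradation.fragment_window,
            unlabel_fraction=0.0,
            chimera_count=degradation.chimera_count,
        ),
        seed=seed + 3,
    )
    for name, seq in decoy_seqs.items():
        raw.records.append(ConsensusRecord(name, seq))
        truth_map[name] = (
            "ssr" if name.startswith("ssr")
            else "gene" if name.startswith("gene")
            else "singleton"
        )
    # blank a fraction of classifications across the whole raw library
    urng = np.random.default_rng(seed + 4)
    n_unlabel = int(round(degradation.unlabel_fraction * len(raw.records)))
    for i in sorted(urng.choice(len(raw.records), size=n_unlabel, replace=False).tolist()):
        raw.records[i].classification = TEClassification()
        raw.records[i].note("degrade", "classification blanked")

    # reference database: two true families plus unrelated classified entries
    ref = LibraryDocument()
    for fid in reference_families:
        ref.records.append(
            ConsensusRecord(
                f"ref_{fid}",
                sequences[fid],
                TEClassification(order=next(s.order for s in specs if s.family_id == fid),
                                 superfamily=_SUPERFAMILY[fid]),
            )
        )
    xrng = np.random.default_rng(seed + 5)
    for name, order, superfamily, length in [
        ("ref_copia_x", Order.LTR, "Copia", 1500),
        ("ref_gypsy_x", Order.LTR, "Gypsy", 1600),
        ("ref_hat_x", Order.TIR, "hAT", 900),
        ("ref_l1_x", Order.LINE, "L1", 1400),
        ("ref_helitron_x", Order.HELITRON, "Helitron", 1200),
    ]:
        ref.records.append(
            ConsensusRecord(
                name,
                random_dna(xrng, length),
                TEClassification(order=order, superfamily=superfamily),
            )
        )
    return SimulatedDataset(
        genome=genome,
        truth=truth,
        raw_library=raw,
        library_truth=truth_map,
        ancestors=ancestors,
        family_specs=specs,
        gene_profiles=gene_profiles,
        rrna_profiles=rrna_profiles,
        reference_db=ref,
        divergence=divergence,
        n_copies=n_copies,
    )
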