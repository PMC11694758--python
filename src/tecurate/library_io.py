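"""Reading, writing and preprocessing of TE consensus libraries.

Libraries are FASTA files whose headers carry a RepeatMasker-style
classification after a ``#``: ``name#Order/Superfamily``.  Wicker
three-letter codes (``RLC``, ``DTT``, ...) are accepted on input and mapped
through a bundled table.  Preprocessing normalizes label dialects
(``DNA`` -> ``TIR``, ``Unknown`` -> ``Unclassified``) and excludes labels
outside the nomenclature, satellites and RNAs, logging every exclusion.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from Bio import SeqIO

from .models import (
    ConsensusRecord,
    LibraryDocument,
    Order,
    RemovalReason,
    Status,
    TEClass,
    TEClassification,
)

_DNA = set("ACGTN")
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
_VALID = _DNA | _IUPAC_AMBIGUOUS


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("tecurate.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _nomenclature() -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Returns (order tokens, alias map, exclusion map), keys lower-cased."""
    orders: dict[str, str] = {}
    aliases: dict[str, str] = {}
    excludes: dict[str, str] = {}
    for row in _load_table("nomenclature.tsv"):
        token, kind = row[0], row[1]
        target = row[2] if len(row) > 2 else ""
        if kind == "order":
            orders[token.lower()] = target
        elif kind == "alias":
            aliases[token.lower()] = target
        elif kind == "exclude":
            excludes[token.lower()] = target
    return orders, aliases, excludes


def _wicker_codes() -> dict[str, tuple[str, str]]:
    out = {}
    for row in _load_table("wicker_codes.tsv"):
        code = row[0]
        order = row[1]
        superfamily = row[2] if len(row) > 2 else ""
        out[code.upper()] = (order, superfamily)
    return out


_ORDERS, _ALIASES, _EXCLUDES = _nomenclature()
_WICKER = _wicker_codes()


def _classification_from_token(order_token: str, superfamily: str) -> TEClassification | None:
    """Map a canonical order token (already in the nomenclature) if possible."""
    canon = _ORDERS.get(order_token.lower())
    if canon is None:
        return None
    if canon == "ClassI":
        return TEClassification(te_class=TEClass.CLASS_I)
    if canon == "ClassII":
        return TEClassification(te_class=TEClass.CLASS_II)
    order = Order(canon)
    if order is Order.UNCLASSIFIED:
        return TEClassification()
    return TEClassification(order=order, superfamily=superfamily)


def parse_label(label: str) -> TEClassification | None:
    """Parse the header part after '#'. None when not directly canonical."""
    label = label.strip()
    if not label:
        return TEClassification()
    if label.upper() in _WICKER:
        order_token, superfamily = _WICKER[label.upper()]
        cls = _classification_from_token(order_token, superfamily)
        if cls is not None:
            return TEClassification(
                order=cls.order, superfamily=cls.superfamily,
                wicker_code=label.upper(), te_class=cls.te_class,
            )
    order_token, _, superfamily = label.partition("/")
    return _classification_from_token(order_token.strip(), superfamily.strip())


def resolve_label(label: str) -> TEClassification:
    """Parse a classification label with alias normalization applied.

    Unlike :func:`parse_label` (which defers dialect handling so that
    preprocessing can log it), this resolves ``DNA`` -> ``TIR`` etc.
    directly; anything unresolvable comes back Unclassified.  Used for
    annotation inputs (BED names, RepeatMasker class/family columns).
    """
    cls = parse_label(label)
    if cls is not None:
        return cls
    order_token, _, superfamily = label.partition("/")
    token = order_token.strip().lower()
    if token in _ALIASES:
        mapped = _classification_from_token(_ALIASES[token], superfamily.strip())
        if mapped is not None:
            return mapped
    return TEClassification()


def clean_sequence(record_id: str, raw: str) -> tuple[str, int]:
    """Uppercase, map non-N IUPAC ambiguity codes to N; count conversions."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"record {record_id!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    n_converted = sum(seq.count(c) for c in _IUPAC_AMBIGUOUS)
    if n_converted:
        table = str.maketrans({c: "N" for c in _IUPAC_AMBIGUOUS})
        seq = seq.translate(table)
    return seq, n_converted


def parse_library(fasta_path: str | Path) -> LibraryDocument:
    """Read a raw TE library into a :class:`LibraryDocument`.

    Headers without a ``#`` yield Unclassified records.  Duplicate ids are
    disambiguated with a numeric suffix (``x``, ``x_2``, ...) and logged.
    Labels that are not directly canonical are stashed for
    :func:`normalize_nomenclature` to resolve or exclude.
    """
    fasta_path = Path(fasta_path)
    doc = LibraryDocument()
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        header = rec.description.split()[0] if rec.description else rec.id
        name, _, label = header.partition("#")
        seq, n_conv = clean_sequence(name, str(rec.seq))
        if not seq:
            raise ValueError(f"record {name!r} has an empty sequence")
        if name in seen:
            seen[name] += 1
            new_name = f"{name}_{seen[name]}"
            doc.exclusion_log.append((header, f"duplicate id renamed to {new_name}"))
            name = new_name
        else:
            seen[name] = 1
        classification = parse_label(label) if "#" in header else TEClassification()
        record = ConsensusRecord(
            id=name,
            sequence=seq,
            classification=classification if classification else TEClassification(),
        )
        if classification is None:
            # unresolved dialect label: defer to normalize_nomenclature
            record.note("parse", f"raw_label={label.strip()}")
            record.classification = TEClassification()
        if n_conv:
            record.note("parse", f"{n_conv} IUPAC ambiguity bases converted to N")
        doc.records.append(record)
    if not doc.records:
        raise ValueError("empty library")
    return doc


def _pending_label(record: ConsensusRecord) -> str | None:
    for stage, note in record.provenance:
        if stage == "parse" and note.startswith("raw_label="):
            return note[len("raw_label="):]
    return None


def normalize_nomenclature(doc: LibraryDocument) -> LibraryDocument:
    """Resolve label dialects in place; exclude out-of-nomenclature records.

    ``DNA`` orders become ``TIR`` and ``Unknown`` becomes ``Unclassified``;
    satellites/RNAs and labels outside the nomenclature are removed and
    logged.  Idempotent: resolved or removed records are left untouched.
    """
    for record in doc.records:
        if record.status is Status.REMOVED:
            continue
        label = _pending_label(record)
        if label is None:
            continue
        # already resolved on a previous pass?
        if any(s == "normalize" for s, _ in record.provenance):
            continue
        order_token, _, superfamily = label.partition("/")
        token = order_token.strip().lower()
        if token in _ALIASES:
            mapped = _ALIASES[token]
            cls = _classification_from_token(mapped, superfamily.strip())
            record.classification = cls if cls is not None else TEClassification()
            record.note("normalize", f"label {order_token!r} normalized to {mapped!r}")
        elif token in _EXCLUDES:
            reason = RemovalReason(_EXCLUDES[token])
            record.remove(reason, "normalize", f"excluded label {label!r}")
            doc.exclusion_log.append((record.header, reason.value))
        else:
            record.remove(
                RemovalReason.EXCLUDED_NOMENCLATURE,
                "normalize",
                f"label {label!r} not in nomenclature",
            )
            doc.exclusion_log.append(
                (f"{record.id}#{label}", RemovalReason.EXCLUDED_NOMENCLATURE.value)
            )
    return doc


def write_library(
    doc: LibraryDocument,
    path: str | Path,
    include_incomplete: bool = True,
    width: int = 80,
) -> Path:
    """Write kept records as FASTA with ``id#Order/Superfamily`` headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for record in doc.records:
            if not record.is_kept():
                continue
            if record.status is Status.INCOMPLETE and not include_incomplete:
                continue
            fh.write(f">{record.header}\n")
            seq = record.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_exclusion_log(doc: LibraryDocument, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["original_header", "reason"])
        for header, reason in doc.exclusion_log:
            writer.writerow([header, reason])
    return path


def read_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a genome assembly as {contig: uppercase sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no sequences in genome file {fasta_path}")
    return genome


def write_genome(genome: dict[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path
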