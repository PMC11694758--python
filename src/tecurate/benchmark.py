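"""Library- and annotation-level quality metrics.

Library level: family-quality labels (perfect / good / present / missing)
of a reference library against a test library, and chimera detection.
Annotation level: copy counts (total, short, overlapping), the NTE50/LTE50
annotation-contiguity metrics (the N50 analogue over TE copy lengths
against half the mobilome), and per-order genomic proportions.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .models import (
    AnnotationRecord,
    LibraryDocument,
    Order,
    covered_length,
)
from .search import local_search, merged_coverage


# ---------------------------------------------------------------------------
# family quality evaluation


@dataclass
class FamilyQualityLabel:
    reference_id: str
    label: str  # perfect | good | present | missing
    best_identity: float = 0.0
    merged_coverage: float = 0.0
    n_matching_sequences: int = 0


def evaluate_family_quality(
    reference_lib: LibraryDocument,
    test_lib: LibraryDocument,
    max_evalue: float = 1e-5,
) -> list[FamilyQualityLabel]:
    """Label each reference family by how well the test library captures it.

    perfect: a single test sequence matches with >95% identity and >95%
    coverage of the reference; good: several test sequences jointly reach
    those thresholds; present: the same at >80%/>80%; else missing.  A
    single dominant >95%/95% match wins over additional minor hits.
    """
    subjects = {r.id: r.sequence for r in test_lib.kept()}
    labels: list[FamilyQualityLabel] = []
    for ref in reference_lib.kept():
        if not subjects:
            labels.append(FamilyQualityLabel(ref.id, "missing"))
            continue
        hits = local_search(ref.sequence, subjects, max_evalue=max_evalue)
        label = FamilyQualityLabel(ref.id, "missing")
        for min_ident, cov_thr in ((0.95, 0.95), (0.80, 0.80)):
            qual = [h for h in hits if h.identity > min_ident]
            if not qual:
                continue
            cov = merged_coverage(qual, len(ref.sequence), on="query")
            if cov <= cov_thr:
                continue
            per_subject: dict[str, list] = {}
            for h in qual:
                per_subject.setdefault(h.subject_id, []).append(h)
            dominant = any(
                merged_coverage(hs, len(ref.sequence), on="query") > cov_thr
                for hs in per_subject.values()
            )
            n = len(per_subject)
            best_ident = max(
                sum(h.identity * h.aln_length for h in hs)
                / sum(h.aln_length for h in hs)
                for hs in per_subject.values()
            )
            if min_ident == 0.95:
                label = FamilyQualityLabel(
                    ref.id,
                    "perfect" if dominant else "good",
                    best_identity=best_ident,
                    merged_coverage=cov,
                    n_matching_sequences=1 if dominant else n,
                )
            else:
                label = FamilyQualityLabel(
                    ref.id,
                    "present",
                    best_identity=best_ident,
                    merged_coverage=cov,
                    n_matching_sequences=n,
                )
            break
        labels.append(label)
    return labels


def quality_summary(labels: list[FamilyQualityLabel]) -> dict[str, int]:
    out = {"perfect": 0, "good": 0, "present": 0, "missing": 0}
    for lab in labels:
        out[lab.label] += 1
    return out


# ---------------------------------------------------------------------------
# chimera detection


def detect_chimeras(
    library: LibraryDocument,
    reference_db: LibraryDocument,
    min_identity: float = 0.80,
    min_subject_coverage: float = 0.50,
    max_evalue: float = 1e-5,
) -> list[tuple[str, set[Order]]]:
    """Records hitting reference consensus of two or more distinct orders.

    A qualifying hit set has identity > ``min_identity`` and merged
    coverage > ``min_subject_coverage`` of the reference (subject)
    sequence.
    """
    subjects = {r.id: r.sequence for r in reference_db.kept()}
    orders = {r.id: r.classification.order for r in reference_db.kept()}
    lengths = {r.id: len(r.sequence) for r in reference_db.kept()}
    out = []
    for rec in library.kept():
        hits = local_search(rec.sequence, subjects, max_evalue=max_evalue)
        per_subject: dict[str, list] = {}
        for h in hits:
            if h.identity > min_identity:
                per_subject.setdefault(h.subject_id, []).append(h)
        hit_orders = set()
        for subject_id, hs in per_subject.items():
            cov = merged_coverage(hs, lengths[subject_id], on="subject")
            if cov > min_subject_coverage:
                order = orders[subject_id]
                if order is not Order.UNCLASSIFIED:
                    hit_orders.add(order)
        if len(hit_orders) >= 2:
            out.append((rec.id, hit_orders))
    return out


# ---------------------------------------------------------------------------
# annotation metrics


@dataclass
class MobilomeMetrics:
    total_copies: int = 0
    short_copies: int = 0
    overlapping_copies: int = 0
    nte50: int | None = None
    lte50: int | None = None
    order_proportions: dict[str, float] = field(default_factory=dict)
    mobilome_target_bp: int = 0

    def to_dict(self) -> dict:
        return {
            "total_copies": self.total_copies,
            "short_copies": self.short_copies,
            "overlapping_copies": self.overlapping_copies,
            "nte50": self.nte50,
            "lte50": self.lte50,
            "order_proportions": self.order_proportions,
            "mobilome_target_bp": self.mobilome_target_bp,
        }


def compute_nte_lte(
    annotations: list[AnnotationRecord], mobilome_target_bp: int
) -> tuple[int | None, int | None]:
    """NTE50/LTE50: copies sorted longest-first are accumulated until the
    cumulative length reaches the target (50% of the mobilome); NTE50 is
    how many copies that takes and LTE50 the length of the last one.
    Undefined (None, None) when the total annotated length falls short.
    """
    if mobilome_target_bp <= 0:
        raise ValueError("mobilome_target_bp must be positive")
    if not annotations:
        raise ValueError("no annotations")
    lengths = sorted((a.length for a in annotations), reverse=True)
    cum = 0
    for n, length in enumerate(lengths, start=1):
        cum += length
        if cum >= mobilome_target_bp:
            return n, length
    return None, None


def count_copies(
    annotations: list[AnnotationRecord], short_threshold: int = 100
) -> tuple[int, int]:
    """(total copies, copies shorter than ``short_threshold`` bp)."""
    total = len(annotations)
    short = sum(1 for a in annotations if a.length < short_threshold)
    return total, short


def count_overlapping(annotations: list[AnnotationRecord]) -> int:
    """Merged genomic regions annotated by two or more distinct consensus.

    Only strict overlaps merge (shared bp >= 1; book-ended copies stay
    separate, the bedtools merge -d -1 convention).
    """
    by_contig: dict[str, list[AnnotationRecord]] = {}
    for a in annotations:
        by_contig.setdefault(a.contig, []).append(a)
    n = 0
    for contig in sorted(by_contig):
        anns = sorted(by_contig[contig], key=lambda a: (a.start, a.end))
        cur_end = None
        cur_ids: set[str] = set()
        for a in anns:
            if cur_end is not None and a.start < cur_end:
                cur_end = max(cur_end, a.end)
                cur_ids.add(a.consensus_id)
            else:
                if cur_end is not None and len(cur_ids) >= 2:
                    n += 1
                cur_end = a.end
                cur_ids = {a.consensus_id}
        if cur_end is not None and len(cur_ids) >= 2:
            n += 1
    return n


def order_proportions(
    annotations: list[AnnotationRecord], genome_bp: int
) -> dict[str, float]:
    """Fraction of the genome annotated per order (within-order interval
    union, so overlapping same-order copies count once)."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    per_order: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for a in annotations:
        per_order.setdefault(a.order.value, {}).setdefault(a.contig, []).append(
            (a.start, a.end)
        )
    out = {}
    for order, contigs in sorted(per_order.items()):
        bp = sum(covered_length(iv) for iv in contigs.values())
        out[order] = bp / genome_bp
    return out


def compute_metrics(
    annotations: list[AnnotationRecord],
    genome_bp: int,
    mobilome_target_bp: int | None = None,
    short_threshold: int = 100,
) -> MobilomeMetrics:
    """All annotation metrics in one pass; the default target is half the
    annotated (mobilome) length."""
    total, short = count_copies(annotations, short_threshold)
    metrics = MobilomeMetrics(
        total_copies=total,
        short_copies=short,
        overlapping_copies=count_overlapping(annotations),
        order_proportions=order_proportions(annotations, genome_bp)
        if annotations
        else {},
    )
    if annotations:
        if mobilome_target_bp is None:
            mobilome_target_bp = int(math.ceil(sum(a.length for a in annotations) / 2))
        metrics.mobilome_target_bp = mobilome_target_bp
        metrics.nte50, metrics.lte50 = compute_nte_lte(annotations, mobilome_target_bp)
    return metrics


# ---------------------------------------------------------------------------
# annotation input formats


def _order_from_label(label: str) -> Order:
    from .library_io import resolve_label  # deferred: avoid import cycle

    return resolve_label(label).order


def read_bed(path: str | Path) -> list[AnnotationRecord]:
    """BED (0-based half-open); the name column may carry ``id#Order``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "+"
            cons_id, _, label = name.partition("#")
            out.append(
                AnnotationRecord(
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-" else "+",
                    consensus_id=cons_id,
                    order=_order_from_label(label) if label else Order.UNCLASSIFIED,
                )
            )
    return out


def read_repeatmasker_out(path: str | Path) -> list[AnnotationRecord]:
    """RepeatMasker ``.out`` (1-based inclusive; converted on read)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i < 3 or not line.strip():  # header block
                continue
            f = line.split()
            if len(f) < 11:
                continue
            contig, start, end = f[4], int(f[5]) - 1, int(f[6])
            strand = "-" if f[8] in ("C", "-") else "+"
            name, family = f[9], f[10]
            rows.append(
                AnnotationRecord(
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    consensus_id=name,
                    order=_order_from_label(family),
                )
            )
    return rows


def write_metrics_json(metrics: MobilomeMetrics, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_family_labels(
    labels: list[FamilyQualityLabel], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["reference_id", "label", "best_identity", "merged_coverage", "n_matching"]
        )
        for lab in labels:
            writer.writerow(
                [
                    lab.reference_id,
                    lab.label,
                    f"{lab.best_identity:.4f}",
                    f"{lab.merged_coverage:.4f}",
                    lab.n_matching_sequences,
                ]
            )
    return path
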