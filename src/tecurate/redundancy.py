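"""Greedy incremental clustering for library redundancy reduction.

Mirrors CD-HIT-EST-style behaviour at the thresholds used for TE library
curation (95% identity, 98% coverage of the shorter sequence): sequences
are sorted longest-first and each joins the first existing cluster whose
representative it matches at the thresholds, else founds its own cluster.
The longest member (ties: lexicographically smallest id) represents each
cluster, so exact fragments and near-duplicates are absorbed into their
parent consensus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .models import ConsensusRecord, LibraryDocument, RemovalReason
from .search import local_search, merged_coverage, weighted_identity


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    pairwise_stats: list[tuple[str, float, float]] = field(default_factory=list)


def pairwise_identity_coverage(
    seq_a: str, seq_b: str, max_evalue: float = 1e-5
) -> tuple[float, float]:
    """(identity, coverage of the shorter) between two sequences.

    The shorter sequence is searched against the longer; identity is the
    length-weighted mean over its hits and coverage is the merged hit span
    on the shorter sequence.
    """
    shorter, longer = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    hits = local_search(shorter, {"rep": longer}, max_evalue=max_evalue)
    if not hits:
        return 0.0, 0.0
    return weighted_identity(hits), merged_coverage(hits, len(shorter), on="query")


def cluster_library(
    records: list[ConsensusRecord],
    identity_threshold: float = 0.95,
    coverage_threshold: float = 0.98,
) -> list[Cluster]:
    """Greedy first-fit clustering, longest sequences first.

    Deterministic: input order does not matter beyond the
    (length descending, id ascending) sort.
    """
    if not records:
        raise ValueError("cannot cluster an empty record set")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[Cluster] = []
    reps: dict[str, ConsensusRecord] = {}
    for rec in ordered:
        placed = False
        for cluster in clusters:
            rep = reps[cluster.representative_id]
            ident, cov = pairwise_identity_coverage(rec.sequence, rep.sequence)
            if ident >= identity_threshold and cov >= coverage_threshold:
                cluster.member_ids.append(rec.id)
                cluster.pairwise_stats.append((rec.id, ident, cov))
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    representative_id=rec.id,
                    member_ids=[rec.id],
                    pairwise_stats=[(rec.id, 1.0, 1.0)],
                )
            )
            reps[rec.id] = rec
    return clusters


def select_representatives(
    clusters: list[Cluster], doc: LibraryDocument
) -> LibraryDocument:
    """Mark non-representative members as removed (reason: redundant)."""
    by_id = {r.id: r for r in doc.records}
    for cluster in clusters:
        for member_id in cluster.member_ids:
            if member_id == cluster.representative_id:
                by_id[member_id].note(
                    "redundancy",
                    f"representative of cluster ({len(cluster.member_ids)} members)",
                )
                continue
            by_id[member_id].remove(
                RemovalReason.REDUNDANT,
                "redundancy",
                f"redundant with representative {cluster.representative_id}",
            )
    return doc


def write_cluster_table(clusters: list[Cluster], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["representative", "member", "identity", "coverage_of_shorter"])
        for cluster in clusters:
            for member_id, ident, cov in cluster.pairwise_stats:
                writer.writerow(
                    [cluster.representative_id, member_id, f"{ident:.4f}", f"{cov:.4f}"]
                )
    return path
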