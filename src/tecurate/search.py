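"""Nucleotide local-similarity search used throughout the pipeline.

A seed-and-extend search (exact k-mer seeds on both strands, ungapped
X-drop extension, match +1 / mismatch -2) with Karlin-Altschul e-values.
This is the workhorse behind copy collection, redundancy statistics,
homology classification and the benchmarking metrics.  Coordinates follow
the 0-based half-open convention with subject positions always on the
forward strand; a ``-`` hit means the reverse complement of the query
matches the subject forward strand.

The statistical model is the ungapped Karlin-Altschul approximation with
lambda = 1.33 and K = 0.621 for the +1/-2 scoring scheme; since every
stage filters on a fixed e-value cutoff, any calibrated monotone
score-to-e-value map yields the same filtering behaviour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import AlignmentHit, covered_length, merge_intervals

LAMBDA = 1.33
K_PARAM = 0.621
MATCH = 1
MISMATCH = -2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class SubjectIndex:
    """Exact k-mer index over a set of subject sequences (built once)."""

    sequences: dict[str, str]
    k: int = 11
    _kmers: dict[str, dict[str, list[int]]] = field(default_factory=dict, repr=False)
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            table: dict[str, list[int]] = {}
            for i in range(len(seq) - self.k + 1):
                kmer = seq[i : i + self.k]
                if "N" in kmer:
                    continue
                table.setdefault(kmer, []).append(i)
            self._kmers[name] = table
            self._encoded[name] = _encode(seq)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def lookup(self, kmer: str, name: str) -> list[int]:
        return self._kmers[name].get(kmer, [])


def _xdrop_segment(
    q: np.ndarray, s: np.ndarray, diag: int, anchor: int, xdrop: int
) -> tuple[int, int, int, int]:
    """Best ungapped segment on a diagonal through ``anchor`` (query coords).

    Returns (q_start, q_end, score, n_matches).  ``diag`` is s_pos - q_pos.
    """
    lo = max(0, -diag)
    hi = min(len(q), len(s) - diag)
    if anchor < lo or anchor >= hi:
        return anchor, anchor, 0, 0
    window = q[lo:hi] == s[lo + diag : hi + diag]
    steps = np.where(window, MATCH, MISMATCH)
    a = anchor - lo
    # extend right from the anchor
    right = np.cumsum(steps[a:])
    run_max = np.maximum.accumulate(right)
    stop = np.nonzero(run_max - right > xdrop)[0]
    r_lim = stop[0] if stop.size else len(right)
    r_best = int(np.argmax(right[:r_lim])) if r_lim > 0 else -1
    # extend left from just before the anchor
    if a > 0:
        left = np.cumsum(steps[a - 1 :: -1])
        run_max = np.maximum.accumulate(left)
        stop = np.nonzero(run_max - left > xdrop)[0]
        l_lim = stop[0] if stop.size else len(left)
        l_best = int(np.argmax(left[:l_lim])) if l_lim > 0 else -1
        l_score = int(left[l_best]) if l_best >= 0 else 0
        l_off = l_best + 1 if l_best >= 0 and l_score > 0 else 0
    else:
        l_score, l_off = 0, 0
    r_score = int(right[r_best]) if r_best >= 0 else 0
    if r_score <= 0:
        return anchor, anchor, 0, 0
    q_start = lo + a - (l_off if l_score > 0 else 0)
    q_end = lo + a + r_best + 1
    score = r_score + (l_score if l_score > 0 else 0)
    n_match = int(np.count_nonzero(window[q_start - lo : q_end - lo]))
    return q_start, q_end, score, n_match


def evalue_from_score(score: float, query_len: int, subject_len: int) -> float:
    return K_PARAM * query_len * subject_len * math.exp(-LAMBDA * score)


def local_search(
    query: str,
    subjects: SubjectIndex | dict[str, str],
    max_evalue: float = 1e-10,
    query_id: str = "query",
    seed_size: int = 11,
    xdrop: int = 20,
) -> list[AlignmentHit]:
    """Seed-and-extend local search of ``query`` against the subjects.

    Hits are reported on both strands, sorted by score descending, all with
    e-value <= ``max_evalue``.  One best segment is reported per
    (subject, strand, diagonal band); ungapped extension is exact for the
    substitution-only divergence model the rest of the pipeline assumes.
    """
    if not isinstance(subjects, SubjectIndex):
        subjects = SubjectIndex(subjects, k=seed_size)
    if len(query) < seed_size:
        warnings.warn(
            f"query {query_id!r} shorter than seed size {seed_size}; no search done"
        )
        return []
    n_total = subjects.total_length
    hits: list[AlignmentHit] = []
    for strand in "+-":
        q_seq = query if strand == "+" else revcomp(query)
        q_arr = _encode(q_seq)
        q_kmers = [
            (i, q_seq[i : i + seed_size])
            for i in range(len(q_seq) - seed_size + 1)
        ]
        for name, subj_seq in subjects.sequences.items():
            s_arr = subjects._encoded[name]
            diag_seeds: dict[int, list[int]] = {}
            for i, kmer in q_kmers:
                if "N" in kmer:
                    continue
                for j in subjects.lookup(kmer, name):
                    diag_seeds.setdefault(j - i, []).append(i)
            done_spans: dict[int, list[tuple[int, int]]] = {}
            for diag in sorted(diag_seeds):
                for anchor in diag_seeds[diag]:
                    if any(a <= anchor < b for a, b in done_spans.get(diag, [])):
                        continue
                    q0, q1, score, n_match = _xdrop_segment(
                        q_arr, s_arr, diag, anchor, xdrop
                    )
                    if q1 <= q0 or score <= 0:
                        continue
                    done_spans.setdefault(diag, []).append((q0, q1))
                    ev = evalue_from_score(score, len(query), n_total)
                    if ev > max_evalue:
                        continue
                    aln_len = q1 - q0
                    s0, s1 = q0 + diag, q1 + diag
                    if strand == "+":
                        hq0, hq1 = q0, q1
                    else:  # map back to forward query coords
                        hq0, hq1 = len(query) - q1, len(query) - q0
                    hits.append(
                        AlignmentHit(
                            query_id=query_id,
                            subject_id=name,
                            identity=n_match / aln_len,
                            q_start=hq0,
                            q_end=hq1,
                            s_start=s0,
                            s_end=s1,
                            strand=strand,
                            aln_length=aln_len,
                            score=float(score),
                            evalue=ev,
                        )
                    )
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start, h.strand))
    return _dedup_hits(hits)


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose subject interval duplicates a better same-strand hit."""
    kept: list[AlignmentHit] = []
    for h in hits:
        dup = False
        for k in kept:
            if (
                k.subject_id == h.subject_id
                and k.strand == h.strand
                and max(h.s_start, k.s_start) < min(h.s_end, k.s_end)
                and max(h.q_start, k.q_start) < min(h.q_end, k.q_end)
            ):
                ov = min(h.s_end, k.s_end) - max(h.s_start, k.s_start)
                if ov >= 0.9 * (h.s_end - h.s_start):
                    dup = True
                    break
        if not dup:
            kept.append(h)
    return kept


def meets_rule(
    hits: AlignmentHit | list[AlignmentHit],
    min_len: int,
    min_identity: float,
    min_coverage: float,
    covered_seq_length: int,
    on: str = "query",
) -> bool:
    """The 80-80-80-style homology rule on one hit or a merged set of hits.

    True iff the longest hit is >= ``min_len`` bp, the length-weighted mean
    identity is >= ``min_identity``, and the merged hit span covers
    >= ``min_coverage`` of the sequence of length ``covered_seq_length``
    (query side by default, subject side with ``on='subject'``).
    The canonical instances are (80, 0.80, 0.80) and (70, 0.70, 0.70).
    """
    if covered_seq_length <= 0:
        raise ValueError("covered_seq_length must be positive")
    if isinstance(hits, AlignmentHit):
        hits = [hits]
    if not hits:
        return False
    if on == "query":
        intervals = [(h.q_start, h.q_end) for h in hits]
    else:
        intervals = [(h.s_start, h.s_end) for h in hits]
    span = covered_length(intervals)
    total = sum(h.aln_length for h in hits)
    mean_identity = sum(h.identity * h.aln_length for h in hits) / total
    longest = max(h.aln_length for h in hits)
    return (
        longest >= min_len
        and mean_identity >= min_identity
        and span / covered_seq_length >= min_coverage
    )


def merged_coverage(
    hits: list[AlignmentHit], covered_seq_length: int, on: str = "query"
) -> float:
    if not hits:
        return 0.0
    if on == "query":
        intervals = [(h.q_start, h.q_end) for h in hits]
    else:
        intervals = [(h.s_start, h.s_end) for h in hits]
    return covered_length(intervals) / covered_seq_length


def weighted_identity(hits: list[AlignmentHit]) -> float:
    if not hits:
        return 0.0
    total = sum(h.aln_length for h in hits)
    return sum(h.identity * h.aln_length for h in hits) / total


__all__ = [
    "SubjectIndex",
    "local_search",
    "meets_rule",
    "merged_coverage",
    "weighted_identity",
    "revcomp",
    "evalue_from_score",
    "merge_intervals",
]
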