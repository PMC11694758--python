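"""False-positive consensus removal.

Three checks, applied in order with the first failure recorded: genomic
support (full-length fragments, FLFs), homology to multicopy host genes or
rRNAs, and simple-sequence-repeat content.  A consensus supported by at
most ``min_flf`` full-length genomic copies (default one), or matching
gene/rRNA profiles over at least half its length, or composed of more than
``ssr_max`` (default 60%) simple repeats, is filtered out.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import (
    DomainHit,
    LibraryDocument,
    RemovalReason,
    covered_length,
)
from .extension import Locus, collect_copies
from .profiles import Profile, domain_nt_intervals, profile_search
from .search import SubjectIndex


@dataclass
class FalsePositiveEvidence:
    flf_count: int
    ssr_fraction: float
    gene_hits: list[DomainHit] = field(default_factory=list)
    rrna_hits: list[DomainHit] = field(default_factory=list)
    verdict: str = "keep"  # keep | few_flf | gene_or_rrna | ssr


def count_flf(
    consensus: str, loci: list[Locus], flf_coverage: float = 0.94
) -> int:
    """Full-length fragments: loci covering >= ``flf_coverage`` of the
    consensus (the merged alignment span of the locus's hits on the query).
    """
    n = 0
    for locus in loci:
        span = covered_length([(h.q_start, h.q_end) for h in locus.hits])
        if span / len(consensus) >= flf_coverage:
            n += 1
    return n


def ssr_tracts(
    sequence: str,
    max_period: int = 6,
    min_tract: int = 12,
    min_identity: float = 0.8,
    xdrop: int = 12,
) -> list[tuple[int, int]]:
    """Maximal simple-repeat tracts, merged across periods.

    For each period p a tract grows along a +1 match / -2 mismatch score
    walk over ``seq[i] == seq[i-p]`` and ends at its score maximum (X-drop
    12), so it cannot leak into flanking non-repetitive sequence; tracts
    shorter than ``min_tract`` or below ``min_identity`` self-matches are
    ignored.
    """
    n = len(sequence)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    tracts: list[tuple[int, int]] = []
    for p in range(1, max_period + 1):
        if n < min_tract or n <= p:
            continue
        match = arr[p:] == arr[:-p]  # position i+p repeats position i
        steps = np.where(match, 1, -2)
        i = 0
        m = len(match)
        while i < m:
            if not match[i]:
                i += 1
                continue
            score = 0
            best_score, best_j = 0, i - 1
            j = i
            while j < m:
                score += steps[j]
                if score > best_score:
                    best_score, best_j = score, j
                if best_score - score > xdrop:
                    break
                j += 1
            end = best_j + 1 + p  # repeat of position best_j lands at +p
            length = end - i
            ident = np.count_nonzero(match[i : best_j + 1]) / max(1, best_j + 1 - i)
            if length >= min_tract and ident >= min_identity:
                tracts.append((i, end))
            i = max(best_j + 1, i + 1)
    # merge overlapping tracts from all periods
    merged: list[tuple[int, int]] = []
    for s, e in sorted(tracts):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def ssr_fraction(sequence: str, max_period: int = 6, min_tract: int = 12) -> float:
    """Fraction of the sequence inside simple-repeat tracts."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(e - s for s, e in ssr_tracts(sequence, max_period, min_tract)) / len(
        sequence
    )


def evaluate_false_positive(
    consensus: str,
    loci: list[Locus],
    gene_profiles: list[Profile],
    rrna_profiles: list[Profile],
    min_flf: int = 1,
    ssr_max: float = 0.60,
    flf_coverage: float = 0.94,
    profile_evalue: float = 10.0,
    gene_cov_min: float = 0.5,
) -> FalsePositiveEvidence:
    """Run the three checks in order (FLF, gene/rRNA, SSR)."""
    flf = count_flf(consensus, loci, flf_coverage)
    ssr = ssr_fraction(consensus)
    ev = FalsePositiveEvidence(flf_count=flf, ssr_fraction=ssr)
    if flf <= min_flf:
        ev.verdict = "few_flf"
        return ev
    profiles = list(gene_profiles) + list(rrna_profiles)
    if profiles:
        hits = profile_search(consensus, profiles, max_evalue=profile_evalue)
        gene_names = {p.name for p in gene_profiles}
        ev.gene_hits = [h for h in hits if h.profile_name in gene_names]
        ev.rrna_hits = [h for h in hits if h.profile_name not in gene_names]
        span = covered_length(domain_nt_intervals(hits, len(consensus)))
        if hits and span / len(consensus) >= gene_cov_min:
            ev.verdict = "gene_or_rrna"
            return ev
    if ssr > ssr_max:
        ev.verdict = "ssr"
        return ev
    ev.verdict = "keep"
    return ev


_VERDICT_REASON = {
    "few_flf": RemovalReason.FEW_FLF,
    "gene_or_rrna": RemovalReason.GENE_OR_RRNA,
    "ssr": RemovalReason.SSR,
}


def filter_false_positives(
    doc: LibraryDocument,
    genome: SubjectIndex,
    gene_profiles: list[Profile],
    rrna_profiles: list[Profile],
    min_flf: int = 1,
    ssr_max: float = 0.60,
    flf_coverage: float = 0.94,
    profile_evalue: float = 10.0,
    copy_evalue: float = 1e-20,
    report_path: str | Path | None = None,
) -> LibraryDocument:
    """Remove false-positive consensus sequences from the kept records."""
    if not gene_profiles and not rrna_profiles:
        warnings.warn("no gene/rRNA profiles supplied; homology check skipped")
    rows = []
    for record in doc.kept():
        loci = collect_copies(record.sequence, genome, max_evalue=copy_evalue)
        ev = evaluate_false_positive(
            record.sequence,
            loci,
            gene_profiles,
            rrna_profiles,
            min_flf=min_flf,
            ssr_max=ssr_max,
            flf_coverage=flf_coverage,
            profile_evalue=profile_evalue,
        )
        if ev.verdict != "keep":
            record.remove(
                _VERDICT_REASON[ev.verdict],
                "false_positive_filter",
                f"flf={ev.flf_count} ssr={ev.ssr_fraction:.2f} verdict={ev.verdict}",
            )
        rows.append(
            (
                record.id,
                ev.flf_count,
                f"{ev.ssr_fraction:.4f}",
                len(ev.gene_hits),
                len(ev.rrna_hits),
                ev.verdict,
            )
        )
    if report_path is not None:
        with open(report_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "flf_count", "ssr_fraction", "gene_hits", "rrna_hits", "verdict"])
            writer.writerows(rows)
    return doc
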