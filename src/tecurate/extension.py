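"""Iterative consensus extension to true element boundaries.

Each round (a BEE round: collect genomic copies, extract them with flanks,
re-align, re-polish) grows the consensus by up to ``flank_bp`` per side
until both element ends are reached or the iteration budget runs out.

The multiple alignment is anchored on the current consensus (center-star:
each copy's matching segment is pairwise-aligned to the consensus and its
gaps projected onto consensus columns).  Newly added flank sequence is
placed only where it is supported by agreement between copies: flanks are
compared outward from the core boundary and each contributes characters up
to its supported extent, so sequence beyond the true element end - which
differs between insertion sites - collapses to gap columns.  Edge
detection is then a simple depth statistic on the outermost flank columns.

Families are split into subfamilies when average-linkage clustering of the
aligned copies on Kimura 2-parameter distances separates two or more
well-populated groups.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .models import AlignmentHit
from .search import SubjectIndex, local_search, revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class Locus:
    """One genomic copy: merged collinear hits at a single insertion site."""

    contig: str
    strand: str
    s_start: int
    s_end: int
    q_start: int
    q_end: int
    score: float
    hits: list[AlignmentHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.s_end - self.s_start


@dataclass
class MSAProfile:
    """A gapped alignment of genomic copies around the current consensus.

    Columns are split into a left flank block, the core (consensus-anchored)
    block and a right flank block; flank characters appear only where a
    copy's flank is supported by agreement with the other copies.
    """

    member_windows: list[tuple[str, int, int, str]]
    aligned_rows: list[str]
    flank_left: int = 0
    flank_right: int = 0

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.aligned_rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows must all have the same length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_rows[0]) if self.aligned_rows else 0

    @property
    def column_depth(self) -> np.ndarray:
        if not self.aligned_rows:
            return np.zeros(0, dtype=int)
        arr = np.array([list(r) for r in self.aligned_rows])
        return np.count_nonzero(arr != "-", axis=0)

    def core_slice(self) -> slice:
        return slice(self.flank_left, self.n_columns - self.flank_right)

    def subset(self, row_indices: list[int]) -> "MSAProfile":
        return MSAProfile(
            member_windows=[self.member_windows[i] for i in row_indices],
            aligned_rows=[self.aligned_rows[i] for i in row_indices],
            flank_left=self.flank_left,
            flank_right=self.flank_right,
        )


@dataclass
class ExtensionState:
    consensus: str
    left_done: bool = False
    right_done: bool = False
    iteration: int = 0
    history: list[tuple[int, int, bool, bool]] = field(default_factory=list)
    msa: MSAProfile | None = None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# copy collection


def collect_copies(
    consensus: str,
    genome: SubjectIndex,
    max_evalue: float = 1e-20,
    max_copies: int = 40,
    locus_gap: int = 50,
    min_identity: float = 0.80,
) -> list[Locus]:
    """Genomic loci of a consensus: e-value-filtered hits merged per site.

    Hits below ``min_identity`` are discarded: a genuine family copy
    aligns far above that floor, while conserved segments shared with
    other families (e.g. coding domains) fall below it and must not enter
    the copy set.  Collinear hits closer than ``locus_gap`` bp on the same
    contig/strand are one locus when their query spans are essentially
    disjoint (split fragments of one copy); hits re-covering the same
    query span (tandem copies) stay separate.  The best-scoring
    ``max_copies`` loci are kept.
    """
    hits = [
        h
        for h in local_search(consensus, genome, max_evalue=max_evalue)
        if h.identity >= min_identity
    ]
    # internal repeats (e.g. the two LTRs of one element) produce extra hits
    # nested inside the span of the full-copy hit; they are not independent
    # loci, so drop hits subject-contained in a higher-scoring hit.
    hits = [
        h
        for h in hits
        if not any(
            o is not h
            and o.subject_id == h.subject_id
            and o.score >= h.score
            and (min(h.s_end, o.s_end) - max(h.s_start, o.s_start))
            >= 0.8 * (h.s_end - h.s_start)
            and (h.s_end - h.s_start) < (o.s_end - o.s_start)
            for o in hits
        )
    ]
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.strand), []).append(h)
    loci: list[Locus] = []
    for (contig, strand), hs in sorted(groups.items()):
        hs.sort(key=lambda h: h.s_start)
        current: Locus | None = None
        for h in hs:
            if current is not None and h.s_start - current.s_end < locus_gap:
                q_ov = min(h.q_end, current.q_end) - max(h.q_start, current.q_start)
                shorter = min(h.q_end - h.q_start, current.q_end - current.q_start)
                if q_ov < 0.5 * shorter:
                    current.s_end = max(current.s_end, h.s_end)
                    current.q_start = min(current.q_start, h.q_start)
                    current.q_end = max(current.q_end, h.q_end)
                    current.score += h.score
                    current.hits.append(h)
                    continue
            current = Locus(
                contig=contig,
                strand=strand,
                s_start=h.s_start,
                s_end=h.s_end,
                q_start=h.q_start,
                q_end=h.q_end,
                score=h.score,
                hits=[h],
            )
            loci.append(current)
    loci.sort(key=lambda l: (-l.score, l.contig, l.s_start))
    return loci[:max_copies]


# ---------------------------------------------------------------------------
# anchored multiple alignment


def _align_core(segment: str, consensus_sub: str) -> tuple[list[str], dict[int, str]]:
    """Project ``segment`` onto the columns of ``consensus_sub``.

    Returns (per-column characters, insertions keyed by following column).
    """
    res = edlib.align(segment, consensus_sub, mode="NW", task="path")
    cols: list[str] = []
    inserts: dict[int, str] = {}
    qi = 0
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(count)
        if op in "=XM":
            cols.extend(segment[qi : qi + n])
            qi += n
        elif op == "D":  # gap in segment relative to consensus
            cols.extend("-" * n)
        elif op == "I":  # extra segment bases between consensus columns
            inserts[len(cols)] = inserts.get(len(cols), "") + segment[qi : qi + n]
            qi += n
    return cols, inserts


def _flank_pair_extent(a: np.ndarray, b: np.ndarray, min_score: int = 10) -> int:
    """Supported extent of two flanks anchored at index 0 (+1/-1 walk)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0
    steps = np.where(a[:n] == b[:n], 1, -1)
    cum = np.cumsum(steps)
    best = int(np.argmax(cum))
    return best + 1 if cum[best] >= min_score else 0


def _flank_block(
    flanks: list[str], side: str, min_extent: int = 20
) -> tuple[int, list[str]]:
    """Place flank sequences by mutual support.

    ``flanks`` are given in consensus orientation; the core-abutting end is
    the right end for ``side='left'`` and the left end for ``side='right'``.
    Each flank contributes characters out to its supported extent relative
    to the best-supported reference flank; unsupported flanks contribute
    only gaps.  Returns (block width, per-row strings of that width).
    """
    anchored = [
        np.frombuffer(
            (f[::-1] if side == "left" else f).encode("ascii"), dtype=np.uint8
        )
        for f in flanks
    ]
    n = len(anchored)
    if n < 2:
        return 0, ["" for _ in flanks]
    extents = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            e = _flank_pair_extent(anchored[i], anchored[j])
            extents[i, j] = extents[j, i] = e
    support = extents.sum(axis=1)
    ref = int(np.argmax(support))
    placed = [int(extents[i, ref]) for i in range(n)]
    placed[ref] = max((e for i, e in enumerate(placed) if i != ref), default=0)
    placed = [e if e >= min_extent else 0 for e in placed]
    width = max(placed, default=0)
    rows = []
    for f, e in zip(flanks, placed):
        if e == 0:
            rows.append("-" * width)
        elif side == "left":
            rows.append("-" * (width - e) + f[len(f) - e :])
        else:
            rows.append(f[:e] + "-" * (width - e))
    return width, rows


def build_msa(
    consensus: str,
    loci: list[Locus],
    genome: dict[str, str],
    flank_bp: int = 500,
    extend_left: bool = True,
    extend_right: bool = True,
    end_tolerance: int = 20,
    min_flank_locus_cov: float = 0.5,
) -> MSAProfile:
    """Anchored MSA of the copies with supported flank columns.

    Only loci that reach a consensus end (within ``end_tolerance``) and
    cover at least ``min_flank_locus_cov`` of the consensus contribute
    flank sequence; a short shared segment (e.g. a coding domain hit in
    another family) must not drive extension.
    """
    L = len(consensus)
    core_cols: list[list[str]] = []
    core_inserts: list[dict[int, str]] = []
    left_flanks: list[str] = []
    right_flanks: list[str] = []
    windows: list[tuple[str, int, int, str]] = []
    for locus in loci:
        contig_seq = genome[locus.contig]
        covers = (locus.q_end - locus.q_start) / L >= min_flank_locus_cov
        want_left = extend_left and covers and locus.q_start <= end_tolerance
        want_right = extend_right and covers and locus.q_end >= L - end_tolerance
        if locus.strand == "+":
            g_left = flank_bp if want_left else 0
            g_right = flank_bp if want_right else 0
        else:
            g_left = flank_bp if want_right else 0
            g_right = flank_bp if want_left else 0
        w_start = max(0, locus.s_start - g_left)
        w_end = min(len(contig_seq), locus.s_end + g_right)
        windows.append((locus.contig, w_start, w_end, locus.strand))
        core = contig_seq[locus.s_start : locus.s_end]
        up = contig_seq[w_start : locus.s_start]
        down = contig_seq[locus.s_end : w_end]
        if locus.strand == "-":
            core = revcomp(core)
            up, down = revcomp(down), revcomp(up)
        cols, inserts = _align_core(core, consensus[locus.q_start : locus.q_end])
        full = ["-"] * L
        full[locus.q_start : locus.q_start + len(cols)] = cols
        core_cols.append(full)
        core_inserts.append({locus.q_start + k: v for k, v in inserts.items()})
        left_flanks.append(up if want_left else "")
        right_flanks.append(down if want_right else "")

    # pool insertion columns across rows; an insertion column is only
    # realised where at least half the locally aligned rows carry it,
    # otherwise single-copy alignment artifacts would leak into the core
    core_depth_at = np.zeros(L + 1, dtype=int)
    for cols in core_cols:
        for p, ch in enumerate(cols):
            if ch != "-":
                core_depth_at[p] += 1
    core_depth_at[L] = core_depth_at[L - 1] if L else 0
    ins_width: dict[int, int] = {}
    for p in range(L + 1):
        lens = sorted(
            (len(ins[p]) for ins in core_inserts if p in ins), reverse=True
        )
        if not lens:
            continue
        local = core_depth_at[min(p, L - 1)] if L else 0
        need = max(2, int(math.ceil(0.5 * local)))
        width = 0
        for k in range(1, lens[0] + 1):
            if sum(1 for x in lens if x >= k) >= need:
                width = k
        if width:
            ins_width[p] = width
    core_rows: list[str] = []
    for cols, ins in zip(core_cols, core_inserts):
        parts: list[str] = []
        for p in range(L + 1):
            if p in ins_width:
                s = ins.get(p, "")[: ins_width[p]]
                parts.append(s + "-" * (ins_width[p] - len(s)))
            if p < L:
                parts.append(cols[p])
        core_rows.append("".join(parts))

    lw, lrows = _flank_block(left_flanks, "left") if extend_left else (0, [""] * len(loci))
    rw, rrows = _flank_block(right_flanks, "right") if extend_right else (0, [""] * len(loci))
    rows = [
        (lr or "-" * lw) + cr + (rr or "-" * rw)
        for lr, cr, rr in zip(lrows, core_rows, rrows)
    ]
    return MSAProfile(
        member_windows=windows, aligned_rows=rows, flank_left=lw, flank_right=rw
    )


# ---------------------------------------------------------------------------
# polishing and edge detection

_TIE_ORDER = "ACGT"


def polish_consensus(msa: MSAProfile, min_depth_fraction: float = 0.2) -> str:
    """Majority-vote consensus with terminal low-depth trimming.

    Per column the majority base among non-gap characters wins (ties broken
    A<C<G<T); columns whose depth falls below max(2, fraction x median core
    depth) are dropped from the termini only, never from the interior.
    """
    if not msa.aligned_rows:
        raise ValueError("cannot polish an empty alignment")
    arr = np.array([list(r) for r in msa.aligned_rows])
    depth = np.count_nonzero(arr != "-", axis=0)
    if depth.max(initial=0) == 0:
        raise ValueError("all-gap alignment")
    core = msa.core_slice()
    core_depth = depth[core] if depth[core].size else depth
    threshold = max(2, min_depth_fraction * float(np.median(core_depth)))
    lo, hi = 0, len(depth)
    while lo < hi and depth[lo] < threshold:
        lo += 1
    while hi > lo and depth[hi - 1] < threshold:
        hi -= 1
    out = []
    for col in range(lo, hi):
        counts: dict[str, int] = {}
        for ch in arr[:, col]:
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue
        best = max(
            counts,
            key=lambda b: (counts[b], -_TIE_ORDER.index(b) if b in _TIE_ORDER else -99),
        )
        out.append(best)
    return "".join(out)


def detect_edges(
    msa: MSAProfile, window: int = 50, depth_fraction: float = 0.1
) -> tuple[bool, bool]:
    """A side is done when its outermost flank columns lose copy support.

    The statistic is the mean depth over the outermost ``window`` flank
    columns (missing columns count as depth zero, so a side whose support
    collapsed inside the requested flank is done) against
    max(2, depth_fraction x median core depth).
    """
    depth = msa.column_depth
    core = msa.core_slice()
    core_depth = depth[core]
    if core_depth.size == 0 or len(msa.aligned_rows) < 2:
        return True, True
    threshold = max(2.0, depth_fraction * float(np.median(core_depth)))
    left_cols = depth[: msa.flank_left]
    right_cols = depth[msa.n_columns - msa.flank_right :]
    left_mean = float(np.sum(left_cols[:window])) / window if window else 0.0
    right_mean = float(np.sum(right_cols[-window:])) / window if window else 0.0
    return left_mean < threshold, right_mean < threshold


def trim_msa(
    msa: MSAProfile,
    trim_left: bool,
    trim_right: bool,
    depth_fraction: float = 0.1,
) -> MSAProfile:
    """Cut flank columns beyond the depth collapse point on done sides."""
    depth = msa.column_depth
    core = msa.core_slice()
    core_depth = depth[core]
    threshold = max(2.0, depth_fraction * float(np.median(core_depth))) if core_depth.size else 2.0
    lo, new_fl = 0, msa.flank_left
    if trim_left and msa.flank_left:
        keep = 0
        for i in range(msa.flank_left - 1, -1, -1):  # core boundary outward
            if depth[i] >= threshold:
                keep += 1
            else:
                break
        lo = msa.flank_left - keep
        new_fl = keep
    hi, new_fr = msa.n_columns, msa.flank_right
    if trim_right and msa.flank_right:
        start = msa.n_columns - msa.flank_right
        keep = 0
        for i in range(start, msa.n_columns):
            if depth[i] >= threshold:
                keep += 1
            else:
                break
        hi = start + keep
        new_fr = keep
    rows = [r[lo:hi] for r in msa.aligned_rows]
    return MSAProfile(
        member_windows=msa.member_windows,
        aligned_rows=rows,
        flank_left=new_fl,
        flank_right=new_fr,
    )


# ---------------------------------------------------------------------------
# BEE iteration


def bee_iteration(
    state: ExtensionState,
    genome: SubjectIndex,
    flank_bp: int = 500,
    max_evalue: float = 1e-20,
    max_copies: int = 40,
    edge_window: int = 50,
    edge_depth_fraction: float = 0.1,
    min_depth_fraction: float = 0.2,
) -> ExtensionState:
    """One BLAST-Extract-Extend round; no-op once both sides are done."""
    if state.left_done and state.right_done:
        return state
    loci = collect_copies(
        state.consensus, genome, max_evalue=max_evalue, max_copies=max_copies
    )
    if not loci:
        state.left_done = state.right_done = True
        state.notes.append("no genomic support")
        state.history.append((len(state.consensus), 0, True, True))
        return state
    if len(loci) < 2:
        # a single copy can neither support extension nor be polished
        state.left_done = state.right_done = True
        state.notes.append("single-copy support; consensus left as is")
        state.history.append((len(state.consensus), len(loci), True, True))
        return state
    msa = build_msa(
        state.consensus,
        loci,
        genome.sequences,
        flank_bp=flank_bp,
        extend_left=not state.left_done,
        extend_right=not state.right_done,
    )
    left_edge, right_edge = detect_edges(
        msa, window=edge_window, depth_fraction=edge_depth_fraction
    )
    left_done = state.left_done or left_edge
    right_done = state.right_done or right_edge
    msa = trim_msa(
        msa,
        trim_left=left_done and not state.left_done,
        trim_right=right_done and not state.right_done,
        depth_fraction=edge_depth_fraction,
    )
    consensus = polish_consensus(msa, min_depth_fraction=min_depth_fraction)
    state.consensus = consensus
    state.left_done = left_done
    state.right_done = right_done
    state.iteration += 1
    state.msa = msa
    state.history.append((len(consensus), len(loci), left_done, right_done))
    return state


def extend_consensus(
    seed: str,
    genome: SubjectIndex,
    max_iterations: int = 16,
    **kwargs,
) -> ExtensionState:
    """Run BEE rounds until both ends are reached or the budget runs out."""
    state = ExtensionState(consensus=seed)
    for _ in range(max_iterations):
        state = bee_iteration(state, genome, **kwargs)
        if state.left_done and state.right_done:
            break
    return state


# ---------------------------------------------------------------------------
# Kimura 2-parameter distances and subfamily splitting

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = set("ACGT")


@dataclass(frozen=True)
class PairwiseDistance:
    """K2P distance between two gapped rows (gap/N columns excluded)."""

    p_transitions: float
    q_transversions: float
    d: float
    comparable_sites: int
    saturated: bool = False


def kimura2p_distance(row_a: str, row_b: str) -> PairwiseDistance:
    """Kimura two-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    comparable = transitions = transversions = 0
    for a, b in zip(row_a, row_b):
        if a not in _BASES or b not in _BASES:
            continue
        comparable += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if comparable == 0:
        raise ValueError("no comparable sites")
    P = transitions / comparable
    Q = transversions / comparable
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return PairwiseDistance(P, Q, math.inf, comparable, saturated=True)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseDistance(P, Q, d, comparable)


def split_subfamilies(
    msa: MSAProfile,
    distance_cutoff: float = 0.10,
    min_members: int = 5,
    min_sites: int = 100,
    min_separation: float = 1.3,
) -> list[MSAProfile]:
    """Average-linkage K2P clustering; well-populated clusters become
    subfamilies, the rest join their nearest large cluster.

    Returns ``[msa]`` unchanged when no split is warranted: too few rows,
    fewer than two clusters of at least ``min_members``, or insufficient
    separation.  Saturated pairs are imputed at the matrix maximum
    (flagged through the distance itself); pairs sharing fewer than
    ``min_sites`` comparable columns carry no subfamily information (they
    reflect opposite truncations) and are imputed at the mean informative
    distance instead.  A split is only accepted when the mean
    between-cluster distance exceeds ``min_separation`` times the mean
    within-cluster distance - a uniformly diverged family forms a single
    star-shaped cloud that must not be carved up by cutoff noise.
    """
    n = len(msa.aligned_rows)
    if n < 2 * min_members:
        return [msa]
    dmat = np.zeros((n, n))
    informative = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                pd = kimura2p_distance(msa.aligned_rows[i], msa.aligned_rows[j])
            except ValueError:  # disjoint rows (opposite truncations)
                pd = None
            if pd is None or pd.comparable_sites < min_sites:
                informative[i, j] = informative[j, i] = False
                dmat[i, j] = dmat[j, i] = np.nan
            elif pd.saturated:
                dmat[i, j] = dmat[j, i] = np.inf
            else:
                dmat[i, j] = dmat[j, i] = pd.d
    # rows that share no aligned columns cannot belong to one family: two
    # or more well-populated components of the overlap graph mean the
    # consensus glues unrelated segments together (a chimeric assembly),
    # and each component is processed as its own family
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if informative[i, j]:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    if len(comps) > 1:
        large_comps = [rows for rows in comps.values() if len(rows) >= min_members]
        if len(large_comps) >= 2:
            largest = max(large_comps, key=len)
            for rows in comps.values():
                if len(rows) < min_members:
                    largest.extend(rows)
            out: list[MSAProfile] = []
            for rows in sorted(large_comps, key=lambda r: (-len(r), min(r))):
                out.extend(
                    split_subfamilies(
                        msa.subset(sorted(rows)),
                        distance_cutoff=distance_cutoff,
                        min_members=min_members,
                        min_sites=min_sites,
                        min_separation=min_separation,
                    )
                )
            return out

    finite = dmat[np.isfinite(dmat)]
    if finite.size == 0:
        return [msa]
    dmat[np.isinf(dmat)] = float(finite.max())
    dmat[np.isnan(dmat)] = float(finite.mean())
    Z = linkage(squareform(dmat, checks=False), method="average")
    labels = fcluster(Z, t=distance_cutoff, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    large = {lab: rows for lab, rows in groups.items() if len(rows) >= min_members}
    if len(large) < 2:
        return [msa]
    within = []
    for rows in large.values():
        idx = np.ix_(rows, rows)
        tri = dmat[idx][np.triu_indices(len(rows), k=1)]
        within.extend(tri.tolist())
    between = []
    labs = sorted(large)
    for a in range(len(labs)):
        for b in range(a + 1, len(labs)):
            between.extend(dmat[np.ix_(large[labs[a]], large[labs[b]])].ravel().tolist())
    if not within or not between:
        return [msa]
    if float(np.mean(between)) < min_separation * float(np.mean(within)):
        return [msa]
    for lab, rows in groups.items():
        if lab in large:
            continue
        best_lab, best_d = None, math.inf
        for tlab, trows in large.items():
            d = float(np.mean(dmat[np.ix_(rows, trows)]))
            if d < best_d:
                best_lab, best_d = tlab, d
        large[best_lab].extend(rows)
    ordered = sorted(large.values(), key=lambda rows: (-len(rows), min(rows)))
    return [msa.subset(sorted(rows)) for rows in ordered]


def write_extension_report(
    states: dict[str, ExtensionState], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "iteration", "length", "n_copies", "left_done", "right_done"])
        for rec_id in sorted(states):
            for it, (length, n_hits, ld, rd) in enumerate(states[rec_id].history, 1):
                writer.writerow([rec_id, it, length, n_hits, int(ld), int(rd)])
    return path
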