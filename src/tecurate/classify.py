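"""Classification: homology assignment, structural checking, unknown rescue.

Records that match a curated reference database under the 80-80-80 rule
keep (or gain) that classification directly.  Classified records without
such a hit are checked against an order-specific table of expected
structural features (terminal repeats, poly(A) tails, coding domains);
failures are retained but flagged with an ``_inc`` suffix.  Unclassified
records go through a three-step rescue: relaxed homology (70-70-70),
coding-domain content, and terminal repeats alone, in that order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .models import (
    ConsensusRecord,
    DNA_ROLES,
    LibraryDocument,
    Order,
    ProfileRole,
    RETRO_ROLES,
    StructuralFeatureSet,
    TEClass,
    TEClassification,
)
from .profiles import Profile, profile_search
from .search import local_search, meets_rule, revcomp, weighted_identity


@dataclass
class ClassificationDecision:
    final: TEClassification
    step: str  # kept_original | homology_80 | structural_pass |
    #            structural_fail_inc | unknown_homology_70 | unknown_domains |
    #            unknown_tr | still_unclassified
    evidence: str = ""


# ---------------------------------------------------------------------------
# structural feature detection


def _best_ungapped_terminal(
    left: str, right_rc: str, min_len: int, max_offset: int, min_identity: float
) -> tuple[int, int, int, float] | None:
    """Best ungapped match between two terminal windows.

    ``right_rc`` is already in the orientation that should match ``left``.
    Only matches starting within ``max_offset`` of the start of both
    windows are considered.  Returns (off_a, off_b, length, identity).
    """
    a = np.frombuffer(left.encode(), dtype=np.uint8)
    b = np.frombuffer(right_rc.encode(), dtype=np.uint8)
    best = None
    for off_a in range(min(max_offset + 1, len(a))):
        for off_b in range(min(max_offset + 1, len(b))):
            n = min(len(a) - off_a, len(b) - off_b)
            if n < min_len:
                continue
            eq = a[off_a : off_a + n] == b[off_b : off_b + n]
            # +1/-2 prefix score keeps short spurious matches out: a random
            # pair of termini essentially never reaches score >= min_len
            cum = np.cumsum(np.where(eq, 1, -2))
            L = int(np.argmax(cum)) + 1
            score = int(cum[L - 1])
            ident = float(np.count_nonzero(eq[:L]) / L)
            if L >= min_len and score >= min_len and ident >= min_identity:
                if best is None or score > best[0]:
                    best = (score, off_a, off_b, L, ident)
    if best is None:
        return None
    _, off_a, off_b, L, ident = best
    return off_a, off_b, L, ident


def detect_terminal_repeats(
    sequence: str,
    end_window_fraction: float = 0.25,
    min_ltr: int = 100,
    min_tir: int = 10,
    min_identity: float = 0.8,
    tir_max_offset: int = 20,
) -> StructuralFeatureSet:
    """Detect direct (LTR-like) and inverted (TIR-like) terminal repeats.

    LTRs: best local alignment between the first and last quarter of the
    sequence with length >= ``min_ltr``.  TIRs: best ungapped terminal
    reverse-complement match starting within ``tir_max_offset`` nt of each
    terminus.  At most one of each is reported.
    """
    features = StructuralFeatureSet()
    L = len(sequence)
    w = max(1, int(L * end_window_fraction))
    if L >= 200:
        head, tail = sequence[:w], sequence[L - w :]
        hits = local_search(head, {"tail": tail}, max_evalue=1e-5)
        direct = [
            h
            for h in hits
            if h.strand == "+" and h.aln_length >= min_ltr and h.identity >= min_identity
        ]
        if direct:
            h = max(direct, key=lambda h: h.score)
            features.ltr = (
                (h.q_start, h.q_end),
                (L - w + h.s_start, L - w + h.s_end),
                h.identity,
            )
    if L >= 50:
        w_tir = min(w, 120)
        head = sequence[:w_tir]
        tail_rc = revcomp(sequence[L - w_tir :])
        m = _best_ungapped_terminal(head, tail_rc, min_tir, tir_max_offset, min_identity)
        if m is not None:
            off_a, off_b, n, ident = m
            features.tir = (
                (off_a, off_a + n),
                (L - off_b - n, L - off_b),
                ident,
            )
    return features


def detect_polya(
    sequence: str, tail_window: int = 30, min_run: int = 10, min_purity: float = 0.9
) -> tuple[tuple[int, int], float] | None:
    """An A-rich run (>= ``min_run`` nt, >= ``min_purity`` A) in the last
    ``tail_window`` nt; forward orientation only."""
    L = len(sequence)
    tail = sequence[max(0, L - tail_window) :]
    offset = L - len(tail)
    is_a = np.array([c == "A" for c in tail], dtype=int)
    best = None
    for i in range(len(tail)):
        for j in range(i + min_run, len(tail) + 1):
            purity = is_a[i:j].mean()
            if purity >= min_purity:
                key = (j - i, purity)
                if best is None or key > best[0]:
                    best = (key, (offset + i, offset + j), float(purity))
    if best is None:
        return None
    return best[1], best[2]


def compute_features(
    record: ConsensusRecord,
    te_profiles: list[Profile],
    profile_evalue: float = 10.0,
    **tr_kwargs,
) -> StructuralFeatureSet:
    """Full structural feature set: terminal repeats, poly(A), domains."""
    features = detect_terminal_repeats(record.sequence, **tr_kwargs)
    features.polya = detect_polya(record.sequence)
    if te_profiles:
        features.domains = profile_search(
            record.sequence, te_profiles, max_evalue=profile_evalue
        )
    return features


# ---------------------------------------------------------------------------
# homology assignment


def homology_assign(
    record: ConsensusRecord,
    reference_db: LibraryDocument,
    rule: tuple[int, float, float] = (80, 0.80, 0.80),
    max_evalue: float = 1e-10,
) -> ClassificationDecision | None:
    """Donate the classification of the best reference matching the rule.

    Coverage is measured on the query (the record being classified); the
    best subject is the one with the highest total hit score among those
    whose merged hits satisfy the rule.
    """
    min_len, min_ident, min_cov = rule
    step = "homology_80" if min_ident >= 0.8 else "unknown_homology_70"
    subjects = {r.id: r.sequence for r in reference_db.kept()}
    if not subjects:
        return None
    hits = local_search(record.sequence, subjects, max_evalue=max_evalue)
    by_subject: dict[str, list] = {}
    for h in hits:
        by_subject.setdefault(h.subject_id, []).append(h)
    best = None
    for subject_id, hs in sorted(by_subject.items()):
        if not meets_rule(hs, min_len, min_ident, min_cov, len(record.sequence)):
            continue
        score = sum(h.score for h in hs)
        if best is None or score > best[0]:
            best = (score, subject_id, hs)
    if best is None:
        return None
    _, subject_id, hs = best
    donor = reference_db.get(subject_id)
    return ClassificationDecision(
        final=donor.classification,
        step=step,
        evidence=(
            f"best match {subject_id} identity={weighted_identity(hs):.3f} "
            f"({len(hs)} hits)"
        ),
    )


# ---------------------------------------------------------------------------
# structural checking against the order rules table


def load_structure_rules() -> dict[Order, str]:
    text = resources.files("tecurate.data").joinpath("structure_rules.tsv").read_text()
    rules: dict[Order, str] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        order_token, rule = line.split("\t")
        rules[Order(order_token)] = rule
    return rules


_RULES = load_structure_rules()


def _atom_holds(atom: str, record: ConsensusRecord, f: StructuralFeatureSet) -> bool:
    if atom == "ltr":
        return f.ltr is not None
    if atom == "tir":
        return f.tir is not None
    if atom == "polya":
        return f.polya is not None
    if atom == "no_ltr":
        return f.ltr is None
    if atom == "no_tir":
        return f.tir is None
    if atom == "no_coding":
        return not f.domains
    if atom.startswith("len<="):
        return len(record.sequence) <= int(atom[5:])
    if atom.startswith("domain:"):
        return f.has_role(ProfileRole(atom[7:]))
    if atom == "any_retro_domain":
        return f.has_role(*RETRO_ROLES)
    if atom == "any_dna_domain":
        return f.has_role(*DNA_ROLES)
    raise ValueError(f"unknown structural atom {atom!r}")


def structure_matches(
    record: ConsensusRecord, features: StructuralFeatureSet, order: Order
) -> bool:
    rule = _RULES.get(order)
    if rule is None:
        return False
    return any(
        all(_atom_holds(atom, record, features) for atom in alt.split("&"))
        for alt in rule.split("|")
    )


def check_structure(
    record: ConsensusRecord, features: StructuralFeatureSet
) -> ClassificationDecision:
    """Verify that a classified record shows its order's expected features.

    Never changes the order - only the completeness status: a failing
    record is flagged incomplete (``_inc`` id suffix) but its
    classification is retained.
    """
    order = record.classification.order
    if order is Order.UNCLASSIFIED:
        raise ValueError("check_structure requires a classified record")
    if structure_matches(record, features, order):
        return ClassificationDecision(
            final=record.classification,
            step="structural_pass",
            evidence=_feature_summary(features),
        )
    return ClassificationDecision(
        final=record.classification,
        step="structural_fail_inc",
        evidence=_feature_summary(features),
    )


def _feature_summary(f: StructuralFeatureSet) -> str:
    parts = []
    if f.ltr:
        parts.append(f"LTR({f.ltr[0][1] - f.ltr[0][0]}bp,{f.ltr[2]:.2f})")
    if f.tir:
        parts.append(f"TIR({f.tir[0][1] - f.tir[0][0]}bp,{f.tir[2]:.2f})")
    if f.polya:
        parts.append("polyA")
    for role in sorted({d.profile_role.value for d in f.domains}):
        parts.append(role)
    return "+".join(parts) if parts else "none"


# ---------------------------------------------------------------------------
# three-step rescue of unclassified records


def classify_unknown(
    record: ConsensusRecord,
    reference_db: LibraryDocument,
    features: StructuralFeatureSet,
    rule: tuple[int, float, float] = (70, 0.70, 0.70),
) -> ClassificationDecision:
    """Homology (70-70-70), then coding domains, then terminal repeats."""
    decision = homology_assign(record, reference_db, rule=rule)
    if decision is not None:
        return decision
    roles = features.roles()
    retro = roles & RETRO_ROLES
    dna = roles & DNA_ROLES
    if retro or dna:
        if len(retro) >= len(dna) and retro:
            if features.ltr is not None:
                final = TEClassification(order=Order.LTR)
            elif features.polya is not None and features.tir is None:
                final = TEClassification(order=Order.LINE)
            else:
                final = TEClassification(te_class=TEClass.CLASS_I)
        else:
            if features.tir is not None:
                final = TEClassification(order=Order.TIR)
            elif ProfileRole.HELICASE in dna:
                final = TEClassification(order=Order.HELITRON)
            else:
                final = TEClassification(te_class=TEClass.CLASS_II)
        return ClassificationDecision(
            final=final,
            step="unknown_domains",
            evidence="domains: " + ",".join(sorted(r.value for r in retro | dna)),
        )
    if features.ltr is not None:
        return ClassificationDecision(
            final=TEClassification(order=Order.LTR),
            step="unknown_tr",
            evidence="direct terminal repeats only",
        )
    if features.tir is not None:
        return ClassificationDecision(
            final=TEClassification(order=Order.TIR),
            step="unknown_tr",
            evidence="inverted terminal repeats only",
        )
    return ClassificationDecision(
        final=TEClassification(), step="still_unclassified", evidence="no signal"
    )


def write_decision_table(
    decisions: dict[str, ClassificationDecision], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "step", "classification", "evidence"])
        for rec_id in sorted(decisions):
            d = decisions[rec_id]
            writer.writerow([rec_id, d.step, d.final.label, d.evidence])
    return path
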