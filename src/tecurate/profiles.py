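"""Protein-profile search over six-frame translations.

Profiles are position-specific scoring matrices (PSSMs) over peptides,
stored as JSON (name, role, alphabet, matrix).  Each profile carries a
functional role (reverse transcriptase, transposase, host gene, rRNA, ...)
that downstream classification and false-positive filtering consume.
Significance uses the ungapped Karlin-Altschul model with a per-profile
lambda solved numerically from the column score distributions.

A deterministic built-in set of TE coding-domain profiles (RT, INT, GAG,
PROT, RNaseH, EN, Transposase, Helicase) is bundled; the simulator plants
back-translations of the same consensus peptides, which keeps the whole
test bed self-contained and download-free.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from scipy.optimize import brentq

from .models import DomainHit, ProfileRole

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_BG = 1.0 / len(AA_ALPHABET)
K_PARAM = 0.1
_MATCH_P = 0.9  # emission probability of the consensus residue


@dataclass
class Profile:
    """A peptide PSSM with a functional role."""

    name: str
    role: ProfileRole
    matrix: np.ndarray  # (length, 20) log2-odds scores
    consensus: str = ""
    _lambda: float | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def karlin_lambda(self) -> float:
        """Solve sum_a bg_a * exp(lambda * s_nat(a)) = 1 per column (mean)."""
        if self._lambda is None:
            s_nat = self.matrix * math.log(2.0)

            def f(lam: float) -> float:
                return float(np.mean(np.sum(_BG * np.exp(lam * s_nat), axis=1)) - 1.0)

            self._lambda = brentq(f, 1e-4, 10.0)
        return self._lambda

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "role": self.role.value,
            "alphabet": AA_ALPHABET,
            "consensus": self.consensus,
            "matrix": [[round(float(x), 4) for x in row] for row in self.matrix],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Profile":
        return cls(
            name=d["name"],
            role=ProfileRole(d["role"]),
            matrix=np.asarray(d["matrix"], dtype=float),
            consensus=d.get("consensus", ""),
        )


def pssm_from_peptide(name: str, role: ProfileRole, peptide: str) -> Profile:
    """Log2-odds PSSM strongly favouring ``peptide`` at each position."""
    n = len(AA_ALPHABET)
    off_p = (1.0 - _MATCH_P) / (n - 1)
    mat = np.full((len(peptide), n), math.log2(off_p / _BG))
    for i, aa in enumerate(peptide):
        mat[i, _AA_INDEX[aa]] = math.log2(_MATCH_P / _BG)
    return Profile(name=name, role=role, matrix=mat, consensus=peptide)


def _role_rng(tag: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(tag.encode()) & 0x7FFFFFFF)


def role_peptide(tag: str, length: int = 60) -> str:
    """Deterministic consensus peptide for a profile tag."""
    rng = _role_rng("peptide::" + tag)
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), length))


_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def back_translate(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)


_TE_DOMAIN_ROLES = [
    ProfileRole.RT, ProfileRole.INT, ProfileRole.GAG, ProfileRole.PROT,
    ProfileRole.RNASEH, ProfileRole.EN, ProfileRole.TRANSPOSASE,
    ProfileRole.HELICASE,
]


def builtin_te_profiles() -> list[Profile]:
    """The bundled TE coding-domain profile set (deterministic)."""
    return [
        pssm_from_peptide(f"{role.value}_dom", role, role_peptide(role.value))
        for role in _TE_DOMAIN_ROLES
    ]


def make_decoy_profiles(kind: ProfileRole, count: int, seed: int = 0) -> list[Profile]:
    """Mock multicopy-gene or rRNA profiles (e.g. a desk-scale BUSCO set)."""
    out = []
    for i in range(count):
        tag = f"{kind.value}::{seed}::{i}"
        out.append(pssm_from_peptide(f"{kind.value}_{i + 1}", kind, role_peptide(tag)))
    return out


def write_profiles(profiles: list[Profile], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in profiles], fh)
    return path


def read_profiles(path: str | Path) -> list[Profile]:
    with open(path) as fh:
        data = json.load(fh)
    return [Profile.from_dict(d) for d in data]


def _translate_frames(query: str) -> list[tuple[int, str]]:
    """Six-frame translation; returns (frame, peptide) pairs."""
    frames = []
    rc = str(Seq(query).reverse_complement())
    for off in range(3):
        for sign, seq in ((1, query), (-1, rc)):
            sub = seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            pep = str(Seq(sub).translate())
            frames.append((sign * (off + 1), pep))
    return frames


def _encode_peptide(pep: str) -> np.ndarray:
    """Map to PSSM row indices; stops and unknowns get a sentinel (-1)."""
    arr = np.full(len(pep), -1, dtype=np.int64)
    for i, aa in enumerate(pep):
        arr[i] = _AA_INDEX.get(aa, -1)
    return arr


def profile_search(
    query: str,
    profiles: list[Profile],
    max_evalue: float = 10.0,
) -> list[DomainHit]:
    """Scan all six frames of ``query`` against peptide PSSMs.

    Reports the best non-overlapping windows per frame and profile with
    e-value <= ``max_evalue`` (the HMMER-style default cutoff of 10).
    """
    if not profiles:
        raise ValueError("no profiles loaded")
    if len(query) < 3:
        return []
    frames = _translate_frames(query)
    search_space = sum(len(p) for _, p in frames)
    hits: list[DomainHit] = []
    worst = float(np.min([p.matrix.min() for p in profiles])) - 1.0
    for profile in profiles:
        L = profile.length
        lam = profile.karlin_lambda()
        for frame, pep in frames:
            if len(pep) < L:
                continue
            idx = _encode_peptide(pep)
            # per-position scores for every window start, via stride tricks
            padded = np.where(idx >= 0, idx, 0)
            windows = np.lib.stride_tricks.sliding_window_view(padded, L)
            pos_scores = profile.matrix[np.arange(L)[None, :], windows]
            invalid = np.lib.stride_tricks.sliding_window_view(idx < 0, L)
            pos_scores = np.where(invalid, worst, pos_scores)
            scores = pos_scores.sum(axis=1)
            order = np.argsort(-scores, kind="stable")
            taken: list[tuple[int, int]] = []
            for w in order:
                s_bits = float(scores[w])
                s_nat = s_bits * math.log(2.0)
                ev = K_PARAM * search_space * L * math.exp(-lam * s_nat)
                if ev > max_evalue:
                    break
                a, b = int(w), int(w) + L
                if any(a < e and s < b for s, e in taken):
                    continue
                taken.append((a, b))
                hits.append(
                    DomainHit(
                        profile_name=profile.name,
                        profile_role=profile.role,
                        q_start=a,
                        q_end=b,
                        frame=frame,
                        evalue=ev,
                        score=s_bits,
                    )
                )
    hits.sort(key=lambda h: (h.evalue, h.profile_name, h.frame, h.q_start))
    return hits


def domain_nt_intervals(hits: list[DomainHit], query_len: int) -> list[tuple[int, int]]:
    """Project amino-acid hit windows back to nucleotide query coordinates."""
    out = []
    for h in hits:
        if h.frame > 0:
            off = h.frame - 1
            start = off + 3 * h.q_start
            end = off + 3 * h.q_end
        else:
            off = -h.frame - 1
            end = query_len - (off + 3 * h.q_start)
            start = query_len - (off + 3 * h.q_end)
        start = max(0, start)
        end = min(query_len, end)
        if start < end:
            out.append((start, end))
    return out
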