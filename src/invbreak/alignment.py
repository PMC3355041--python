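"""Local similarity search used throughout the breakpoint analysis.

Two engines live here:

* a seeded, ungapped DNA local-similarity search (exact k-mer seeds, X-drop
  extension, per-diagonal seed masking) with Karlin-Altschul e-values, used
  for outgroup narrowing, TE annotation and inverted-duplication detection;
* a protein local aligner (affine-gap Smith-Waterman over BLOSUM62 via
  Bio.Align) with a bit-score-to-e-value conversion, used for duplicate-gene
  detection and reciprocal-best-hit orthology.

The DNA scoring (match +2, mismatch -3) mirrors classic megablast-style
nucleotide scoring; lambda is solved exactly for a uniform background and K
is a fixed conservative constant, which keeps the e-value scale calibrated
well enough that unrelated 1-kb sequences essentially never reach the 1e-3
threshold used for cross-species comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LocalHit",
    "local_search",
    "dna_evalue",
    "protein_align",
    "protein_score_threshold",
]

_MATCH = 2
_MISMATCH = -3
_KA_K = 0.35  # conservative Karlin-Altschul K for the +2/-3 scheme

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet; output is uppercase."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1)
def _ka_lambda() -> float:
    # uniform background: (1/4) e^{lambda*match} + (3/4) e^{lambda*mismatch} = 1
    f = lambda lam: 0.25 * math.exp(lam * _MATCH) + 0.75 * math.exp(lam * _MISMATCH) - 1.0
    return float(brentq(f, 1e-6, 5.0))


def dna_evalue(score: float, m: int, n: int) -> float:
    """Karlin-Altschul e-value for an ungapped nucleotide score."""
    return _KA_K * m * n * math.exp(-_ka_lambda() * score)


def dna_score_threshold(evalue: float, m: int, n: int) -> float:
    """Raw score needed for a hit of e-value <= ``evalue``."""
    return math.log(_KA_K * m * n / evalue) / _ka_lambda()


@dataclass(frozen=True)
class LocalHit:
    """One ungapped local similarity block.

    Coordinates are 0-based half-open on the forward strand of both
    sequences; ``strand`` is '+' when query and subject align directly and
    '-' when the query matches the reverse complement of the subject.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: float
    length: int
    identity: float  # percent
    evalue: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


def _extend(q: np.ndarray, s: np.ndarray, qi: int, si: int, k: int, xdrop: float):
    """Ungapped two-sided X-drop extension of a seed of length k."""
    nq, ns = len(q), len(s)
    # right extension
    score = 0.0
    best = 0.0
    best_right = k
    i, j = qi + k, si + k
    matches_r = 0
    best_matches_r = 0
    while i < nq and j < ns:
        score += _MATCH if q[i] == s[j] and q[i] != 4 else _MISMATCH
        matches_r += 1 if (q[i] == s[j] and q[i] != 4) else 0
        if score > best:
            best, best_right, best_matches_r = score, i - qi + 1, matches_r
        if best - score > xdrop:
            break
        i += 1
        j += 1
    right_score, right_len = best, best_right
    # left extension
    score = 0.0
    best = 0.0
    best_left = 0
    i, j = qi - 1, si - 1
    matches_l = 0
    best_matches_l = 0
    while i >= 0 and j >= 0:
        score += _MATCH if q[i] == s[j] and q[i] != 4 else _MISMATCH
        matches_l += 1 if (q[i] == s[j] and q[i] != 4) else 0
        if score > best:
            best, best_left, best_matches_l = score, qi - i, matches_l
        if best - score > xdrop:
            break
        i -= 1
        j -= 1
    left_score, left_len = best, best_left
    seed_score = k * _MATCH
    total = seed_score + left_score + right_score
    start_q = qi - left_len
    end_q = qi + right_len
    length = end_q - start_q
    matches = k + best_matches_l + best_matches_r
    return start_q, end_q, si - left_len, si + right_len, total, length, matches


def _search_one_strand(
    query: str, subject: str, k: int, xdrop: float, max_evalue: float
) -> list[LocalHit]:
    q = _encode(query)
    s = _encode(subject)
    nq, ns = len(q), len(s)
    if nq < k or ns < k:
        return []
    index: dict[bytes, list[int]] = {}
    sb = bytes(s.tobytes())
    for j in range(ns - k + 1):
        word = sb[j : j + k]
        if 4 in word:
            continue
        index.setdefault(word, []).append(j)
    qb = bytes(q.tobytes())
    covered: dict[int, list[tuple[int, int]]] = {}  # diagonal -> q-intervals already in a hit
    hits: list[LocalHit] = []
    for i in range(nq - k + 1):
        word = qb[i : i + k]
        if 4 in word:
            continue
        for j in index.get(word, ()):
            diag = i - j
            skip = False
            for a, b in covered.get(diag, ()):
                if a <= i and i + k <= b:
                    skip = True
                    break
            if skip:
                continue
            qs, qe, ss, se, score, length, matches = _extend(q, s, i, j, k, xdrop)
            covered.setdefault(diag, []).append((qs, qe))
            ev = dna_evalue(score, nq, ns)
            if ev <= max_evalue and length >= k:
                hits.append(
                    LocalHit(
                        q_start=qs,
                        q_end=qe,
                        s_start=ss,
                        s_end=se,
                        strand="+",
                        score=score,
                        length=length,
                        identity=100.0 * matches / length,
                        evalue=ev,
                    )
                )
    # deduplicate identical blocks discovered from different seeds
    uniq = {}
    for h in hits:
        key = (h.q_start, h.q_end, h.s_start)
        if key not in uniq or h.score > uniq[key].score:
            uniq[key] = h
    return sorted(uniq.values(), key=lambda h: (-h.score, h.q_start))


def local_search(
    query: str,
    subject: str,
    *,
    k: int = 11,
    xdrop: float = 20.0,
    max_evalue: float = 1e-3,
    both_strands: bool = True,
) -> list[LocalHit]:
    """Seeded ungapped local similarity search, best hits first.

    Subject coordinates of minus-strand hits are reported on the forward
    strand of the subject.
    """
    hits = _search_one_strand(query, subject, k, xdrop, max_evalue)
    if both_strands:
        ns = len(subject)
        for h in _search_one_strand(query, revcomp(subject), k, xdrop, max_evalue):
            hits.append(
                LocalHit(
                    q_start=h.q_start,
                    q_end=h.q_end,
                    s_start=ns - h.s_end,
                    s_end=ns - h.s_start,
                    strand="-",
                    score=h.score,
                    length=h.length,
                    identity=h.identity,
                    evalue=h.evalue,
                )
            )
    return sorted(hits, key=lambda h: (-h.score, h.q_start))


# --- protein alignment -----------------------------------------------------

_BLOSUM62_LAMBDA = 0.267  # published ungapped Karlin-Altschul parameters
_BLOSUM62_K = 0.041

_AA = set("ACDEFGHIKLMNPQRSTVWYBZXJUO*")


@lru_cache(maxsize=1)
def _protein_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def protein_score_threshold(evalue: float, m: int, n: int) -> float:
    """Raw BLOSUM62 score equivalent to the given e-value for sizes m x n."""
    return math.log(_BLOSUM62_K * max(m, 1) * max(n, 1) / evalue) / _BLOSUM62_LAMBDA


def protein_align(seq_a: str, seq_b: str) -> tuple[float, int, float]:
    """Best local alignment of two protein sequences.

    Returns ``(percent_identity, hit_length, raw_score)`` of the best local
    alignment (BLOSUM62, gap open -11 / extend -1).  Raises ``ValueError``
    on empty input or non-amino-acid characters.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty protein sequence")
    for s in (seq_a, seq_b):
        bad = set(s.upper()) - _AA
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    aligner = _protein_aligner()
    score = aligner.score(seq_a.upper(), seq_b.upper())
    if score <= 0:
        return 0.0, 0, 0.0
    aln = next(iter(aligner.align(seq_a.upper(), seq_b.upper())))
    a_idx, b_idx = aln.indices
    matches = 0
    length = 0
    for x, y in zip(a_idx, b_idx):
        length += 1
        if x >= 0 and y >= 0 and seq_a.upper()[x] == seq_b.upper()[y]:
            matches += 1
    identity = 100.0 * matches / length if length else 0.0
    return identity, length, float(score)
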