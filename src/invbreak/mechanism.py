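"""Inversion generation mechanism from junction sequence evidence.

Three signatures are diagnostic:

* a TE copy at each junction bounded by *exchanged* target-site
  duplications — each junction's flanking 9-bp-scale words are the reverse
  complements of the other junction's — proves ectopic recombination
  between oppositely oriented TE copies;
* inverted duplications of originally single-copy DNA at the two junctions,
  absent from the parental arrangement, indicate staggered single-strand
  breaks repaired by NHEJ; their noncoding divergence dates the inversion
  (K / 2r with the neutral rate r, both copies diverging since the event);
* duplications also present between the parental junctions are preexisting
  and are reported, not treated as mechanism evidence.

Precedence: exchanged TSDs, then inversion-associated inverted
duplications, else undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Optional, Sequence

from . import alignment
from .alignment import local_search
from .config import ConfigDefaults

__all__ = [
    "TsdEvidence",
    "DuplicationBlock",
    "TeAnnotation",
    "MechanismCall",
    "reverse_complement",
    "annotate_te_fragments",
    "find_tsds",
    "detect_exchanged_tsd",
    "detect_inverted_duplications",
    "estimate_inversion_age",
    "classify_mechanism",
    "classify_junctions",
    "principal_te",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement (ACGTN, case-insensitive); an involution."""
    return alignment.revcomp(seq)


@dataclass(frozen=True)
class TeAnnotation:
    """A TE-library match within a junction sequence."""

    te_id: str
    start: int
    end: int  # 0-based half-open on the junction sequence
    strand: str
    kind: str  # full_copy | fragment | composite_footprint
    end_composition: tuple[int, int] = (0, 0)  # bp matching each TE terminus


@dataclass(frozen=True)
class TsdCandidates:
    """Flanking words of one TE annotation, by word length."""

    left: dict[int, str]
    right: dict[int, str]
    edge_flags: tuple[bool, bool] = (False, False)  # (left missing, right missing)


@dataclass(frozen=True)
class TsdEvidence:
    distal_left: str = ""
    distal_right: str = ""
    proximal_left: str = ""
    proximal_right: str = ""
    exchanged: bool = False


@dataclass(frozen=True)
class DuplicationBlock:
    """A similarity block between the AC and BD junction sequences."""

    ac_start: int
    ac_end: int
    bd_start: int
    bd_end: int
    orientation: str  # inverted | direct
    length: int
    pct_identity: float
    evalue: float


@dataclass(frozen=True)
class MechanismCall:
    label: str  # ectopic_recombination | staggered_ssb_nhej | undetermined
    evidence: str = ""
    age_myr: Optional[float] = None
    preexisting_duplication: bool = False


def annotate_te_fragments(
    seq: str,
    te_library: dict[str, str],
    min_match: int = 18,
    full_copy_coverage: float = 0.9,
    footprint_gap: int = 10,
) -> list[TeAnnotation]:
    """Locate TE-library matches in a junction sequence.

    Matches of at least ``min_match`` bp are reported.  A match covering at
    least ``full_copy_coverage`` of the element is a ``full_copy``.  Two
    adjacent fragments (gap at most ``footprint_gap`` bp) matching the two
    termini of the same element with no internal body between them merge
    into a ``composite_footprint`` — the residue transposons leave behind
    on excision.
    """
    if not te_library:
        raise ValueError("empty TE library")
    out: list[TeAnnotation] = []
    for te_id, te_seq in te_library.items():
        k = min(11, max(6, min_match - 2))
        hits = [
            h
            for h in local_search(seq, te_seq, k=k, max_evalue=10.0)
            if h.length >= min_match and h.identity >= 90.0
        ]
        hits.sort(key=lambda h: h.q_start)
        used = [False] * len(hits)
        te_len = len(te_seq)
        # composite footprints: left-terminus fragment abutting a
        # right-terminus fragment of the same element
        for i, hi in enumerate(hits):
            for j, hj in enumerate(hits):
                if i == j or used[i] or used[j]:
                    continue
                gap = hj.q_start - hi.q_end
                if not (0 <= gap <= footprint_gap):
                    continue
                # orient subject coords on the element
                left_first = hi.s_start <= 2 and te_len - hj.s_end <= 2
                right_first = hj.s_start <= 2 and te_len - hi.s_end <= 2
                if (hi.length + hj.length) < full_copy_coverage * te_len and (
                    left_first or right_first
                ):
                    out.append(
                        TeAnnotation(
                            te_id=te_id,
                            start=hi.q_start,
                            end=hj.q_end,
                            strand=hi.strand,
                            kind="composite_footprint",
                            end_composition=(hi.length, hj.length),
                        )
                    )
                    used[i] = used[j] = True
        for i, h in enumerate(hits):
            if used[i]:
                continue
            kind = "full_copy" if h.length >= full_copy_coverage * te_len else "fragment"
            out.append(
                TeAnnotation(
                    te_id=te_id,
                    start=h.q_start,
                    end=h.q_end,
                    strand=h.strand,
                    kind=kind,
                )
            )
    return sorted(out, key=lambda a: a.start)


def find_tsds(
    junction_seq: str,
    te: TeAnnotation,
    tsd_len_range: tuple[int, int] = (4, 12),
) -> TsdCandidates:
    """Flanking words of each length in range bordering a TE match."""
    lo, hi = tsd_len_range
    if not (0 <= te.start <= te.end <= len(junction_seq)):
        raise ValueError("TE annotation outside junction sequence")
    left: dict[int, str] = {}
    right: dict[int, str] = {}
    left_missing = te.start < lo
    right_missing = len(junction_seq) - te.end < lo
    for L in range(lo, hi + 1):
        if te.start >= L:
            left[L] = junction_seq[te.start - L : te.start]
        if len(junction_seq) - te.end >= L:
            right[L] = junction_seq[te.end : te.end + L]
    return TsdCandidates(left=left, right=right, edge_flags=(left_missing, right_missing))


def detect_exchanged_tsd(
    distal: TsdCandidates, proximal: TsdCandidates
) -> TsdEvidence:
    """Test the cross reverse-complement relation between junction flanks.

    Exchange holds when, for some word length, the two junctions' flanking
    words are reverse complements of each other — either same-side
    (distal_left = revcomp(proximal_left) and distal_right =
    revcomp(proximal_right)) or crossed (distal_left =
    revcomp(proximal_right) and proximal_left = revcomp(distal_right)).
    Matching is exact.
    """
    lengths = sorted(
        set(distal.left) & set(distal.right) & set(proximal.left) & set(proximal.right),
        reverse=True,
    )
    for L in lengths:
        dl, dr = distal.left[L], distal.right[L]
        pl, pr = proximal.left[L], proximal.right[L]
        same_side = dl == reverse_complement(pl) and dr == reverse_complement(pr)
        crossed = dl == reverse_complement(pr) and pl == reverse_complement(dr)
        if same_side or crossed:
            return TsdEvidence(
                distal_left=dl,
                distal_right=dr,
                proximal_left=pl,
                proximal_right=pr,
                exchanged=True,
            )
    L = lengths[0] if lengths else None
    if L is None:
        return TsdEvidence()
    return TsdEvidence(
        distal_left=distal.left[L],
        distal_right=distal.right[L],
        proximal_left=proximal.left[L],
        proximal_right=proximal.right[L],
        exchanged=False,
    )


def detect_inverted_duplications(
    ac_seq: str,
    bd_seq: str,
    cfg: Optional[ConfigDefaults] = None,
) -> list[DuplicationBlock]:
    """Similarity blocks between the two junctions, chained into segments.

    Local blocks at e-value <= ``cfg.invdup_evalue`` are reported with
    orientation; blocks on the same orientation whose AC coordinates lie
    within ``cfg.dup_chain_gap`` of each other are chained into one
    duplication segment (deletions fragment one copy into several blocks).
    """
    cfg = cfg or ConfigDefaults()
    # generous X-drop: divergence estimation needs blocks that run through
    # mismatch-dense stretches instead of truncating at them
    raw = local_search(ac_seq, bd_seq, max_evalue=cfg.invdup_evalue, xdrop=120.0)
    blocks = [
        DuplicationBlock(
            ac_start=h.q_start,
            ac_end=h.q_end,
            bd_start=h.s_start,
            bd_end=h.s_end,
            orientation="inverted" if h.strand == "-" else "direct",
            length=h.length,
            pct_identity=h.identity,
            evalue=h.evalue,
        )
        for h in raw
    ]
    chained: list[DuplicationBlock] = []
    for orientation in ("inverted", "direct"):
        group = sorted(
            (b for b in blocks if b.orientation == orientation),
            key=lambda b: b.ac_start,
        )
        cur: Optional[DuplicationBlock] = None
        for b in group:
            if cur is not None and b.ac_start - cur.ac_end <= cfg.dup_chain_gap:
                total = cur.length + b.length
                cur = DuplicationBlock(
                    ac_start=cur.ac_start,
                    ac_end=max(cur.ac_end, b.ac_end),
                    bd_start=min(cur.bd_start, b.bd_start),
                    bd_end=max(cur.bd_end, b.bd_end),
                    orientation=orientation,
                    length=total,
                    pct_identity=(
                        cur.pct_identity * cur.length + b.pct_identity * b.length
                    )
                    / total,
                    evalue=min(cur.evalue, b.evalue),
                )
            else:
                if cur is not None:
                    chained.append(cur)
                cur = b
        if cur is not None:
            chained.append(cur)
    return sorted(chained, key=lambda b: (-b.length, b.ac_start))


def estimate_inversion_age(
    blocks: Sequence[DuplicationBlock],
    rate: float,
    jukes_cantor: bool = True,
) -> float:
    """Date an inversion from the divergence of its duplicated junctions.

    Pools the per-block identities (noncoding blocks only; filter before
    calling) into a length-weighted p-distance, corrects it with
    Jukes-Cantor (optional flag for the raw distance) and returns
    K / (2 * rate): both copies accumulate substitutions independently
    since the inversion arose.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    total = sum(b.length for b in blocks)
    if total == 0:
        raise ValueError("no aligned sites")
    p = sum(b.length * (1.0 - b.pct_identity / 100.0) for b in blocks) / total
    if jukes_cantor:
        if p >= 0.75:
            raise ValueError("divergence saturated; Jukes-Cantor undefined")
        k = -0.75 * log(1.0 - 4.0 * p / 3.0)
    else:
        k = p
    return k / (2.0 * rate)


def classify_mechanism(
    tsd: Optional[TsdEvidence],
    dups: Sequence[DuplicationBlock],
    preexisting_dup: bool = False,
    rate: float = 0.0111,
    min_dup_length: int = 45,
) -> MechanismCall:
    """Label an inversion's generation mechanism from junction evidence.

    Exchanged TSDs take precedence (ectopic recombination); otherwise
    inverted duplications absent from the parental arrangement indicate
    staggered breaks repaired by NHEJ, and the duplication divergence dates
    the event.  Duplications also present in the parental genome are
    preexisting, not mechanism evidence.
    """
    if tsd is not None and tsd.exchanged:
        return MechanismCall(
            label="ectopic_recombination",
            evidence=(
                f"exchanged TSDs {tsd.distal_left}/{tsd.distal_right} vs "
                f"{tsd.proximal_left}/{tsd.proximal_right}"
            ),
            preexisting_duplication=preexisting_dup,
        )
    inverted = [
        b for b in dups if b.orientation == "inverted" and b.length >= min_dup_length
    ]
    if inverted and not preexisting_dup:
        try:
            age = estimate_inversion_age(inverted, rate)
        except ValueError:
            age = None
        return MechanismCall(
            label="staggered_ssb_nhej",
            evidence=f"{len(inverted)} inverted duplication segment(s), "
            f"{sum(b.length for b in inverted)} bp",
            age_myr=age,
        )
    return MechanismCall(
        label="undetermined",
        evidence="no exchanged TSDs, no inversion-associated inverted duplications",
        preexisting_duplication=preexisting_dup,
    )


_KIND_PRIORITY = {"full_copy": 0, "composite_footprint": 1, "fragment": 2}


def principal_te(annotations: Sequence[TeAnnotation]) -> Optional[TeAnnotation]:
    """The annotation most plausibly the junction's causal element."""
    if not annotations:
        return None
    return min(
        annotations, key=lambda a: (_KIND_PRIORITY[a.kind], -(a.end - a.start))
    )


def classify_junctions(
    ac_seq: str,
    bd_seq: str,
    te_library: Optional[dict[str, str]] = None,
    parent_ab_seq: Optional[str] = None,
    parent_cd_seq: Optional[str] = None,
    cfg: Optional[ConfigDefaults] = None,
) -> MechanismCall:
    """Full evidence chain for one inversion's pair of junction windows.

    Annotates TEs in both junctions, tests their flanks for TSD exchange,
    detects inverted duplications between the junctions, checks the
    parental windows for preexisting duplications, and classifies.
    """
    cfg = cfg or ConfigDefaults()
    tsd_evidence: Optional[TsdEvidence] = None
    if te_library:
        te_ac = principal_te(
            annotate_te_fragments(ac_seq, te_library, min_match=cfg.te_min_match)
        )
        te_bd = principal_te(
            annotate_te_fragments(bd_seq, te_library, min_match=cfg.te_min_match)
        )
        if te_ac is not None and te_bd is not None:
            rng = (cfg.tsd_len_min, cfg.tsd_len_max)
            tsd_evidence = detect_exchanged_tsd(
                find_tsds(ac_seq, te_ac, rng), find_tsds(bd_seq, te_bd, rng)
            )
    dups = detect_inverted_duplications(ac_seq, bd_seq, cfg)
    preexisting = False
    if parent_ab_seq and parent_cd_seq and dups:
        parent_dups = detect_inverted_duplications(parent_ab_seq, parent_cd_seq, cfg)
        preexisting = any(
            b.orientation == "inverted" and b.length >= 45 for b in parent_dups
        )
    return classify_mechanism(
        tsd_evidence, dups, preexisting_dup=preexisting, rate=cfg.neutral_rate
    )
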