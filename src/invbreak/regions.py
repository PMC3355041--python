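"""Breakpoint-region delimitation, pairing, narrowing and refinement.

Breakpoint regions start as the target-genome intervals between adjacent
syntenic segments (last marker of one segment to first marker of the next).
The two regions of one inversion are associated by replaying an optimal
sorting scenario and mapping each reversal's two cut sites back into the
final target frame.  Regions are then narrowed by locating where similarity
to the outgroup (ancestral-arrangement) junction sequences is lost, and
finally refined by excising the coding spans of structure-conserved
orthologs so that breakpoints are confined to intergenic space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .alignment import local_search, protein_align
from .config import ConfigDefaults
from .rearrangement import Reversal, SignedPermutation, apply_reversal
from .segmentation import SyntenicSegment
from .simulate import GeneModel

__all__ = [
    "BreakpointRegion",
    "OrthologPair",
    "initial_regions",
    "pair_breakpoints",
    "narrow_by_outgroup",
    "refine_by_orthologs",
    "reciprocal_best_hit",
]


@dataclass(frozen=True)
class BreakpointRegion:
    """Inter-segment interval on the target chromosome.

    ``side`` is assigned when the region is paired with its inversion:
    ``distal_AC`` for the higher-coordinate junction and ``proximal_BD``
    for the lower one (coordinates begin at the centromere, so higher
    coordinate means more distal).
    """

    region_id: int
    start: int
    end: int  # 0-based half-open
    inversion_ids: tuple[str, ...] = ()
    side: str = ""
    narrowed_start: Optional[int] = None
    narrowed_end: Optional[int] = None
    narrowed: bool = False
    refined: bool = False
    zero_length: bool = False
    flanking_genes: tuple[str, str] = ("", "")

    @property
    def initial_size(self) -> int:
        return self.end - self.start

    @property
    def narrowed_size(self) -> int:
        if self.narrowed_start is None or self.narrowed_end is None:
            return self.initial_size
        return self.narrowed_end - self.narrowed_start


@dataclass(frozen=True)
class OrthologPair:
    gene_id_a: str
    gene_id_b: str
    score: float
    mutual: bool


def initial_regions(segments: Sequence[SyntenicSegment]) -> list[BreakpointRegion]:
    """One region per adjacent segment pair, marker-to-marker."""
    if len(segments) < 2:
        raise ValueError("need at least two segments")
    ordered = sorted(segments, key=lambda s: s.target_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.target_start < a.target_end:
            raise ValueError(f"segments {a.index}, {b.index} overlap")
    out = []
    for k, (a, b) in enumerate(zip(ordered, ordered[1:]), start=1):
        out.append(
            BreakpointRegion(
                region_id=k,
                start=a.target_end,
                end=b.target_start,
                zero_length=(b.target_start == a.target_end),
            )
        )
    return out


def _gap_through_reversal(gap: int, r: Reversal) -> int:
    """Map a gap index (between positions gap, gap+1) through a reversal."""
    if r.i <= gap <= r.j - 1:
        return r.i + r.j - 1 - gap
    return gap


def pair_breakpoints(
    regions: Sequence[BreakpointRegion],
    scenario: Sequence[Reversal],
    permutation: SignedPermutation,
) -> list[BreakpointRegion]:
    """Assign inversion ids and distal/proximal sides to regions.

    ``scenario`` must sort ``permutation`` (the target chromosome in source
    labels) to the identity.  The t-th reversal acts on an intermediate
    arrangement; its two cut sites are mapped back through the earlier
    reversals into the final target frame, where they index the
    inter-segment gaps, i.e. the regions.  A reused gap collects the ids of
    every inversion cutting it.
    """
    n = permutation.n
    if len(regions) != n - 1:
        raise ValueError("expected one region per internal segment gap")
    cur = permutation
    for r in scenario:
        cur = apply_reversal(cur, r)
    if not cur.is_identity:
        raise ValueError("scenario does not sort the permutation to identity")
    gap_to_invs: dict[int, list[str]] = {}
    for t, r in enumerate(scenario):
        for gap in (r.i - 1, r.j):
            g = gap
            for prev in reversed(scenario[:t]):
                g = _gap_through_reversal(g, prev)
            if 1 <= g <= n - 1:  # gaps 0 and n are the chromosome ends
                gap_to_invs.setdefault(g, []).append(f"inv{t + 1:02d}")
    out = []
    for region in sorted(regions, key=lambda rg: rg.start):
        invs = tuple(gap_to_invs.get(region.region_id, ()))
        out.append(replace(region, inversion_ids=invs))
    # distal/proximal per inversion by target coordinate
    by_inv: dict[str, list[int]] = {}
    for idx, region in enumerate(out):
        for inv in region.inversion_ids:
            by_inv.setdefault(inv, []).append(idx)
    sides: dict[int, str] = {}
    for inv, idxs in by_inv.items():
        if len(idxs) >= 2:
            hi = max(idxs, key=lambda i: out[i].start)
            lo = min(idxs, key=lambda i: out[i].start)
            sides.setdefault(hi, "distal_AC")
            sides.setdefault(lo, "proximal_BD")
    return [
        replace(region, side=sides.get(idx, region.side))
        for idx, region in enumerate(out)
    ]


def _merge_intervals(iv: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for a, b in iv[1:]:
        if a - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def mask_repeats(seq: str, te_library: dict[str, str]) -> str:
    """N-mask TE-library matches, mimicking a repeat-masked genome.

    Repeats present at both parental loci otherwise produce conflicting
    similarity chains across a junction.
    """
    arr = list(seq)
    for te_seq in te_library.values():
        for h in local_search(seq, te_seq, max_evalue=1e-3):
            arr[h.q_start : h.q_end] = "N" * (h.q_end - h.q_start)
    return "".join(arr)


def narrow_by_outgroup(
    region_seq: str,
    outgroup_ab_seq: str,
    outgroup_cd_seq: str,
    cfg: Optional[ConfigDefaults] = None,
    te_library: Optional[dict[str, str]] = None,
) -> tuple[int, int, bool]:
    """Narrow a breakpoint region to where outgroup similarity is lost.

    Local matches of the region against each outgroup junction window
    (e-value at most ``cfg.max_evalue_outgroup``) are tiled along the
    region; tiles closer than ``cfg.tile_merge_gap`` are merged; the new
    breakpoint limits are the end of the similarity chain anchored at the
    region start and the start of the chain anchored at the region end.
    When ``te_library`` is given, repeats are N-masked in all sequences
    first (the comparative protocol runs against repeat-masked genomes).
    Returns ``(start, end, narrowed)`` on region coordinates; with no
    similarity at all the region is returned unchanged with a warning and
    ``narrowed=False``.
    """
    cfg = cfg or ConfigDefaults()
    n = len(region_seq)
    if te_library:
        region_seq = mask_repeats(region_seq, te_library)
        outgroup_ab_seq = mask_repeats(outgroup_ab_seq, te_library)
        outgroup_cd_seq = mask_repeats(outgroup_cd_seq, te_library)
    per_side: list[list[tuple[int, int]]] = []
    for out_seq in (outgroup_ab_seq, outgroup_cd_seq):
        tiles = [
            (h.q_start, h.q_end)
            for h in local_search(
                region_seq, out_seq, max_evalue=cfg.max_evalue_outgroup
            )
        ]
        per_side.append(_merge_intervals(tiles, cfg.tile_merge_gap))
    if not any(per_side):
        warnings.warn("no outgroup similarity; region not narrowed")
        return 0, n, False
    gap = cfg.tile_merge_gap
    # similarity loss: the end of the similarity chain anchored at the
    # region start and the start of the chain anchored at the region end;
    # breakpoint limits are where those chains stop
    prefix_end = 0
    suffix_start = n
    for merged in per_side:
        for a, b in merged:
            if a <= gap and b > prefix_end:
                prefix_end = b
            if n - b <= gap and a < suffix_start:
                suffix_start = a
    if prefix_end == 0 and suffix_start == n:
        warnings.warn("outgroup similarity not anchored at region edges")
        return 0, n, False
    if prefix_end <= suffix_start:
        return prefix_end, suffix_start, True
    # conflicting overlap of the two chains: collapse to its midpoint
    mid = (suffix_start + prefix_end) // 2
    return mid, mid, True


def refine_by_orthologs(
    region: BreakpointRegion,
    genes: Sequence[GeneModel],
    orthologs: Sequence[OrthologPair],
    ortholog_genes: Optional[dict[str, GeneModel]] = None,
    span_tolerance: float = 0.25,
) -> BreakpointRegion:
    """Excise structure-conserved ortholog coding spans from region edges.

    A gene overlapping a region edge whose mutual-best ortholog has the
    same exon count and a similar span (within ``span_tolerance``
    relative difference) is still ancestral coding sequence, not junction
    DNA, so its overlap is cut off the region.  Refinement never extends
    the region and is idempotent; a conserved gene spanning the whole
    region leaves it unchanged (flagged unrefinable upstream by the
    caller inspecting sizes).
    """
    start = region.narrowed_start if region.narrowed_start is not None else region.start
    end = region.narrowed_end if region.narrowed_end is not None else region.end
    mutual = {p.gene_id_a: p.gene_id_b for p in orthologs if p.mutual}
    changed = False
    for g in sorted(genes, key=lambda g: g.start):
        if g.end <= start or g.start >= end:
            continue
        partner_id = mutual.get(g.gene_id)
        if partner_id is None:
            continue
        if ortholog_genes is not None:
            partner = ortholog_genes.get(partner_id)
            if partner is None:
                continue
            if len(partner.exons) != len(g.exons):
                continue
            span_g, span_p = g.end - g.start, partner.end - partner.start
            if abs(span_g - span_p) > span_tolerance * max(span_g, span_p):
                continue
        if g.start <= start < g.end and g.end < end:
            start = g.end
            changed = True
        elif start < g.start and g.end >= end:
            end = g.start
            changed = True
        # a conserved gene spanning the entire region: leave unchanged
    return replace(
        region,
        narrowed_start=start,
        narrowed_end=end,
        refined=region.refined or changed,
    )


def reciprocal_best_hit(
    genes_a: dict[str, str], genes_b: dict[str, str]
) -> list[OrthologPair]:
    """Mutual-best-scoring protein pairs between two gene sets."""
    if not genes_a or not genes_b:
        return []
    best_ab: dict[str, tuple[str, float]] = {}
    best_ba: dict[str, tuple[str, float]] = {}
    for ida, sa in genes_a.items():
        for idb, sb in genes_b.items():
            _, _, score = protein_align(sa, sb)
            if score <= 0:
                continue
            if ida not in best_ab or score > best_ab[ida][1]:
                best_ab[ida] = (idb, score)
            if idb not in best_ba or score > best_ba[idb][1]:
                best_ba[idb] = (ida, score)
    out = []
    for ida, (idb, score) in sorted(best_ab.items()):
        if best_ba.get(idb, (None,))[0] == ida:
            out.append(OrthologPair(ida, idb, score, mutual=True))
    return out
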