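"""Synthetic chromosome evolution with mechanism-specific inversion junctions.

The generator emulates a comparative-mapping experiment: a ~34 Mb ancestral
chromosome carries ordered markers (one every ~13.8 kb on average, placed by
an exponential renewal process) and optionally gene models.  Inversion
scenarios are applied with per-junction mechanism structure:

* ``te_ectopic`` — ectopic recombination between two TE copies in opposite
  orientation leaves a chimeric TE copy at each junction bounded by
  exchanged target-site duplications (each junction's TSDs are the reverse
  complements of the other junction's);
* ``staggered_ssb`` — staggered single-strand breaks repaired by NHEJ leave
  inverted duplications of originally single-copy DNA at the two junctions
  (the displaced copy may subsequently be eroded by deletions);
* ``clean_dsb`` — blunt double-strand breaks leave no signature.

Marker tables are emitted in BLAST tabular form with configurable dropout
and spurious (orphan) relocations; sequence-level simulation is confined to
windows around junctions.  Every operation takes an explicit seed and is
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import revcomp
from .config import ParameterError
from .rearrangement import Reversal, SignedPermutation, apply_reversal

__all__ = [
    "AncestralChromosome",
    "GeneModel",
    "MechanismSpec",
    "InversionEvent",
    "TruthRecord",
    "JunctionWindows",
    "TwoLineageScenario",
    "simulate_ancestor",
    "apply_inversion_scenario",
    "evolve_sequences",
    "emit_marker_hits",
    "marker_map",
    "junction_windows",
    "two_lineage_permutation",
    "simulate_comparative_map",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    start: int
    end: int  # 0-based half-open
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParameterError(f"bad gene interval {self.gene_id}")
        for a, b in self.exons:
            if not (self.start <= a < b <= self.end):
                raise ParameterError(f"exon outside gene span in {self.gene_id}")


@dataclass(frozen=True)
class AncestralChromosome:
    """A marker-bearing chromosome; coordinates 0-based half-open."""

    length: int
    markers: tuple[tuple[str, int], ...]  # (marker_id, position), sorted
    strands: tuple[str, ...] = ()
    genes: tuple[GeneModel, ...] = ()
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        pos = [p for _, p in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ParameterError("marker positions must be strictly increasing")
        if pos and not (0 <= pos[0] and pos[-1] < self.length):
            raise ParameterError("marker positions out of chromosome bounds")
        if not self.strands:
            object.__setattr__(self, "strands", tuple("+" for _ in self.markers))
        for g in self.genes:
            if g.end > self.length:
                raise ParameterError(f"gene {g.gene_id} outside chromosome")


MechanismKind = Literal["te_ectopic", "staggered_ssb", "clean_dsb"]


@dataclass(frozen=True)
class MechanismSpec:
    """How an inversion's junctions are structured."""

    kind: MechanismKind
    tsd_length: int = 9
    te_id: str = "TE1"
    dup_length_distal: int = 0
    dup_length_proximal: int = 0
    deletion_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("te_ectopic", "staggered_ssb", "clean_dsb"):
            raise ParameterError(f"unknown mechanism kind {self.kind!r}")
        if self.tsd_length < 0 or self.dup_length_distal < 0 or self.dup_length_proximal < 0:
            raise ParameterError("TSD/duplication lengths must be >= 0")
        if not (0.0 <= self.deletion_fraction <= 1.0):
            raise ParameterError("deletion_fraction must be in [0, 1]")


@dataclass(frozen=True)
class InversionEvent:
    inversion_id: str
    lineage: str
    start: int
    end: int  # bp, half-open, frame at time of application
    mechanism: MechanismSpec
    tsd_distal: str = ""  # TSDs recorded for te_ectopic only
    tsd_proximal: str = ""
    dup_intervals: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class TruthRecord:
    scenario: tuple[InversionEvent, ...]
    distinct_breakpoints: int
    reused_breakpoints: int

    def __post_init__(self) -> None:
        expected = 2 * len(self.scenario) - self.distinct_breakpoints
        if expected != self.reused_breakpoints:
            raise ParameterError("reuse bookkeeping violated: reused != 2d - distinct")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_ancestor(
    length: int,
    marker_spacing_mean: float,
    n_genes: int = 0,
    seed: int = 0,
    with_sequence: bool = False,
) -> AncestralChromosome:
    """Ancestral chromosome with renewal-process marker placement.

    Markers are dropped with exponential inter-arrival distances of the
    given mean, which spreads them homogeneously along the chromosome with
    natural (Poisson) variance in local density.
    """
    if length <= 0:
        raise ParameterError("length must be positive")
    if marker_spacing_mean <= 0:
        raise ParameterError("marker_spacing_mean must be positive")
    rng = np.random.default_rng(seed)
    positions = []
    x = rng.exponential(marker_spacing_mean)
    while x < length:
        positions.append(int(x))
        x += max(1.0, rng.exponential(marker_spacing_mean))
    # renewal floors could collide after int(); deduplicate conservatively
    positions = sorted(set(positions))
    markers = tuple((f"m{i + 1:05d}", p) for i, p in enumerate(positions))
    genes: list[GeneModel] = []
    if n_genes > 0:
        starts = np.sort(rng.integers(0, max(1, length - 20_000), size=n_genes))
        cursor = 0
        for i, s in enumerate(starts):
            s = int(max(s, cursor))
            glen = int(500 + rng.exponential(2_000))
            e = min(s + glen, length)
            if e - s < 200 or e > length:
                continue
            n_ex = int(rng.integers(1, 6))
            bounds = np.sort(rng.choice(np.arange(s + 1, e), size=2 * n_ex - 2, replace=False)) if e - s > 2 * n_ex else np.array([], dtype=int)
            edges = [s, *bounds.tolist(), e]
            exons = tuple((edges[k], edges[k + 1]) for k in range(0, len(edges) - 1, 2))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{i + 1:04d}", s, e, strand, exons))
            cursor = e + 1
    return AncestralChromosome(length=length, markers=markers, genes=tuple(genes))


def _invert_point(x: int, s: int, e: int) -> int:
    return s + e - 1 - x if s <= x < e else x


def _invert_interval(a: int, b: int, s: int, e: int) -> tuple[int, int]:
    if s <= a and b <= e:
        return s + e - b, s + e - a
    return a, b


def apply_inversion_scenario(
    chrom: AncestralChromosome,
    scenario: Sequence[tuple[int, int, MechanismSpec]],
    seed: int = 0,
    lineage: str = "A",
) -> tuple[AncestralChromosome, TruthRecord]:
    """Apply inversions sequentially, tracking junctions and mechanisms.

    Each scenario entry is ``(start, end, mechanism)`` in bp on the evolving
    chromosome (half-open).  Breakpoint reuse is counted by tracking
    junction boundary coordinates forward through subsequent inversions: a
    cut that lands exactly on an existing junction is a reuse.
    """
    rng = np.random.default_rng(seed)
    markers = [(mid, pos) for mid, pos in chrom.markers]
    strands = list(chrom.strands)
    genes = list(chrom.genes)
    junctions: set[int] = set()
    reused = 0
    events: list[InversionEvent] = []
    for idx, (s, e, mech) in enumerate(scenario):
        if not (0 <= s < e <= chrom.length):
            raise ParameterError(f"inversion interval ({s}, {e}) out of bounds")
        if e - s == 0:
            raise ParameterError("zero-length inversion interval")
        for cut in (s, e):
            if cut in junctions:
                reused += 1
            junctions.add(cut)
        junctions = {s + e - j if s < j < e else j for j in junctions}
        order = np.argsort([p for _, p in markers], kind="stable")
        new_markers = []
        new_strands = []
        for mid_pos, strand in zip(markers, strands):
            mid, pos = mid_pos
            if s <= pos < e:
                new_markers.append((mid, _invert_point(pos, s, e)))
                new_strands.append("-" if strand == "+" else "+")
            else:
                new_markers.append((mid, pos))
                new_strands.append(strand)
        markers, strands = new_markers, new_strands
        new_genes = []
        for g in genes:
            if s <= g.start and g.end <= e:
                ns, ne = _invert_interval(g.start, g.end, s, e)
                exons = tuple(sorted(_invert_interval(a, b, s, e) for a, b in g.exons))
                new_genes.append(
                    GeneModel(g.gene_id, ns, ne, "-" if g.strand == "+" else "+", exons)
                )
            else:
                new_genes.append(g)  # genes straddling a cut are left; cuts are intergenic in this model
        genes = new_genes
        tsd_d = tsd_p = ""
        dup_iv: tuple[tuple[int, int], ...] = ()
        if mech.kind == "te_ectopic" and mech.tsd_length > 0:
            tsd_d = _random_seq(rng, mech.tsd_length)
            tsd_p = _random_seq(rng, mech.tsd_length)
        elif mech.kind == "staggered_ssb":
            dup_iv = tuple(
                iv
                for iv in (
                    (s, s + mech.dup_length_distal) if mech.dup_length_distal else None,
                    (e - mech.dup_length_proximal, e) if mech.dup_length_proximal else None,
                )
                if iv
            )
        events.append(
            InversionEvent(
                inversion_id=f"inv{idx + 1:02d}",
                lineage=lineage,
                start=s,
                end=e,
                mechanism=mech,
                tsd_distal=tsd_d,
                tsd_proximal=tsd_p,
                dup_intervals=dup_iv,
            )
        )
    order = np.argsort([p for _, p in markers], kind="stable")
    markers_sorted = tuple(markers[i] for i in order)
    strands_sorted = tuple(strands[i] for i in order)
    derived = AncestralChromosome(
        length=chrom.length,
        markers=markers_sorted,
        strands=strands_sorted,
        genes=tuple(sorted(genes, key=lambda g: g.start)),
        sequence=None,
    )
    truth = TruthRecord(
        scenario=tuple(events),
        distinct_breakpoints=len(junctions),
        reused_breakpoints=reused,
    )
    return derived, truth


def evolve_sequences(
    seqs: Sequence[str], rate: float, time: float, seed: int = 0
) -> list[str]:
    """Neutral independent-site substitution for ``time`` myr at ``rate``.

    Each site differs from its ancestor with the Jukes-Cantor probability
    p = 3/4 (1 - exp(-4 rt / 3)); a substituted site takes one of the three
    other bases uniformly.
    """
    if rate < 0 or time < 0:
        raise ParameterError("rate and time must be non-negative")
    rng = np.random.default_rng(seed)
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * rate * time / 3.0))
    out = []
    lookup = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    for seq in seqs:
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise ParameterError(f"non-nucleotide characters: {sorted(bad)}")
        if p_diff == 0.0:
            out.append(seq)
            continue
        arr = list(seq.upper())
        hit = np.flatnonzero(rng.random(len(arr)) < p_diff)
        choices = rng.integers(0, 3, size=hit.size)
        for i, c in zip(hit, choices):
            if arr[i] != "N":
                arr[i] = lookup[arr[i]][c]
        out.append("".join(arr))
    return out


def marker_map(chrom: AncestralChromosome) -> pd.DataFrame:
    """Physical-map order of markers: marker_id -> 1-based source rank."""
    return pd.DataFrame(
        {
            "marker_id": [mid for mid, _ in chrom.markers],
            "source_rank": np.arange(1, len(chrom.markers) + 1),
        }
    )


def emit_marker_hits(
    derived: AncestralChromosome,
    dropout: float = 0.0,
    orphan_rate: float = 0.0,
    seed: int = 0,
    target_id: str = "chr2",
) -> pd.DataFrame:
    """BLAST-tabular marker hit table for the derived chromosome.

    One row per surviving marker, with e-value / length / identity drawn
    from configured distributions resembling the emulated mapping regime
    (identity ~83%, lengths a few hundred bp).  With probability
    ``orphan_rate`` a marker's hit is relocated to a uniform random
    coordinate, making it a spurious (orphan) placement; with probability
    ``dropout`` the marker is omitted.  Coordinates are 1-based inclusive,
    minus-strand hits have sstart > send.
    """
    if not (0.0 <= dropout <= 1.0 and 0.0 <= orphan_rate <= 1.0):
        raise ParameterError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for (mid, pos), strand in zip(derived.markers, derived.strands):
        if rng.random() < dropout:
            continue
        length = int(np.clip(np.exp(rng.normal(math.log(400), 0.45)), 60, 1200))
        pident = float(np.clip(rng.normal(83.1, 5.0), 60.0, 100.0))
        evalue = float(10.0 ** (-rng.uniform(21.0, 180.0)))
        if rng.random() < orphan_rate:
            pos = int(rng.integers(0, max(1, derived.length - length)))
            strand = "+" if rng.random() < 0.5 else "-"
        sstart, send = pos + 1, pos + length
        if strand == "-":
            sstart, send = send, sstart
        mismatches = int(round(length * (100.0 - pident) / 100.0))
        rows.append(
            (
                mid,
                target_id,
                round(pident, 2),
                length,
                mismatches,
                0,
                1,
                length,
                sstart,
                send,
                evalue,
                round(2.0 * length - 3.0 * mismatches, 1),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "qseqid",
            "sseqid",
            "pident",
            "length",
            "mismatch",
            "gapopen",
            "qstart",
            "qend",
            "sstart",
            "send",
            "evalue",
            "bitscore",
        ],
    )


# --- junction-window sequence simulation -----------------------------------


@dataclass(frozen=True)
class JunctionWindows:
    """Sequence windows around one inversion's two junctions.

    ``ac``/``bd`` are the derived (inverted-chromosome) junction windows;
    ``ab``/``cd`` the parental-arrangement windows.  ``junction_ac`` and
    ``junction_bd`` are the true junction coordinates within the derived
    windows (0-based offsets of the first post-junction base).
    """

    ac: str
    bd: str
    ab: str
    cd: str
    junction_ac: int
    junction_bd: int
    mechanism: MechanismSpec
    tsd_distal: str = ""
    tsd_proximal: str = ""


def _delete_fraction(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Erode ``fraction`` of a sequence with a few internal deletions."""
    if fraction <= 0 or not seq:
        return seq
    n = len(seq)
    target = int(n * fraction)
    remaining = seq
    guard = 0
    while target > 0 and len(remaining) > 30 and guard < 50:
        guard += 1
        chunk = int(min(target, max(20, rng.integers(50, 400))))
        chunk = min(chunk, len(remaining) - 20)
        if chunk <= 0:
            break
        start = int(rng.integers(0, len(remaining) - chunk))
        remaining = remaining[:start] + remaining[start + chunk :]
        target -= chunk
    return remaining


def junction_windows(
    mech: MechanismSpec,
    seed: int = 0,
    flank: int = 25_000,
    age_myr: float = 0.0,
    rate: float = 0.0111,
    te_library: Optional[dict[str, str]] = None,
    footprint_proximal: Optional[tuple[int, int]] = None,
) -> JunctionWindows:
    """Construct the four junction windows for one inversion.

    The parental chromosome reads ... A|B ... C|D ... ; inverting the B..C
    segment yields junctions AC (distal) and BD (proximal).  Mechanism
    decorations follow the module docstring.  With ``age_myr`` > 0,
    duplicated copies are evolved independently for that time at ``rate``
    (so their pairwise divergence is ~2 x rate x age).

    For ``te_ectopic``, ``footprint_proximal=(left_bp, right_bp)`` replaces
    the proximal TE copy with an excision footprint made of the element's
    two termini.
    """
    rng = np.random.default_rng(seed)
    a = _random_seq(rng, flank)
    b = _random_seq(rng, flank)
    c = _random_seq(rng, flank)
    d = _random_seq(rng, flank)
    if mech.kind == "te_ectopic":
        te_seq = (
            te_library[mech.te_id]
            if te_library and mech.te_id in te_library
            else _random_seq(rng, 981)
        )
        t1 = _random_seq(rng, mech.tsd_length)
        t2 = _random_seq(rng, mech.tsd_length)
        if footprint_proximal:
            fl, fr = footprint_proximal
            te_prox = te_seq[:fl] + te_seq[len(te_seq) - fr :]
        else:
            te_prox = te_seq
        ab = a + t1 + te_seq + t1 + b
        cd = c + t2 + revcomp(te_seq) + t2 + d
        ac = a + t1 + te_seq + revcomp(t2) + revcomp(c)
        bd = revcomp(b) + revcomp(t1) + revcomp(te_prox) + t2 + d
        # the exchange point sits at the far edge of the chimeric element:
        # material up to there derives from one parental locus, beyond it
        # from the other
        return JunctionWindows(
            ac=ac,
            bd=bd,
            ab=ab,
            cd=cd,
            junction_ac=len(a) + mech.tsd_length + len(te_seq),
            junction_bd=len(b) + mech.tsd_length + len(te_prox),
            mechanism=mech,
            tsd_distal=t1,
            tsd_proximal=t2,
        )
    if mech.kind == "staggered_ssb":
        l1 = min(mech.dup_length_distal, flank)
        l2 = min(mech.dup_length_proximal, flank)
        u1 = b[:l1]  # segment spanning the distal cut, duplicated by fill-in
        u2 = c[len(c) - l2 :]  # segment spanning the proximal cut
        if age_myr > 0:
            u1_fill, u1_orig = evolve_sequences(
                [u1, u1], rate, age_myr, seed=int(rng.integers(0, 2**31 - 1))
            )
            u2_fill, u2_orig = evolve_sequences(
                [u2, u2], rate, age_myr, seed=int(rng.integers(0, 2**31 - 1))
            )
        else:
            u1_fill, u1_orig = u1, u1
            u2_fill, u2_orig = u2, u2
        u1_fill = _delete_fraction(u1_fill, mech.deletion_fraction, rng)
        u2_fill = _delete_fraction(u2_fill, mech.deletion_fraction, rng)
        b_derived = u1_orig + b[l1:]
        c_derived = c[: len(c) - l2] + u2_orig
        ab = a + b
        cd = c + d
        ac = a + u1_fill + revcomp(c_derived)
        bd = revcomp(b_derived) + u2_fill + d
        # junction = boundary between distal- and proximal-derived material
        return JunctionWindows(
            ac=ac,
            bd=bd,
            ab=ab,
            cd=cd,
            junction_ac=len(a) + len(u1_fill),
            junction_bd=len(b_derived),
            mechanism=mech,
        )
    # clean_dsb
    return JunctionWindows(
        ac=a + revcomp(c),
        bd=revcomp(b) + d,
        ab=a + b,
        cd=c + d,
        junction_ac=len(a),
        junction_bd=len(b),
        mechanism=mech,
    )


# --- two-lineage scenarios --------------------------------------------------


@dataclass(frozen=True)
class TwoLineageScenario:
    """Segment-level truth for a two-lineage inversion scenario.

    ``relative`` expresses lineage A's chromosome in lineage B's segment
    frame (the permutation a comparative map between the two derived
    genomes would produce); ``lineage_b`` holds B's inversions as reversals
    on its evolving arrangement (the subtractable scenario);
    ``arrangement_a`` is A's chromosome in the ancestral frame.
    """

    relative: SignedPermutation
    arrangement_a: SignedPermutation
    arrangement_b: SignedPermutation
    lineage_a: tuple[Reversal, ...]
    lineage_b: tuple[Reversal, ...]
    distinct_breakpoints: int
    n_inversions: int


def _internal_adjacencies(p: SignedPermutation) -> int:
    # signed adjacency: (u, u+1) reads as preserved ancestral order in
    # either orientation, e.g. (+5, +6) or (-6, -5)
    return sum(1 for u, v in zip(p.values, p.values[1:]) if v == u + 1)


def two_lineage_permutation(
    seed: int,
    n_segments: int = 20,
    n_a: int = 7,
    n_b: int = 3,
    max_tries: int = 1000,
) -> TwoLineageScenario:
    """Draw a two-lineage scenario with one shared (tandem-pair) breakpoint.

    The ancestral chromosome has ``n_segments`` segments delimited by
    ``n_segments - 1`` gaps.  Lineage A receives ``2 * n_a`` gaps for
    ``n_a`` inversions with mutually distinct breakpoints; lineage B
    receives ``2 * n_b - 1`` gaps: a tandem pair sharing its middle
    breakpoint plus independent inversions.  All gaps are used exactly
    once, giving ``n_segments - 1`` distinct breakpoints and exactly one
    reuse.  Degenerate draws (a composition restoring an ancestral
    adjacency, so that the comparative map would not show ``n_segments``
    segments, or an A-side composition without ``2 * n_a`` independent
    breakpoints) are rejected and redrawn.
    """
    n_gaps = n_segments - 1
    if 2 * n_a + 2 * n_b - 1 != n_gaps:
        raise ParameterError(
            "scenario shape requires 2*n_a + 2*n_b - 1 == n_segments - 1"
        )
    rng = np.random.default_rng(seed)
    identity = SignedPermutation(tuple(range(1, n_segments + 1)))
    for _ in range(max_tries):
        gaps = rng.permutation(np.arange(1, n_gaps + 1))
        a_gaps, b_gaps = gaps[: 2 * n_a], np.sort(gaps[2 * n_a :])
        # lineage B: tandem pair on the first three sorted gaps, then pairs
        g1, g2, g3 = (int(x) for x in b_gaps[:3])
        b_revs = [Reversal(g1 + 1, g2), Reversal(g2 + 1, g3)]
        rest = b_gaps[3:]
        for k in range(0, len(rest), 2):
            b_revs.append(Reversal(int(rest[k]) + 1, int(rest[k + 1])))
        # lineage A: random pairing of its gaps
        a_pairs = a_gaps.reshape(n_a, 2)
        a_revs = [Reversal(int(min(x, y)) + 1, int(max(x, y))) for x, y in a_pairs]
        arr_a = identity
        for r in a_revs:
            arr_a = apply_reversal(arr_a, r)
        arr_b = identity
        for r in b_revs:
            arr_b = apply_reversal(arr_b, r)
        # A relative to B: relabel A's segments by their signed position in B
        pos_in_b = {}
        for k, v in enumerate(arr_b.values, start=1):
            pos_in_b[abs(v)] = k if v > 0 else -k
        rel = tuple(
            pos_in_b[abs(v)] if v > 0 else -pos_in_b[abs(v)] for v in arr_a.values
        )
        p_rel = SignedPermutation(rel)
        if _internal_adjacencies(p_rel) != 0:
            continue
        if _internal_adjacencies(arr_a) != n_gaps - 2 * n_a:
            continue
        return TwoLineageScenario(
            relative=p_rel,
            arrangement_a=arr_a,
            arrangement_b=arr_b,
            lineage_a=tuple(a_revs),
            lineage_b=tuple(b_revs),
            distinct_breakpoints=n_gaps,
            n_inversions=n_a + n_b,
        )
    raise RuntimeError("could not draw a non-degenerate scenario")  # pragma: no cover


def simulate_comparative_map(
    seed: int,
    length: int = 34_148_556,
    marker_spacing_mean: float = 13_800.0,
    n_segments: int = 20,
    n_a: int = 7,
    n_b: int = 3,
    dropout: float = 0.0,
    orphan_rate: float = 0.0,
    min_markers_per_segment: int = 12,
    target_id: str = "chr2",
) -> tuple[pd.DataFrame, pd.DataFrame, TwoLineageScenario]:
    """Full synthetic comparative map between two derived genomes.

    Returns ``(hits, physical_map, scenario)``: a BLAST tabular table of
    lineage-B markers located on the lineage-A chromosome, the marker
    physical-map order along the lineage-B chromosome, and the segment-level
    truth.  Segment boundaries are drawn uniformly and redrawn until every
    ancestral segment carries at least ``min_markers_per_segment`` markers,
    matching the emulated regime in which accepted segments are backed by
    at least nine hits.
    """
    rng = np.random.default_rng(seed)
    scen = two_lineage_permutation(int(rng.integers(0, 2**31 - 1)), n_segments, n_a, n_b)
    ancestor = simulate_ancestor(
        length, marker_spacing_mean, seed=int(rng.integers(0, 2**31 - 1))
    )
    positions = np.array([p for _, p in ancestor.markers])
    # boundaries with a minimum separation so every segment holds enough
    # markers: draw in the shrunk interval, then fan out by the separation
    min_sep = int(1.5 * min_markers_per_segment * marker_spacing_mean)
    slack = length - n_segments * min_sep
    if slack <= n_segments:
        raise ParameterError("chromosome too short for the requested segment count")
    for _ in range(200):
        raw = np.sort(rng.choice(np.arange(1, slack), size=n_segments - 1, replace=False))
        bounds = raw + min_sep * np.arange(1, n_segments)
        edges = np.concatenate(([0], bounds, [length]))
        counts = np.histogram(positions, bins=edges)[0]
        if counts.min() >= min_markers_per_segment:
            break
    else:  # pragma: no cover - marker density makes this vanishing
        raise RuntimeError("could not place segment boundaries with enough markers")

    def build_genome(arrangement: SignedPermutation):
        """Markers of a derived genome: (marker_id, position, strand)."""
        out = []
        cursor = 0
        for v in arrangement.values:
            s_idx = abs(v) - 1
            lo, hi = edges[s_idx], edges[s_idx + 1]
            in_seg = [(mid, p) for mid, p in ancestor.markers if lo <= p < hi]
            if v > 0:
                for mid, p in in_seg:
                    out.append((mid, cursor + (p - lo), "+"))
            else:
                for mid, p in reversed(in_seg):
                    out.append((mid, cursor + (hi - 1 - p), "-"))
            cursor += hi - lo
        return out

    genome_a = build_genome(scen.arrangement_a)
    genome_b = build_genome(scen.arrangement_b)
    phys_map = pd.DataFrame(
        {
            "marker_id": [mid for mid, _, _ in genome_b],
            "source_rank": np.arange(1, len(genome_b) + 1),
        }
    )
    derived_a = AncestralChromosome(
        length=length,
        markers=tuple((mid, p) for mid, p, _ in genome_a),
        strands=tuple(s for _, _, s in genome_a),
    )
    # orientation in the hit table is relative between the two genomes
    strand_b = {mid: s for mid, _, s in genome_b}
    rel_strands = tuple(
        "+" if s == strand_b[mid] else "-" for mid, _, s in genome_a
    )
    derived_a = replace(derived_a, strands=rel_strands)
    hits = emit_marker_hits(
        derived_a,
        dropout=dropout,
        orphan_rate=orphan_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
        target_id=target_id,
    )
    return hits, phys_map, scen
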