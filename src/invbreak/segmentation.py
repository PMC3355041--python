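"""Marker-hit filtering and syntenic-segment identification.

A comparative map places ordered markers from a source physical map onto a
target chromosome.  After filtering (e-value, length, single target) and
merging split hits, maximal runs of markers whose source ranks are collinear
along the target (monotone increasing or decreasing) become syntenic
segments; segments backed by fewer than ``min_markers`` markers are
dissolved into orphans unless whitelisted.  Segment orientation follows the
direction of the source order along the target: +1 for increasing, -1 for
decreasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .config import ConfigDefaults

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerHit",
    "SyntenicSegment",
    "filter_hits",
    "merge_marker_hits",
    "call_segments",
    "segment_stats",
    "segments_to_permutation",
]


@dataclass(frozen=True)
class MarkerHit:
    """One filtered similarity match of a marker to the target chromosome."""

    marker_id: str
    source_rank: int
    target_start: int  # 0-based half-open
    target_end: int
    strand: str
    evalue: float
    hit_length: int
    pct_identity: float

    def __post_init__(self) -> None:
        if self.target_end < self.target_start:
            raise ValueError("target_start must be <= target_end")
        if self.evalue < 0 or self.hit_length < 1:
            raise ValueError("bad e-value or hit length")


@dataclass(frozen=True)
class SyntenicSegment:
    """Maximal run of collinear markers with an orientation sign."""

    index: int
    sign: int  # +1 / -1
    target_start: int
    target_end: int
    marker_count: int
    source_rank_span: tuple[int, int]
    marker_ids: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.target_end - self.target_start


def filter_hits(
    hits: pd.DataFrame, cfg: ConfigDefaults, target_id: str
) -> pd.DataFrame:
    """Retain hits passing the mapping thresholds on the accepted target.

    Keeps rows with ``evalue <= max_evalue_map``, ``length >=
    min_hit_length`` and subject equal to ``target_id``.  Markers with hits
    on several subjects are dropped entirely unless all their hits are on
    the accepted target (multi-hit markers confined to the target are kept,
    to be merged downstream).
    """
    if target_id not in set(hits["sseqid"]):
        warnings.warn(f"target {target_id!r} absent from hit table")
        return hits.iloc[0:0].copy()
    multi = hits.groupby("qseqid")["sseqid"].nunique()
    promiscuous = set(multi[multi > 1].index)
    kept = hits[
        (hits["sseqid"] == target_id)
        & (hits["evalue"] <= cfg.max_evalue_map)
        & (hits["length"] >= cfg.min_hit_length)
        & (~hits["qseqid"].isin(promiscuous))
    ].copy()
    n_dropped = len(hits) - len(kept)
    if n_dropped:
        logger.info("filter_hits: dropped %d of %d hits", n_dropped, len(hits))
    return kept.reset_index(drop=True)


def _row_strand(row) -> str:
    return "-" if row["sstart"] > row["send"] else "+"


def merge_marker_hits(hits: pd.DataFrame, max_gap: int = 10_000) -> pd.DataFrame:
    """Concatenate split hits of one marker into a single spanning hit.

    Same-marker, same-strand hits whose target intervals lie within
    ``max_gap`` of each other are merged: the e-value is the minimum, the
    length the sum.  Opposite-strand or distant hits stay separate.
    """
    if hits.empty:
        return hits.copy()
    df = hits.copy()
    df["_strand"] = df.apply(_row_strand, axis=1)
    df["_start"] = df[["sstart", "send"]].min(axis=1)
    df["_end"] = df[["sstart", "send"]].max(axis=1)
    out_rows = []
    for (mid, strand), grp in df.groupby(["qseqid", "_strand"], sort=False):
        grp = grp.sort_values("_start")
        cur = None
        for _, row in grp.iterrows():
            if cur is None:
                cur = row.copy()
                continue
            if row["_start"] - cur["_end"] <= max_gap:
                cur["_end"] = max(cur["_end"], row["_end"])
                cur["evalue"] = min(cur["evalue"], row["evalue"])
                cur["length"] = cur["length"] + row["length"]
                cur["bitscore"] = max(cur["bitscore"], row["bitscore"])
                cur["pident"] = (cur["pident"] + row["pident"]) / 2.0
            else:
                out_rows.append(cur)
                cur = row.copy()
        if cur is not None:
            out_rows.append(cur)
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    plus = out["_strand"] == "+"
    out.loc[plus, "sstart"] = out.loc[plus, "_start"]
    out.loc[plus, "send"] = out.loc[plus, "_end"]
    out.loc[~plus, "sstart"] = out.loc[~plus, "_end"]
    out.loc[~plus, "send"] = out.loc[~plus, "_start"]
    return out.drop(columns=["_strand", "_start", "_end"])


def _hits_frame(
    hits: pd.DataFrame, source_ranks: pd.DataFrame
) -> pd.DataFrame:
    """Normalize a BLAST-tabular frame into marker/rank/position form."""
    rank = dict(zip(source_ranks["marker_id"], source_ranks["source_rank"]))
    df = hits.copy()
    df["_strand"] = df.apply(_row_strand, axis=1)
    df["_start"] = df[["sstart", "send"]].min(axis=1) - 1  # to 0-based
    df["_end"] = df[["sstart", "send"]].max(axis=1)
    df["_rank"] = df["qseqid"].map(rank)
    df = df.dropna(subset=["_rank"])
    df["_rank"] = df["_rank"].astype(int)
    return df.sort_values(["_start", "_rank"], kind="mergesort").reset_index(drop=True)


def call_segments(
    hits: pd.DataFrame,
    source_ranks: pd.DataFrame,
    cfg: Optional[ConfigDefaults] = None,
    whitelist: Iterable[frozenset] = (),
) -> tuple[list[SyntenicSegment], list[str]]:
    """Identify syntenic segments from a filtered, merged hit table.

    Markers are ordered by target coordinate; maximal runs with monotone
    source rank form candidate segments.  Up to ``cfg.k_stray`` interleaved
    out-of-order markers are tolerated inside a run (they become orphans);
    candidates with fewer than ``cfg.min_markers`` markers are dissolved
    into orphans unless their marker set is contained in a whitelist entry.
    Returns ``(segments, orphan_marker_ids)``; segments are sorted by
    target start and pairwise non-overlapping.
    """
    cfg = cfg or ConfigDefaults()
    df = _hits_frame(hits, source_ranks)
    if df["qseqid"].duplicated().any():
        dupes = df.loc[df["qseqid"].duplicated(), "qseqid"].unique()
        raise ValueError(f"duplicate marker ids after merging: {list(dupes)[:5]}")
    markers = list(
        zip(df["qseqid"], df["_rank"], df["_start"].astype(int), df["_end"].astype(int))
    )
    runs: list[list[tuple]] = []
    orphans: list[str] = []
    i = 0
    m = len(markers)
    k_stray = cfg.k_stray
    max_jump = cfg.max_rank_jump

    def continues(last_rank: int, direction: int, rank: int) -> bool:
        step = rank - last_rank
        if direction == 0:
            return 1 <= abs(step) <= max_jump
        return 1 <= step * direction <= max_jump

    while i < m:
        run = [markers[i]]
        direction = 0
        j = i + 1
        while j < m:
            cand = markers[j]
            if continues(run[-1][1], direction, cand[1]):
                if direction == 0:
                    direction = 1 if cand[1] > run[-1][1] else -1
                run.append(cand)
                j += 1
                continue
            # try skipping up to k_stray out-of-order markers
            skipped = []
            jj = j
            resumed = False
            while jj < m and len(skipped) < k_stray:
                skipped.append(markers[jj])
                jj += 1
                if jj < m and continues(run[-1][1], direction, markers[jj][1]):
                    resumed = True
                    break
            if resumed:
                orphans.extend(s[0] for s in skipped)
                j = jj
                continue
            break
        runs.append(run)
        i = j
    whitelist_sets = [frozenset(w) for w in whitelist]
    segments: list[SyntenicSegment] = []
    for run in runs:
        ids = tuple(r[0] for r in run)
        if len(run) < cfg.min_markers:
            if not any(set(ids) <= w for w in whitelist_sets):
                orphans.extend(ids)
                continue
        ranks = [r[1] for r in run]
        sign = 1 if (len(ranks) < 2 or ranks[-1] >= ranks[0]) else -1
        segments.append(
            SyntenicSegment(
                index=0,
                sign=sign,
                target_start=run[0][2],
                target_end=run[-1][3],
                marker_count=len(run),
                source_rank_span=(min(ranks), max(ranks)),
                marker_ids=ids,
            )
        )
    segments.sort(key=lambda s: s.target_start)
    segments = [
        SyntenicSegment(
            index=k + 1,
            sign=s.sign,
            target_start=s.target_start,
            target_end=s.target_end,
            marker_count=s.marker_count,
            source_rank_span=s.source_rank_span,
            marker_ids=s.marker_ids,
        )
        for k, s in enumerate(segments)
    ]
    return segments, orphans


def segment_stats(
    segments: Sequence[SyntenicSegment], chrom_length: int
) -> dict:
    """Coverage summary: total bp, coverage %, missing bp, size-marker r^2."""
    for a, b in zip(segments, segments[1:]):
        if b.target_start < a.target_end:
            raise ValueError(
                f"segments {a.index} and {b.index} overlap on the target"
            )
    total = sum(s.length for s in segments)
    if chrom_length < total:
        raise ValueError("chromosome shorter than total segment span")
    coverage = 100.0 * total / chrom_length if chrom_length else 0.0
    if len(segments) >= 3:
        lengths = [s.length for s in segments]
        counts = [s.marker_count for s in segments]
        r = _stats.linregress(lengths, counts).rvalue
        r2 = float(r * r)
    else:
        r2 = float("nan")
    return {
        "n_segments": len(segments),
        "total_bp": int(total),
        "coverage_pct": coverage,
        "missing_bp": int(chrom_length - total),
        "r_squared": r2,
    }


def segments_to_permutation(segments: Sequence[SyntenicSegment]):
    """Signed permutation of target-order segments renumbered by source order.

    Segments are already in target order; labels are assigned by the order
    of their source-rank spans, so the source (reference) genome defines
    the identity.  Signs come from each segment's orientation.
    """
    from .rearrangement import SignedPermutation

    by_source = sorted(segments, key=lambda s: s.source_rank_span[0])
    label = {s.index: k + 1 for k, s in enumerate(by_source)}
    return SignedPermutation(tuple(s.sign * label[s.index] for s in segments))
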