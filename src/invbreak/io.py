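"""Readers and writers for the pipeline's on-disk formats.

On disk everything is 1-based inclusive (BLAST / GFF3 convention);
internally coordinates are 0-based half-open.  The conversion lives here
and nowhere else.  Writers and readers are mutual inverses on valid data.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .regions import BreakpointRegion
from .segmentation import SyntenicSegment
from .simulate import GeneModel, InversionEvent, TruthRecord

logger = logging.getLogger(__name__)

BLAST_COLUMNS = [
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
]

__all__ = [
    "read_blast_tab",
    "write_blast_tab",
    "read_fasta",
    "write_fasta",
    "read_marker_map",
    "write_marker_map",
    "write_segments",
    "read_segments",
    "write_regions",
    "read_permutation",
    "write_permutation",
    "write_truth",
    "read_gff3",
    "write_gff3",
]


class ParseError(ValueError):
    pass


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular file.

    Strand is implied by sstart > send; coordinates stay 1-based inclusive
    in the returned frame (the segmentation layer normalizes them).
    Raises :class:`ParseError` with the line number on malformed rows.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            rows.append(parts)
    if not rows:
        warnings.warn(f"empty BLAST table: {path}")
        return pd.DataFrame(columns=BLAST_COLUMNS)
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    for col in ("pident", "evalue", "bitscore"):
        df[col] = df[col].astype(float)
    for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        df[col] = df[col].astype(int)
    return df


def write_blast_tab(df: pd.DataFrame, path: str | Path) -> None:
    df = df[BLAST_COLUMNS]
    with Path(path).open("w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.qseqid),
                        str(row.sseqid),
                        f"{row.pident:.2f}",
                        str(int(row.length)),
                        str(int(row.mismatch)),
                        str(int(row.gapopen)),
                        str(int(row.qstart)),
                        str(int(row.qend)),
                        str(int(row.sstart)),
                        str(int(row.send)),
                        f"{row.evalue:.2e}",
                        f"{row.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an ordered ``{id: uppercased sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"empty record {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_marker_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"marker_id", "source_rank"} <= set(df.columns):
        raise ParseError(f"{path}: need columns marker_id, source_rank")
    return df


def write_marker_map(df: pd.DataFrame, path: str | Path) -> None:
    df[["marker_id", "source_rank"]].to_csv(path, sep="\t", index=False)


def write_segments(segments: Sequence[SyntenicSegment], path: str | Path) -> None:
    """Segments TSV, 1-based inclusive coordinates on disk."""
    with Path(path).open("w") as fh:
        fh.write("index\tsign\tstart\tend\tn_markers\trank_min\trank_max\n")
        for s in segments:
            fh.write(
                f"{s.index}\t{s.sign:+d}\t{s.target_start + 1}\t{s.target_end}\t"
                f"{s.marker_count}\t{s.source_rank_span[0]}\t{s.source_rank_span[1]}\n"
            )


def read_segments(path: str | Path) -> list[SyntenicSegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        SyntenicSegment(
            index=int(r["index"]),
            sign=int(r["sign"]),
            target_start=int(r["start"]) - 1,
            target_end=int(r["end"]),
            marker_count=int(r["n_markers"]),
            source_rank_span=(int(r["rank_min"]), int(r["rank_max"])),
        )
        for _, r in df.iterrows()
    ]


def write_regions(regions: Sequence[BreakpointRegion], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "region_id\tinversion_ids\tside\tstart\tend\t"
            "narrowed_start\tnarrowed_end\tstatus\n"
        )
        for r in regions:
            status = ",".join(
                flag
                for flag, on in (
                    ("narrowed", r.narrowed),
                    ("refined", r.refined),
                    ("zero_length", r.zero_length),
                )
                if on
            )
            ns = "" if r.narrowed_start is None else str(r.narrowed_start + 1)
            ne = "" if r.narrowed_end is None else str(r.narrowed_end)
            fh.write(
                f"{r.region_id}\t{';'.join(r.inversion_ids)}\t{r.side}\t"
                f"{r.start + 1}\t{r.end}\t{ns}\t{ne}\t{status}\n"
            )


def read_permutation(path: str | Path):
    from .rearrangement import SignedPermutation

    text = Path(path).read_text().split()
    return SignedPermutation(tuple(int(x) for x in text))


def write_permutation(p, path: str | Path) -> None:
    Path(path).write_text(" ".join(f"{v:+d}" for v in p.values) + "\n")


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    """Scenario truth TSV, one inversion per row, 1-based inclusive."""
    with Path(path).open("w") as fh:
        fh.write(
            "inversion_id\tlineage\tstart\tend\tmechanism\ttsd_distal\t"
            "tsd_proximal\tdup_len_distal\tdup_len_proximal\n"
        )
        for ev in truth.scenario:
            fh.write(
                f"{ev.inversion_id}\t{ev.lineage}\t{ev.start + 1}\t{ev.end}\t"
                f"{ev.mechanism.kind}\t{ev.tsd_distal}\t{ev.tsd_proximal}\t"
                f"{ev.mechanism.dup_length_distal}\t{ev.mechanism.dup_length_proximal}\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Gene models from GFF3: gene features with exon children (by Parent)."""
    genes: dict[str, dict] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", f"gene{lineno}")
                genes[gid] = {
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "exons": [],
                }
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent in genes:
                    genes[parent]["exons"].append((int(start) - 1, int(end)))
    out = []
    for gid, g in genes.items():
        exons = tuple(sorted(g["exons"])) or ((g["start"], g["end"]),)
        out.append(GeneModel(gid, g["start"], g["end"], g["strand"], exons))
    return sorted(out, key=lambda g: g.start)


def write_gff3(genes: Sequence[GeneModel], path: str | Path, seqid: str = "chr2") -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{seqid}\tinvbreak\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, (a, b) in enumerate(g.exons, start=1):
                fh.write(
                    f"{seqid}\tinvbreak\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{k};Parent={g.gene_id}\n"
                )
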