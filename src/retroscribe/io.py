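"""Readers and writers for the standard annotation formats.

GTF/GFF3 and RepeatMasker .out are 1-based inclusive on disk and converted
to 0-based half-open on read; BED is already half-open. Tabular outputs are
TSV with a header line and optional ``#``-prefixed provenance comments.
"""

from __future__ import annotations

import io as _io
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .models import (
    GenomicInterval,
    RepeatFeature,
    TranscriptModel,
    ValidationError,
    ere_class_of,
    ere_subgroup_of,
)


class ParseError(ValueError):
    """A malformed record; the message names the file line number."""


# --------------------------------------------------------------------------
# attribute parsing

def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: malformed GTF attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gff3_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ParseError(f"line {lineno}: malformed GFF3 attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _strip_gff3_prefix(identifier: str) -> str:
    # Ensembl GFF3 uses "transcript:ENST..." / "gene:ENSG..." IDs
    return identifier.split(":", 1)[1] if ":" in identifier else identifier


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting [start, end) pairs."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# --------------------------------------------------------------------------
# transcripts

def read_transcripts(
    path: str | Path,
    dialect: str = "GTF",
    source: str = "reference",
) -> list[TranscriptModel]:
    """Read transcript models from a GTF or GFF3 annotation.

    Exon records are grouped by transcript, converted from 1-based
    inclusive to 0-based half-open coordinates, sorted and merged. CDS
    records, when present, define the CDS span (min start .. max end).
    """
    dialect = dialect.upper()
    if dialect not in ("GTF", "GFF3"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    parse_attrs = _parse_gtf_attributes if dialect == "GTF" else _parse_gff3_attributes

    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    cds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene)
    tid_to_gene: dict[str, str] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"line {lineno}: invalid coordinates {start1}-{end1}")
            attrs = parse_attrs(attr_s, lineno)

            ftype = feature.lower()
            if dialect == "GFF3" and ftype in ("mrna", "transcript"):
                tid = _strip_gff3_prefix(attrs.get("ID", ""))
                parent = _strip_gff3_prefix(attrs.get("Parent", ""))
                if tid:
                    tid_to_gene[tid] = parent or tid
                continue
            if ftype not in ("exon", "cds"):
                continue

            if dialect == "GTF":
                tid = attrs.get("transcript_id")
                gene = attrs.get("gene_id", "")
            else:
                tid = _strip_gff3_prefix(attrs.get("Parent", ""))
                gene = tid_to_gene.get(tid, "")
            if not tid:
                raise ParseError(f"line {lineno}: record lacks a transcript id")

            span = (start1 - 1, end1)  # 1-based inclusive -> 0-based half-open
            if tid not in meta:
                meta[tid] = (chrom, strand, gene)
                order.append(tid)
            else:
                prev_chrom, prev_strand, prev_gene = meta[tid]
                if prev_chrom != chrom:
                    raise ValidationError(
                        f"transcript {tid}: exons on multiple chromosomes "
                        f"({prev_chrom}, {chrom})"
                    )
                if prev_strand != strand:
                    raise ValidationError(
                        f"transcript {tid}: exons on mixed strands"
                    )
                if not prev_gene and gene:
                    meta[tid] = (chrom, strand, gene)
            if ftype == "exon":
                exons[tid].append(span)
            else:
                cds[tid].append(span)

    out: list[TranscriptModel] = []
    for tid in order:
        chrom, strand, gene = meta[tid]
        spans = _merge_intervals(exons[tid])
        if not spans:
            continue  # CDS-only stub without exon records
        cds_span: Optional[tuple[int, int]] = None
        if tid in cds:
            cds_span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene or tid,
                chrom=chrom,
                strand=strand,
                exons=[GenomicInterval(chrom, s, e, strand) for s, e in spans],
                cds=cds_span,
                source=source,
            )
        )
    return out


def write_transcripts_gtf(
    transcripts: Iterable[TranscriptModel], path: str | Path
) -> None:
    """Write transcript models as GTF (transcript + exon [+ CDS] lines)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            rows = [(t.chrom, "retroscribe", "transcript", t.start + 1, t.end)]
            rows += [
                (t.chrom, "retroscribe", "exon", e.start + 1, e.end) for e in t.exons
            ]
            if t.cds is not None:
                rows.append((t.chrom, "retroscribe", "CDS", t.cds[0] + 1, t.cds[1]))
            for chrom, src, feat, s1, e1 in rows:
                fh.write(
                    f"{chrom}\t{src}\t{feat}\t{s1}\t{e1}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# --------------------------------------------------------------------------
# repeats

_RM_HEADER_TOKENS = ("SW", "score", "bit")


def read_repeats(path: str | Path, dialect: str = "repeatmasker_out") -> list[RepeatFeature]:
    """Read repeat annotations from RepeatMasker .out or BED6."""
    dialect = dialect.lower()
    if dialect in ("repeatmasker_out", "out", "rm"):
        return _read_repeatmasker_out(path)
    if dialect in ("bed6", "bed"):
        return _read_repeats_bed6(path)
    raise ValueError(f"unknown repeat dialect {dialect!r}")


def _read_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.split()[0] in _RM_HEADER_TOKENS:
                continue
            fields = line.split()
            if len(fields) < 14:
                raise ParseError(
                    f"line {lineno}: RepeatMasker rows need >= 14 columns, got {len(fields)}"
                )
            try:
                start1, end1 = int(fields[5]), int(fields[6])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            strand = "+" if fields[8] == "+" else "-"  # 'C' marks the complement
            name, family = fields[9], fields[10]
            feats.append(
                RepeatFeature(
                    interval=GenomicInterval(fields[4], start1 - 1, end1, strand),
                    repeat_name=name,
                    family=family,
                )
            )
    return feats


def _read_repeats_bed6(path: str | Path) -> list[RepeatFeature]:
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"line {lineno}: BED6 rows need 6 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if strand not in ("+", "-", "."):
                raise ParseError(f"line {lineno}: invalid strand {strand!r}")
            family = fields[6] if len(fields) > 6 else ""
            feats.append(
                RepeatFeature(
                    interval=GenomicInterval(chrom, start, end, strand),
                    repeat_name=name,
                    family=family,
                )
            )
    return feats


def write_repeats_bed(repeats: Iterable[RepeatFeature], path: str | Path) -> None:
    """Write repeats as BED6 + a 7th class/family column."""
    with open(path, "w") as fh:
        for r in repeats:
            iv = r.interval
            family = r.family or f"{r.ere_class}/{r.repeat_name}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.repeat_name}\t0\t"
                f"{iv.strand}\t{family}\n"
            )


# --------------------------------------------------------------------------
# FASTA (plain, uncompressed) and TSV

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    comments: Sequence[str] = (),
    index: bool = False,
) -> None:
    """TSV with a header line, preceded by '#'-prefixed provenance comments."""
    buf = _io.StringIO()
    for c in comments:
        buf.write(f"# {c}\n")
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue())


def read_tsv(path: str | Path, index_col: Optional[int] = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
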