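"""Core genomic data model: intervals, transcript models, repeat features.

All coordinates are 0-based half-open internally; conversion from the
1-based inclusive conventions of GTF/GFF3 and RepeatMasker happens only at
the I/O boundary (see :mod:`retroscribe.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


class ValidationError(ValueError):
    """An object violating a model invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."  # '+', '-' or '.' (unstranded)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval [{self.start},{self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """bp of intersection; 0 when chroms differ (strand ignored)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# --- ERE taxonomy -----------------------------------------------------------
#
# RepeatMasker class/family strings -> the four retroelement classes used for
# ERE accounting. Simple repeats, low-complexity, satellites, DNA transposons
# and RNA genes fall into "Other" and are excluded from ERE totals.

ERE_CLASSES = ("LTR", "LINE", "SINE", "SVA", "Other")

_CLASS_PREFIXES = {
    "LTR": "LTR",
    "LINE": "LINE",
    "SINE": "SINE",
    "SVA": "SVA",
    "Retroposon": "SVA",  # RepeatMasker files label SVAs Retroposon/SVA
}

# name prefixes used when only a locus name is available (e.g. BED6 input)
_NAME_PREFIXES = (
    ("AluY", "SINE"), ("AluS", "SINE"), ("AluJ", "SINE"), ("Alu", "SINE"),
    ("FLAM", "SINE"), ("FRAM", "SINE"), ("MIR", "SINE"),
    ("SVA", "SVA"),
    ("L1", "LINE"), ("L2", "LINE"), ("L3", "LINE"), ("CR1", "LINE"),
    ("LINE", "LINE"), ("HAL1", "LINE"),
    ("HERV", "LTR"), ("ERV", "LTR"), ("LTR", "LTR"), ("MER", "LTR"),
    ("MLT", "LTR"), ("MST", "LTR"), ("THE", "LTR"), ("MaLR", "LTR"),
    ("HUERS", "LTR"), ("PRIMA", "LTR"), ("Harlequin", "LTR"),
)

_MALR_NAME_PREFIXES = ("MST", "MLT", "THE")


def ere_class_of(family: Optional[str] = None, name: Optional[str] = None) -> str:
    """Map a RepeatMasker class/family string (or, failing that, a locus
    name) to one of LTR / LINE / SINE / SVA / Other."""
    if family:
        head = family.split("/", 1)[0].strip()
        if head in _CLASS_PREFIXES:
            cls = _CLASS_PREFIXES[head]
            # Retroposon covers more than SVA in principle; only SVA families count
            if head == "Retroposon" and "SVA" not in family and not (
                name and name.startswith("SVA")
            ):
                return "Other"
            return cls
        return "Other"
    if name:
        for prefix, cls in _NAME_PREFIXES:
            if name.startswith(prefix):
                return cls
    return "Other"


def ere_subgroup_of(family: Optional[str] = None, name: Optional[str] = None) -> Optional[str]:
    """LTR subgroup: MaLR (ERVL-MaLR, MST/MLT/THE) or HERV (ERV*/HERV*)."""
    if ere_class_of(family, name) != "LTR":
        return None
    if family and "MaLR" in family:
        return "MaLR"
    if name and any(name.startswith(p) for p in _MALR_NAME_PREFIXES):
        return "MaLR"
    if family and ("ERV" in family or "HERV" in family):
        return "HERV"
    if name and (name.startswith("HERV") or name.startswith("ERV")):
        return "HERV"
    return None


@dataclass(frozen=True)
class RepeatFeature:
    """One ERE locus with RepeatMasker-style taxonomy labels."""

    interval: GenomicInterval
    repeat_name: str
    family: str = ""
    ere_class: str = field(default="")
    subgroup: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.ere_class:
            object.__setattr__(
                self, "ere_class", ere_class_of(self.family or None, self.repeat_name)
            )
            object.__setattr__(
                self, "subgroup", ere_subgroup_of(self.family or None, self.repeat_name)
            )
        if self.ere_class not in ERE_CLASSES:
            raise ValidationError(f"unknown ere_class {self.ere_class!r}")


TRANSCRIPT_SOURCES = ("reference", "denovo", "isoseq")


@dataclass
class TranscriptModel:
    """A stranded exon chain with an optional CDS span.

    Exons must be sorted, non-abutting and pairwise disjoint (a zero-length
    intron is not a splice junction). The CDS, when present, is the genomic
    span from the start codon to the stop codon and both bounds must fall
    inside exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: Optional[tuple[int, int]] = None
    source: str = "reference"

    def __post_init__(self) -> None:
        tid = self.transcript_id
        if not tid:
            raise ValidationError("transcript_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{tid}: transcript strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{tid}: transcript needs >= 1 exon")
        if self.source not in TRANSCRIPT_SOURCES:
            raise ValidationError(f"{tid}: unknown source {self.source!r}")
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValidationError(
                    f"{tid}: exon on {e.chrom} but transcript on {self.chrom}"
                )
            if e.strand not in (".", self.strand):
                raise ValidationError(f"{tid}: exons on mixed strands")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{tid}: exons [{a.start},{a.end}) and [{b.start},{b.end}) "
                    "must be disjoint with a gap"
                )
        if self.cds is not None:
            c0, c1 = self.cds
            if not (c0 < c1):
                raise ValidationError(f"{tid}: empty CDS span")
            if not (self._is_exonic(c0) and self._is_exonic(c1 - 1)):
                raise ValidationError(f"{tid}: CDS bounds fall outside exons")

    def _is_exonic(self, pos: int) -> bool:
        return any(e.start <= pos < e.end for e in self.exons)

    # -- derived geometry ---------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    def introns(self) -> list[GenomicInterval]:
        """Intron intervals in genomic order."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]


def exonic_overlap_bp(t: TranscriptModel, iv: GenomicInterval) -> int:
    """Total bp of intersection between t's exons and iv (strand-agnostic)."""
    if iv.chrom != t.chrom:
        return 0
    return sum(e.overlap_bp(iv) for e in t.exons)
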