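"""Comparison of assembled transcripts against a reference annotation.

A query transcript is tiered as:

* ``full`` — a same-strand reference transcript has the identical intron
  chain (multiexonic) or, for monoexonic queries, reciprocal overlap of at
  least ``monoexonic_reciprocal_min`` with a monoexonic reference;
* ``partial`` — at least one shared splice junction, or >= 1 bp same-strand
  exonic overlap with some reference transcript;
* ``novel`` — neither.

Two independent assemblies (e.g. short-read de novo contigs vs full-length
isoform sequencing) are intersected by requiring identical intron chains
with both transcript ends agreeing within ``end_match_tolerance_bp``;
monoexonic pairs need reciprocal overlap >= 0.90.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import PipelineConfig
from .models import TranscriptModel

TIERS = ("full", "partial", "novel")


@dataclass(frozen=True)
class IntronChain:
    chrom: str
    strand: str
    junctions: tuple[tuple[int, int], ...]  # 0-based half-open intron spans


@dataclass
class AnnotationTier:
    transcript_id: str
    tier: str
    matched_reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "full" and not self.matched_reference_id:
            raise ValueError(
                f"{self.transcript_id}: tier 'full' requires a matched reference id"
            )


def intron_chain(t: TranscriptModel) -> IntronChain:
    """Ordered intron intervals between consecutive exons; empty if monoexonic."""
    juncs = tuple((a.end, b.start) for a, b in zip(t.exons, t.exons[1:]))
    return IntronChain(t.chrom, t.strand, juncs)


def _reciprocal_overlap(a: TranscriptModel, b: TranscriptModel) -> float:
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    if ov == 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def _exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
    return total


def _end_distance(a: TranscriptModel, b: TranscriptModel) -> int:
    return abs(a.start - b.start) + abs(a.end - b.end)


class _ReferenceIndex:
    """Reference transcripts bucketed by (chrom, strand)."""

    def __init__(self, reference: Iterable[TranscriptModel]):
        self.by_loc: dict[tuple[str, str], list[TranscriptModel]] = defaultdict(list)
        self.by_chain: dict[tuple, list[TranscriptModel]] = defaultdict(list)
        self.n = 0
        for r in reference:
            self.by_loc[(r.chrom, r.strand)].append(r)
            ch = intron_chain(r)
            if ch.junctions:
                self.by_chain[(ch.chrom, ch.strand, ch.junctions)].append(r)
            self.n += 1


def build_reference_index(reference: Iterable[TranscriptModel]) -> _ReferenceIndex:
    return _ReferenceIndex(reference)


def annotation_tier(
    t: TranscriptModel,
    reference: _ReferenceIndex | Iterable[TranscriptModel],
    cfg: PipelineConfig = PipelineConfig(),
) -> AnnotationTier:
    """Tier one query transcript against the reference (see module docs)."""
    if not isinstance(reference, _ReferenceIndex):
        reference = _ReferenceIndex(reference)

    chain = intron_chain(t)
    same_strand = reference.by_loc.get((t.chrom, t.strand), [])

    if chain.junctions:
        exact = reference.by_chain.get((t.chrom, t.strand, chain.junctions), [])
        if exact:
            best = min(exact, key=lambda r: (_end_distance(t, r), r.transcript_id))
            return AnnotationTier(t.transcript_id, "full", best.transcript_id)
    else:
        mono = [r for r in same_strand if r.is_monoexonic]
        hits = [
            r for r in mono
            if _reciprocal_overlap(t, r) >= cfg.monoexonic_reciprocal_min
        ]
        if hits:
            best = min(hits, key=lambda r: (_end_distance(t, r), r.transcript_id))
            return AnnotationTier(t.transcript_id, "full", best.transcript_id)

    junctions = set(chain.junctions)
    for r in same_strand:
        if junctions and junctions & set(intron_chain(r).junctions):
            return AnnotationTier(t.transcript_id, "partial")
        if _exonic_overlap_bp(t, r) >= 1:
            return AnnotationTier(t.transcript_id, "partial")
    return AnnotationTier(t.transcript_id, "novel")


def tier_all(
    query: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    cfg: PipelineConfig = PipelineConfig(),
) -> list[AnnotationTier]:
    idx = _ReferenceIndex(reference)
    return [annotation_tier(t, idx, cfg) for t in query]


def intersect_assemblies(
    a: Sequence[TranscriptModel],
    b: Sequence[TranscriptModel],
    cfg: PipelineConfig = PipelineConfig(),
) -> list[tuple[str, str]]:
    """Pairs (a_id, b_id) of transcripts fully supported by both assemblies.

    Multiexonic: identical intron chain and both ends within
    ``end_match_tolerance_bp``. Monoexonic: reciprocal overlap >= 0.90.
    Each a-transcript is paired with at most its best b-match (smallest
    total end distance; ties broken by b id).
    """
    b_by_chain: dict[tuple, list[TranscriptModel]] = defaultdict(list)
    b_mono: dict[tuple[str, str], list[TranscriptModel]] = defaultdict(list)
    for tb in b:
        ch = intron_chain(tb)
        if ch.junctions:
            b_by_chain[(ch.chrom, ch.strand, ch.junctions)].append(tb)
        else:
            b_mono[(tb.chrom, tb.strand)].append(tb)

    pairs: list[tuple[str, str]] = []
    for ta in a:
        ch = intron_chain(ta)
        if ch.junctions:
            cands = [
                tb for tb in b_by_chain.get((ch.chrom, ch.strand, ch.junctions), [])
                if abs(ta.start - tb.start) <= cfg.end_match_tolerance_bp
                and abs(ta.end - tb.end) <= cfg.end_match_tolerance_bp
            ]
        else:
            cands = [
                tb for tb in b_mono.get((ta.chrom, ta.strand), [])
                if tb.is_monoexonic and _reciprocal_overlap(ta, tb) >= 0.90
            ]
        if cands:
            best = min(cands, key=lambda tb: (_end_distance(ta, tb), tb.transcript_id))
            pairs.append((ta.transcript_id, best.transcript_id))
    return pairs


def tiers_to_frame(tiers: Sequence[AnnotationTier]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in tiers],
            "tier": [t.tier for t in tiers],
            "matched_reference_id": [t.matched_reference_id or "" for t in tiers],
        }
    )
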