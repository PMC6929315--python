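"""Intron-retention detection and protein-level consequence prediction.

A variant transcript "retains" intron *i* of its index isoform when the
variant's exonic footprint covers at least ``retention_cov_min`` (default
95%) of that intron. Ordinals are numbered 1..n in transcript orientation
(5' to 3'; reversed relative to genomic order on the minus strand).
Variants terminating inside an intron (intronic polyadenylation) are
scored on the retained portion only.

Consequences follow the canonical premature-termination-codon logic:
translation proceeds from the index start codon through the variant's exon
chain; the first in-frame stop upstream of the index stop is a PTC. A PTC
more than ``nmd_rule_nt`` (50) nt upstream of the variant's last exon-exon
junction flags the transcript for nonsense-mediated decay; a PTC in the
last exon or within 50 nt of the last junction predicts a C-terminally
truncated protein. Variants of a non-coding index are ``noncoding``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .config import PipelineConfig
from .models import TranscriptModel, ValidationError

STOP_CODONS = {"TAA", "TAG", "TGA"}
CONSEQUENCES = ("truncation", "NMD", "none", "noncoding")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class IntronRetentionEvent:
    index_transcript_id: str
    variant_transcript_id: str
    retained_intron_ordinals: tuple[int, ...]
    consequence: Optional[str] = None
    ptc_transcript_pos: Optional[int] = None  # 0-based, start of the stop codon
    ptc_genomic_pos: Optional[int] = None
    distance_to_last_junction: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.retained_intron_ordinals:
            raise ValueError("a retention event needs >= 1 retained intron")
        self.retained_intron_ordinals = tuple(sorted(self.retained_intron_ordinals))


def _share_structure(variant: TranscriptModel, index: TranscriptModel) -> bool:
    v_j = {(a.end, b.start) for a, b in zip(variant.exons, variant.exons[1:])}
    i_j = {(a.end, b.start) for a, b in zip(index.exons, index.exons[1:])}
    if v_j & i_j:
        return True
    for ev in variant.exons:
        for ei in index.exons:
            if min(ev.end, ei.end) > max(ev.start, ei.start):
                return True
    return False


def detect_retained_introns(
    variant: TranscriptModel,
    index: TranscriptModel,
    cfg: PipelineConfig = PipelineConfig(),
) -> Optional[IntronRetentionEvent]:
    """Find index introns exonized in the variant; None when none qualify."""
    if variant.chrom != index.chrom or variant.strand != index.strand:
        raise ValidationError(
            f"{variant.transcript_id} vs {index.transcript_id}: "
            "different chromosome or strand"
        )
    if not _share_structure(variant, index):
        return None

    introns = index.introns()
    n = len(introns)
    if n == 0:
        return None
    # transcript-orientation 3' terminus of the variant
    terminus = variant.end if variant.strand == "+" else variant.start

    ordinals: list[int] = []
    for gi, intron in enumerate(introns):
        lo, hi = intron.start, intron.end
        # intronic polyadenylation: variant ends inside this intron ->
        # score only the portion upstream (5', transcript sense) of the end
        if variant.strand == "+" and lo < terminus < hi:
            hi = terminus
        elif variant.strand == "-" and lo < terminus < hi:
            lo = terminus
        length = hi - lo
        if length < 1:
            continue
        covered = sum(
            max(0, min(e.end, hi) - max(e.start, lo)) for e in variant.exons
        )
        if covered / length >= cfg.retention_cov_min:
            ordinal = gi + 1 if index.strand == "+" else n - gi
            ordinals.append(ordinal)
    if not ordinals:
        return None
    return IntronRetentionEvent(
        index.transcript_id, variant.transcript_id, tuple(ordinals)
    )


# --------------------------------------------------------------------------
# consequence prediction

def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Mature transcript sequence (reverse-complemented on the minus strand)."""
    if t.chrom not in genome:
        raise ValueError(f"{t.transcript_id}: no genome sequence for {t.chrom}")
    chrom_seq = genome[t.chrom]
    if t.end > len(chrom_seq):
        raise ValueError(f"{t.transcript_id}: exons extend past {t.chrom} sequence")
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    return revcomp(seq) if t.strand == "-" else seq


def _genomic_positions(t: TranscriptModel) -> list[int]:
    """Genomic coordinate of each transcript position, 5' to 3'."""
    pos = [p for e in t.exons for p in range(e.start, e.end)]
    return pos[::-1] if t.strand == "-" else pos


@dataclass
class ConsequenceCall:
    consequence: str
    ptc_transcript_pos: Optional[int] = None
    ptc_genomic_pos: Optional[int] = None
    distance_to_last_junction: Optional[int] = None


def predict_consequence(
    variant: TranscriptModel,
    index: TranscriptModel,
    genome: Mapping[str, str],
    cfg: PipelineConfig = PipelineConfig(),
) -> ConsequenceCall:
    """Classify the protein-level consequence of an intron-retaining variant."""
    if index.cds is None:
        return ConsequenceCall("noncoding")

    var_seq = spliced_sequence(variant, genome)
    gpos = _genomic_positions(variant)
    tpos_of = {g: i for i, g in enumerate(gpos)}

    # first base of the index start codon, transcript orientation
    start_g = index.cds[0] if index.strand == "+" else index.cds[1] - 1
    if start_g not in tpos_of:
        raise ValidationError(
            f"{variant.transcript_id}: index start codon not exonic in variant"
        )
    start_t = tpos_of[start_g]
    # first base of the index stop codon (the CDS span includes the stop)
    idx_stop_g = index.cds[1] - 3 if index.strand == "+" else index.cds[0] + 2

    stop_t: Optional[int] = None
    for i in range(start_t, len(var_seq) - 2, 3):
        if var_seq[i : i + 3] in STOP_CODONS:
            stop_t = i
            break
    if stop_t is None:
        return ConsequenceCall("none")
    stop_g = gpos[stop_t]
    if stop_g == idx_stop_g:
        return ConsequenceCall("none")  # translation terminates at the index stop
    idx_stop_t = tpos_of.get(idx_stop_g)
    if idx_stop_t is not None and stop_t >= idx_stop_t:
        return ConsequenceCall("none")

    # distance from the PTC to the variant's last exon-exon junction
    if variant.is_monoexonic:
        return ConsequenceCall("truncation", stop_t, stop_g, None)
    total = variant.exonic_length
    last_exon = variant.exons[-1] if variant.strand == "+" else variant.exons[0]
    last_junction_t = total - len(last_exon)
    d = last_junction_t - stop_t
    label = "NMD" if d > cfg.nmd_rule_nt else "truncation"
    return ConsequenceCall(label, stop_t, stop_g, d)


def call_retention(
    variant: TranscriptModel,
    index: TranscriptModel,
    genome: Optional[Mapping[str, str]] = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> Optional[IntronRetentionEvent]:
    """detect_retained_introns + predict_consequence in one call."""
    event = detect_retained_introns(variant, index, cfg)
    if event is None:
        return None
    if genome is not None:
        cc = predict_consequence(variant, index, genome, cfg)
        event.consequence = cc.consequence
        event.ptc_transcript_pos = cc.ptc_transcript_pos
        event.ptc_genomic_pos = cc.ptc_genomic_pos
        event.distance_to_last_junction = cc.distance_to_last_junction
    return event


# --------------------------------------------------------------------------
# expression comparison

@dataclass
class RetentionRatio:
    ratio: Optional[float]
    flag: str  # ">=index" | "<index" | "retained-only" | "unexpressed"


def retention_ratio(expr_retained: float, expr_spliced: float) -> RetentionRatio:
    """Retained/spliced expression ratio with qualitative flag."""
    if expr_retained < 0 or expr_spliced < 0:
        raise ValueError("expression values must be >= 0")
    if expr_retained == 0 and expr_spliced == 0:
        return RetentionRatio(None, "unexpressed")
    if expr_spliced == 0:
        return RetentionRatio(math.inf, "retained-only")
    ratio = expr_retained / expr_spliced
    return RetentionRatio(ratio, ">=index" if ratio >= 1.0 else "<index")


def events_to_frame(events: Sequence[IntronRetentionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index_transcript_id": [e.index_transcript_id for e in events],
            "variant_transcript_id": [e.variant_transcript_id for e in events],
            "retained_intron_ordinals": [
                ",".join(map(str, e.retained_intron_ordinals)) for e in events
            ],
            "consequence": [e.consequence or "" for e in events],
            "ptc_transcript_pos": [e.ptc_transcript_pos for e in events],
            "ptc_genomic_pos": [e.ptc_genomic_pos for e in events],
            "distance_to_last_junction": [e.distance_to_last_junction for e in events],
        }
    )
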