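"""Transcript–repeat overlap taxonomy.

Every transcript is placed in exactly one of four mutually exclusive
categories by its exonic overlap with annotated retroelements:

* ``standalone`` — repeats of a single ERE class cover >= ``standalone_cov_min``
  (default 80%) of the transcript's exonic sequence: the transcript is
  essentially the element itself.
* ``terminal_exon`` — a repeat dominates the 5'-most or 3'-most exon
  (>= ``terminal_exon_cov_min`` of that exon) and reaches within
  ``terminus_tolerance_bp`` of the transcript terminus: the element provides
  a terminal exon of a chimeric transcript.
* ``embedded`` — any remaining exonic overlap >= ``min_overlap_bp``: the
  element sits inside the transcript body (e.g. a 3'UTR Alu).
* ``none`` — no exonic repeat overlap of at least ``min_overlap_bp``.

Precedence is standalone > terminal_exon > embedded (the most specific
structural claim wins). The class label is the single contributing ERE
class, or ``multiple`` when two or more classes each contribute at least
``min_overlap_bp``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .config import PipelineConfig
from .models import GenomicInterval, RepeatFeature, TranscriptModel, exonic_overlap_bp

CATEGORIES = ("none", "standalone", "embedded", "terminal_exon")


@dataclass
class OverlapCall:
    transcript_id: str
    category: str
    ere_class_label: str  # LTR / LINE / SINE / SVA / multiple / none
    exonic_structure: str  # monoexonic / multiexonic
    covered_fraction: float
    same_strand: Optional[bool] = None
    contributing_repeats: list[str] = field(default_factory=list)


class RepeatIndex:
    """Interval index over repeat features, per chromosome."""

    def __init__(self, repeats: Iterable[RepeatFeature]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._n = 0
        for r in repeats:
            iv = r.interval
            self._trees[iv.chrom].addi(iv.start, iv.end, r)
            self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, chrom: str, start: int, end: int) -> list[RepeatFeature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def overlapping_transcript(self, t: TranscriptModel) -> list[RepeatFeature]:
        seen: dict[int, RepeatFeature] = {}
        for e in t.exons:
            for r in self.query(t.chrom, e.start, e.end):
                seen[id(r)] = r
        return list(seen.values())


def _union_bp_within_exons(
    t: TranscriptModel, intervals: Sequence[GenomicInterval]
) -> int:
    """bp of exonic sequence covered by the union of the given intervals."""
    clipped: list[tuple[int, int]] = []
    for e in t.exons:
        for iv in intervals:
            s, en = max(e.start, iv.start), min(e.end, iv.end)
            if s < en:
                clipped.append((s, en))
    clipped.sort()
    total = 0
    cur_s = cur_e = None
    for s, en in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, en
        else:
            cur_e = max(cur_e, en)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def classify_transcript(
    t: TranscriptModel,
    repeats: RepeatIndex,
    cfg: PipelineConfig = PipelineConfig(),
) -> OverlapCall:
    """Assign a transcript its repeat-overlap category (see module docs)."""
    structure = "monoexonic" if t.is_monoexonic else "multiexonic"
    candidates = repeats.overlapping_transcript(t)

    # per-repeat exonic overlap; ignore repeats below the floor
    retained: list[tuple[RepeatFeature, int]] = []
    for r in candidates:
        bp = exonic_overlap_bp(t, r.interval)
        if bp >= cfg.min_overlap_bp:
            retained.append((r, bp))

    if not retained:
        return OverlapCall(t.transcript_id, "none", "none", structure, 0.0)

    exonic_len = t.exonic_length
    covered = _union_bp_within_exons(t, [r.interval for r, _ in retained])
    covered_fraction = covered / exonic_len

    # class label: union coverage per ERE class
    by_class: dict[str, list[RepeatFeature]] = defaultdict(list)
    for r, _bp in retained:
        by_class[r.ere_class].append(r)
    class_bp = {
        cls: _union_bp_within_exons(t, [r.interval for r in rs])
        for cls, rs in by_class.items()
    }
    contributing = sorted(
        cls for cls, bp in class_bp.items() if bp >= cfg.min_overlap_bp
    )
    if len(contributing) >= 2:
        label = "multiple"
    elif contributing:
        label = contributing[0]
    else:  # every class individually under the floor but jointly retained
        label = max(class_bp, key=class_bp.get)

    strands = {r.interval.strand for r, _ in retained}
    same_strand: Optional[bool] = None
    if strands and "." not in strands:
        same_strand = strands == {t.strand}

    names = sorted({r.repeat_name for r, _ in retained})

    # standalone: one class covers >= standalone_cov_min of the exonic bp
    for cls in sorted(class_bp, key=class_bp.get, reverse=True):
        if class_bp[cls] / exonic_len >= cfg.standalone_cov_min:
            return OverlapCall(
                t.transcript_id, "standalone", label, structure,
                covered_fraction, same_strand, names,
            )

    # terminal exon: a repeat dominates a terminal exon up to the terminus
    first, last = t.exons[0], t.exons[-1]
    for r, _bp in retained:
        iv = r.interval
        for exon, side in ((first, "start"), (last, "end")):
            exon_bp = exon.overlap_bp(iv)
            if exon_bp < cfg.terminal_exon_cov_min * len(exon):
                continue
            if side == "start":
                reaches = iv.start <= exon.start + cfg.terminus_tolerance_bp
            else:
                reaches = iv.end >= exon.end - cfg.terminus_tolerance_bp
            if reaches:
                return OverlapCall(
                    t.transcript_id, "terminal_exon", label, structure,
                    covered_fraction, same_strand, names,
                )

    return OverlapCall(
        t.transcript_id, "embedded", label, structure,
        covered_fraction, same_strand, names,
    )


def classify_all(
    transcripts: Iterable[TranscriptModel],
    repeats: RepeatIndex,
    cfg: PipelineConfig = PipelineConfig(),
) -> list[OverlapCall]:
    return [classify_transcript(t, repeats, cfg) for t in transcripts]


def tabulate_overlap(calls: Sequence[OverlapCall]) -> pd.DataFrame:
    """category x ere_class x structure counts; cell counts sum to len(calls)."""
    if not calls:
        raise ValueError("tabulate_overlap requires at least one call")
    seen: set[str] = set()
    for c in calls:
        if c.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {c.transcript_id!r}")
        seen.add(c.transcript_id)
    df = pd.DataFrame(
        {
            "category": [c.category for c in calls],
            "ere_class": [c.ere_class_label for c in calls],
            "exonic_structure": [c.exonic_structure for c in calls],
        }
    )
    table = (
        df.value_counts(["category", "ere_class", "exonic_structure"])
        .rename("n_transcripts")
        .reset_index()
        .sort_values(["category", "ere_class", "exonic_structure"])
        .reset_index(drop=True)
    )
    return table


def calls_to_frame(calls: Sequence[OverlapCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "category": [c.category for c in calls],
            "ere_class": [c.ere_class_label for c in calls],
            "exonic_structure": [c.exonic_structure for c in calls],
            "covered_fraction": [round(c.covered_fraction, 6) for c in calls],
            "same_strand": [c.same_strand for c in calls],
            "contributing_repeats": [",".join(c.contributing_repeats) for c in calls],
        }
    )
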