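"""Read counting, ERE read-fraction accounting and depth normalization.

Counting follows the uniquely-mapped-reads convention: multimapping
placements contribute nowhere; within a layer (genes or repeat loci) a
read overlapping exactly one feature increments it and a read overlapping
two or more is discarded as ambiguous. The gene and repeat layers are
counted independently, so a read inside an exonized Alu counts once in
each layer.

Depth normalization is the median-of-ratios size factor: the reference is
the per-feature geometric mean across samples (features with any zero
excluded) and each sample's factor is the median of its count/reference
ratios.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GenomicInterval, RepeatFeature, TranscriptModel


@dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    interval: GenomicInterval
    unique: bool = True


def placements_to_frame(placements: Sequence[ReadPlacement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [p.read_id for p in placements],
            "chrom": [p.interval.chrom for p in placements],
            "start": [p.interval.start for p in placements],
            "end": [p.interval.end for p in placements],
            "unique": [int(p.unique) for p in placements],
        }
    )


def frame_to_placements(df: pd.DataFrame) -> list[ReadPlacement]:
    return [
        ReadPlacement(
            str(r.read_id),
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            bool(r.unique),
        )
        for r in df.itertuples(index=False)
    ]


def _feature_tree(
    features: Iterable[object],
) -> dict[str, IntervalTree]:
    """Index features by chrom. Transcripts contribute their exons keyed by
    gene_id; repeats contribute their interval keyed by repeat locus id."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        if isinstance(f, TranscriptModel):
            for e in f.exons:
                trees[f.chrom].addi(e.start, e.end, f.gene_id)
        elif isinstance(f, RepeatFeature):
            iv = f.interval
            key = f"{f.repeat_name}|{iv.chrom}:{iv.start}-{iv.end}"
            trees[iv.chrom].addi(iv.start, iv.end, key)
        elif isinstance(f, GenomicInterval):
            trees[f.chrom].addi(f.start, f.end, f"{f.chrom}:{f.start}-{f.end}")
        else:
            raise TypeError(f"cannot index feature of type {type(f).__name__}")
    return trees


def _hit_ids(trees: Mapping[str, IntervalTree], iv: GenomicInterval) -> set[str]:
    tree = trees.get(iv.chrom)
    if tree is None:
        return set()
    return {hit.data for hit in tree.overlap(iv.start, iv.end)}


def count_reads(
    placements_by_sample: Mapping[str, Sequence[ReadPlacement]],
    gene_features: Sequence[TranscriptModel],
    repeat_features: Sequence[RepeatFeature],
) -> dict[str, pd.DataFrame]:
    """Count unique reads per gene and per repeat locus, per sample.

    Returns ``{"gene": DataFrame, "repeat": DataFrame}``, each features x
    samples with non-negative integer counts. Reads ambiguous within a
    layer (overlapping >= 2 features of that layer) are dropped from that
    layer only.
    """
    gene_trees = _feature_tree(gene_features)
    repeat_trees = _feature_tree(repeat_features)
    gene_ids = sorted({t.gene_id for t in gene_features})
    repeat_ids = sorted(
        {
            f"{r.repeat_name}|{r.interval.chrom}:{r.interval.start}-{r.interval.end}"
            for r in repeat_features
        }
    )
    samples = list(placements_by_sample)
    gene_counts = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=int)
    repeat_counts = pd.DataFrame(0, index=repeat_ids, columns=samples, dtype=int)

    for sample, placements in placements_by_sample.items():
        seen: set[str] = set()
        for p in placements:
            if p.read_id in seen:
                raise ValueError(f"duplicate read_id {p.read_id!r} in {sample}")
            seen.add(p.read_id)
            if not p.unique:
                continue
            for trees, counts in (
                (gene_trees, gene_counts),
                (repeat_trees, repeat_counts),
            ):
                hits = _hit_ids(trees, p.interval)
                if len(hits) == 1:
                    counts.loc[hits.pop(), sample] += 1
    return {"gene": gene_counts, "repeat": repeat_counts}


def ere_read_fraction(
    placements: Sequence[ReadPlacement],
    repeat_features: Sequence[RepeatFeature],
    min_overlap_bp: int = 1,
) -> float:
    """Fraction of unique placements overlapping >= 1 repeat by >= 1 bp."""
    unique = [p for p in placements if p.unique]
    if not unique:
        raise ValueError("ere_read_fraction needs at least one unique placement")
    trees = _feature_tree(repeat_features)
    n_ere = 0
    for p in unique:
        tree = trees.get(p.interval.chrom)
        if tree is None:
            continue
        bp = 0
        for hit in tree.overlap(p.interval.start, p.interval.end):
            bp = max(bp, min(hit.end, p.interval.end) - max(hit.begin, p.interval.start))
        if bp >= min_overlap_bp:
            n_ere += 1
    return n_ere / len(unique)


def ere_read_fraction_by_sample(
    placements_by_sample: Mapping[str, Sequence[ReadPlacement]],
    repeat_features: Sequence[RepeatFeature],
) -> pd.Series:
    return pd.Series(
        {
            s: ere_read_fraction(p, repeat_features)
            for s, p in placements_by_sample.items()
        },
        name="ere_read_fraction",
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth-normalization factors, one per sample.

    Features with a zero in any sample are excluded from the
    geometric-mean pseudo-reference.
    """
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; add a pseudocount "
            "or filter samples"
        )
    sub = mat[all_positive]
    log_ref = np.mean(np.log(sub), axis=1)  # log geometric mean per feature
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """counts / size factor, columnwise."""
    return counts / size_factors(counts)


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from counts and effective lengths.

    TPM_i = (c_i / l_i) / sum_k (c_k / l_k) * 1e6; every sample column
    sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing effective lengths for: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        zero = totals[totals == 0].index.tolist()
        raise ValueError(f"all-zero sample(s): {zero}")
    return rate.div(totals, axis=1) * 1e6
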