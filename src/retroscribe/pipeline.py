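"""End-to-end orchestration of the analysis stages on one configuration.

``run_pipeline`` executes the stages in order — generate (or load) the
annotation, classify repeat overlaps, tier against the reference,
intersect assemblies, simulate and normalize counts, select responsive
and multigroup features, account ERE read fractions, and call intron
retention — writing each stage's TSV before the next starts, and records
a manifest (config snapshot, seed, per-stage paths, row counts and
digests). Two runs from the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .compare import intersect_assemblies, tier_all, tiers_to_frame
from .config import PipelineConfig
from .io import write_fasta, write_repeats_bed, write_transcripts_gtf, write_tsv
from .models import GenomicInterval, TranscriptModel
from .overlap import RepeatIndex, calls_to_frame, classify_all, tabulate_overlap
from .quant import (
    ere_read_fraction,
    normalize_counts,
    placements_to_frame,
    size_factors,
)
from .retention import call_retention, events_to_frame
from .stats import delta_ct_quantify, multigroup_select, responsive_select
from .synth import (
    generate_annotation,
    multigroup_design,
    paired_design,
    simulate_counts,
    simulate_read_placements,
)

# default synthetic study preset: planted overlap categories per ERE class,
# three retention pairs covering the consequence taxonomy
_OVERLAP_PLAN = {
    (cat, cls): 25
    for cat in ("standalone", "embedded", "terminal_exon")
    for cls in ("LTR", "LINE", "SINE", "SVA")
}
_OVERLAP_PLAN[("none", "none")] = 50

_RETENTION_SPECS = (
    {"n_introns": 10, "retained": (6, 9), "consequence": "NMD"},
    {"n_introns": 3, "retained": (3,), "consequence": "truncation"},
    {"n_introns": 3, "retained": (3,), "consequence": "none"},
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jitter_ends(
    transcripts: list[TranscriptModel], rng: np.random.Generator, max_bp: int
) -> list[TranscriptModel]:
    """Extend transcript termini outward by up to max_bp (emulates the end
    wobble between assembly methods; intron chains are untouched)."""
    out = []
    for t in transcripts:
        exons = [GenomicInterval(e.chrom, e.start, e.end, e.strand) for e in t.exons]
        d5 = int(rng.integers(0, max_bp + 1))
        d3 = int(rng.integers(0, max_bp + 1))
        first, last = exons[0], exons[-1]
        exons[0] = GenomicInterval(
            first.chrom, max(0, first.start - d5), first.end, first.strand
        )
        last = exons[-1]
        exons[-1] = GenomicInterval(last.chrom, last.start, last.end + d3, last.strand)
        out.append(
            TranscriptModel(
                t.transcript_id + "_b", t.gene_id, t.chrom, t.strand, exons,
                source="isoseq",
            )
        )
    return out


def run_pipeline(
    out_dir: str | Path,
    cfg: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> dict:
    """Run the bundled synthetic preset end to end; returns the manifest."""
    cfg = cfg or PipelineConfig()
    seed = cfg.rng_seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "retroscribe",
        "version": __version__,
        "seed": seed,
        "config": cfg.to_dict(),
        "stages": {},
    }

    def record(stage: str, path: Path, rows: int) -> None:
        manifest["stages"][stage] = {
            "path": path.name,
            "rows": rows,
            "sha256": _sha256(path),
        }

    # stage 1: annotation with planted truth
    ann = generate_annotation(
        _OVERLAP_PLAN, retention_specs=_RETENTION_SPECS, seed=seed
    )
    gtf = out / "annotation.gtf"
    bed = out / "repeats.bed"
    fa = out / "genome.fa"
    write_transcripts_gtf(ann.transcripts, gtf)
    write_repeats_bed(ann.repeats, bed)
    write_fasta(ann.genome, fa)
    write_tsv(ann.truth, out / "truth_overlap.tsv")
    record("annotation", gtf, len(ann.transcripts))

    # stage 2: repeat-overlap classification
    index = RepeatIndex(ann.repeats)
    calls = classify_all(ann.transcripts, index, cfg)
    calls_path = out / "calls.tsv"
    write_tsv(calls_to_frame(calls), calls_path, comments=[f"seed={seed}"])
    write_tsv(tabulate_overlap(calls), out / "overlap_summary.tsv")
    record("classify", calls_path, len(calls))

    # stage 3: annotation tiers (variants queried against the reference)
    variant_ids = set(ann.retention_truth["variant_transcript_id"])
    reference = [t for t in ann.transcripts if t.transcript_id not in variant_ids]
    tiers = tier_all(ann.transcripts, reference, cfg)
    tiers_path = out / "tiers.tsv"
    write_tsv(tiers_to_frame(tiers), tiers_path)
    record("tiers", tiers_path, len(tiers))

    # stage 4: assembly intersection against an end-jittered copy
    rng = np.random.default_rng(seed + 1)
    jittered = _jitter_ends(ann.transcripts, rng, cfg.end_match_tolerance_bp // 2)
    pairs = intersect_assemblies(ann.transcripts, jittered, cfg)
    pairs_df = pd.DataFrame(pairs, columns=["a_id", "b_id"])
    pairs_path = out / "intersection.tsv"
    write_tsv(pairs_df, pairs_path)
    record("intersect", pairs_path, len(pairs))

    # stage 5: counts, normalization, responsive + multigroup selection
    meta_r = paired_design(8, outcomes=["CR", "FAIL"] * 4)
    counts_r, truth_r = simulate_counts(
        meta_r, n_features=1000, n_de=50, log2fc=2.0,
        contrast=("timepoint", "C6"), seed=seed + 2,
    )
    write_tsv(counts_r, out / "counts_paired.tsv", index=True)
    write_tsv(truth_r.drop(columns="feature_id"), out / "truth_counts_paired.tsv", index=True)
    norm_r = normalize_counts(counts_r)
    de_r = responsive_select(norm_r, meta_r, ("pre", "C6"), cfg)
    de_path = out / "responsive.tsv"
    write_tsv(de_r.drop(columns="feature_id"), de_path, index=True)
    record("responsive", de_path, len(de_r))

    meta_m = multigroup_design(5)
    counts_m, _truth_m = simulate_counts(
        meta_m, n_features=1000, n_de=50, log2fc=2.0,
        contrast=("group", "healthy"), seed=seed + 3,
    )
    norm_m = normalize_counts(counts_m)
    de_m, excluded = multigroup_select(norm_m, meta_m, "group", cfg)
    de_m_path = out / "multigroup.tsv"
    write_tsv(de_m.drop(columns="feature_id"), de_m_path, index=True)
    record("multigroup", de_m_path, len(de_m))

    sf = size_factors(counts_r)
    write_tsv(sf.to_frame(), out / "size_factors.tsv", index=True)

    # stage 6: ERE read-fraction accounting
    genome_len = len(ann.genome["chrS"])
    frac_rows = []
    for i, (sample, target) in enumerate(
        (("healthy_01", 0.16), ("MDS_pre_01", 0.10), ("MDS_C6_01", 0.16))
    ):
        placements, _ = simulate_read_placements(
            ann.repeats, genome_len, target, n_reads=10_000, seed=seed + 10 + i
        )
        measured = ere_read_fraction(placements, ann.repeats)
        frac_rows.append(
            {"sample_id": sample, "target_fraction": target,
             "measured_fraction": round(measured, 6)}
        )
        if i == 0:
            write_tsv(placements_to_frame(placements), out / "placements.tsv")
    frac_path = out / "ere_fraction.tsv"
    write_tsv(pd.DataFrame(frac_rows), frac_path)
    record("ere_fraction", frac_path, len(frac_rows))

    # stage 7: intron retention with consequences
    by_id = {t.transcript_id: t for t in ann.transcripts}
    events = []
    for row in ann.retention_truth.itertuples(index=False):
        ev = call_retention(
            by_id[row.variant_transcript_id],
            by_id[row.index_transcript_id],
            ann.genome,
            cfg,
        )
        if ev is not None:
            events.append(ev)
    ret_path = out / "retention.tsv"
    write_tsv(events_to_frame(events), ret_path)
    write_tsv(ann.retention_truth, out / "truth_retention.tsv")
    record("retention", ret_path, len(events))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
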