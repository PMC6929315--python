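"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the structure of the study inputs — gene models
with planted repeat-overlap categories, negative-binomial count matrices
with planted group/treatment effects, read placements with a planted
ERE-derived fraction, and intron-retention variant/index pairs with
controlled premature-termination codons — so that classification,
selection and consequence calling can be validated against exact truth
without any external dataset. All generators are pure functions of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .models import GenomicInterval, RepeatFeature, TranscriptModel
from .quant import ReadPlacement
from .retention import revcomp
from .stats import SampleMeta, meta_to_frame

# repeat names/families per ERE class, RepeatMasker-style
_REPEAT_POOL = {
    "LTR": (("LTR12C", "LTR/ERV1"), ("MSTB", "LTR/ERVL-MaLR"),
            ("MLT1B", "LTR/ERVL-MaLR"), ("HERVK9-int", "LTR/ERVK"),
            ("MER54A", "LTR/ERV3"), ("LTR24C", "LTR/ERV1")),
    "LINE": (("L1PA3", "LINE/L1"), ("L2a", "LINE/L2"), ("L1MB7", "LINE/L1")),
    "SINE": (("AluY", "SINE/Alu"), ("AluSx", "SINE/Alu"), ("MIRb", "SINE/MIR")),
    "SVA": (("SVA_D", "Retroposon/SVA"), ("SVA_B", "Retroposon/SVA")),
}

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticAnnotation:
    transcripts: list[TranscriptModel]
    repeats: list[RepeatFeature]
    genome: dict[str, str]
    truth: pd.DataFrame  # per-transcript planted category / class / structure
    retention_truth: pd.DataFrame  # planted retention pairs and consequences
    params: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


# --------------------------------------------------------------------------
# planted repeat-overlap annotations

def generate_annotation(
    counts_per_category: Optional[Mapping[tuple[str, str], int]] = None,
    retention_specs: Sequence[dict] = (),
    chrom: str = "chrS",
    spacing: int = 500,
    seed: int = 0,
    with_genome: bool = True,
) -> SyntheticAnnotation:
    """Generate transcripts + repeats with planted overlap categories.

    ``counts_per_category`` maps (category, ere_class) to the number of
    transcripts to plant, e.g. ``{("standalone", "LTR"): 10}``; the class
    is ignored for category ``none``. Each planted transcript satisfies
    its category by construction with margin under the default thresholds.
    ``retention_specs`` are dicts accepted by :func:`generate_retention_pair`
    (minus chrom/offset/ids, which are assigned here).
    """
    rng = np.random.default_rng(seed)
    if counts_per_category is None:
        counts_per_category = {}
    transcripts: list[TranscriptModel] = []
    repeats: list[RepeatFeature] = []
    truth_rows: list[dict] = []
    cursor = spacing
    serial = 0

    plan: list[tuple[str, str]] = []
    for (category, ere_class), n in sorted(counts_per_category.items()):
        if n < 0:
            raise ValueError(f"negative request for {(category, ere_class)}")
        plan.extend([(category, ere_class)] * n)

    for category, ere_class in plan:
        serial += 1
        tid = f"SYN{serial:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        t, rs = _plant_transcript(rng, tid, chrom, cursor, category, ere_class, strand)
        transcripts.append(t)
        repeats.extend(rs)
        truth_rows.append(
            {
                "transcript_id": tid,
                "category": category,
                "ere_class": ere_class if category != "none" else "none",
                "exonic_structure": "monoexonic" if t.is_monoexonic else "multiexonic",
            }
        )
        cursor = t.end + spacing

    # retention pairs get crafted (non-random) sequence segments
    segments: list[tuple[int, str]] = []
    ret_rows: list[dict] = []
    for i, spec in enumerate(retention_specs, start=1):
        spec = dict(spec)
        index_id = spec.pop("index_id", f"IDX{i:03d}")
        variant_id = spec.pop("variant_id", f"VAR{i:03d}")
        pair = generate_retention_pair(
            index_id=index_id, variant_id=variant_id,
            chrom=chrom, offset=cursor, **spec,
        )
        transcripts.extend([pair.index, pair.variant])
        segments.append((cursor, pair.sequence))
        ret_rows.append(
            {
                "index_transcript_id": index_id,
                "variant_transcript_id": variant_id,
                "retained_intron_ordinals": ",".join(
                    map(str, pair.retained_ordinals)
                ),
                "consequence": pair.consequence,
            }
        )
        cursor = cursor + len(pair.sequence) + spacing

    genome: dict[str, str] = {}
    if with_genome:
        seq = list(_random_seq(rng, cursor + spacing))
        for off, segment in segments:
            seq[off : off + len(segment)] = segment
        genome[chrom] = "".join(seq)

    return SyntheticAnnotation(
        transcripts=transcripts,
        repeats=repeats,
        genome=genome,
        truth=pd.DataFrame(
            truth_rows,
            columns=["transcript_id", "category", "ere_class", "exonic_structure"],
        ),
        retention_truth=pd.DataFrame(
            ret_rows,
            columns=[
                "index_transcript_id", "variant_transcript_id",
                "retained_intron_ordinals", "consequence",
            ],
        ),
        params={"seed": seed, "chrom": chrom, "spacing": spacing,
                "counts_per_category": dict(counts_per_category)},
    )


def _pick_repeat(rng: np.random.Generator, ere_class: str) -> tuple[str, str]:
    pool = _REPEAT_POOL[ere_class]
    return pool[rng.integers(0, len(pool))]


def _plant_transcript(
    rng: np.random.Generator,
    tid: str,
    chrom: str,
    cursor: int,
    category: str,
    ere_class: str,
    strand: str,
) -> tuple[TranscriptModel, list[RepeatFeature]]:
    repeats: list[RepeatFeature] = []

    def make_exons(n: int) -> list[GenomicInterval]:
        exons = []
        pos = cursor
        for _ in range(n):
            length = int(rng.integers(200, 401))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(150, 301))
        return exons

    if category == "standalone":
        length = int(rng.integers(300, 801))
        exon = GenomicInterval(chrom, cursor, cursor + length, strand)
        name, family = _pick_repeat(rng, ere_class)
        repeats.append(
            RepeatFeature(
                GenomicInterval(chrom, max(0, cursor - 20), exon.end + 20, strand),
                name, family,
            )
        )
        t = TranscriptModel(tid, f"g_{tid}", chrom, strand, [exon], source="denovo")
    elif category == "embedded":
        exons = make_exons(int(rng.integers(2, 4)))
        host = exons[int(rng.integers(0, len(exons)))]
        margin = 60
        rep_len = int(rng.integers(50, 81))
        start = int(rng.integers(host.start + margin, host.end - margin - rep_len))
        name, family = _pick_repeat(rng, ere_class)
        repeats.append(
            RepeatFeature(
                GenomicInterval(chrom, start, start + rep_len, strand), name, family
            )
        )
        t = TranscriptModel(tid, f"g_{tid}", chrom, strand, exons, source="denovo")
    elif category == "terminal_exon":
        exons = make_exons(3)
        # shrink the terminal exon so the repeat never reaches 80% of the
        # transcript and the category stays below the standalone rule
        last = exons[-1]
        exons[-1] = GenomicInterval(chrom, last.start, last.start + 150, strand)
        name, family = _pick_repeat(rng, ere_class)
        repeats.append(
            RepeatFeature(
                GenomicInterval(
                    chrom, exons[-1].start - 5, exons[-1].end + 20, strand
                ),
                name, family,
            )
        )
        t = TranscriptModel(tid, f"g_{tid}", chrom, strand, exons, source="denovo")
    elif category == "none":
        exons = make_exons(int(rng.integers(1, 4)))
        t = TranscriptModel(tid, f"g_{tid}", chrom, strand, exons, source="denovo")
    else:
        raise ValueError(f"unknown category {category!r}")
    return t, repeats


# --------------------------------------------------------------------------
# retention variant/index pairs with controlled PTCs

@dataclass
class RetentionPair:
    index: TranscriptModel
    variant: TranscriptModel
    sequence: str  # locus sequence (place at `offset` on the chromosome)
    retained_ordinals: tuple[int, ...]
    consequence: str


def generate_retention_pair(
    index_id: str = "IDX",
    variant_id: str = "VAR",
    chrom: str = "chrS",
    offset: int = 0,
    n_introns: int = 3,
    retained: Sequence[int] = (2,),
    consequence: str = "NMD",
    strand: str = "+",
    exon_len: int = 120,
    intron_len: int = 300,
) -> RetentionPair:
    """Build an index/variant pair whose retained introns and consequence
    are exact by construction.

    Exon and intron lengths are multiples of 3, so exonizing an intron
    preserves the downstream reading frame. The locus sequence is a GGC
    lattice (stop- and start-free in every frame) into which the start
    codon, the index stop codon and — for NMD/truncation — a single
    in-frame premature stop inside a retained intron are written:

    * ``NMD`` — PTC mid-way into the first retained intron, which must
      have a splice junction > 50 nt downstream in the variant;
    * ``truncation`` — PTC mid-way into the retained LAST intron (no
      downstream junction);
    * ``none`` — no PTC; the index stop is placed upstream of the first
      retained intron, leaving the retained sequence in the 3'UTR;
    * ``noncoding`` — index carries no CDS.
    """
    if exon_len % 3 or intron_len % 3:
        raise ValueError("exon_len and intron_len must be multiples of 3")
    retained = tuple(sorted(set(retained)))
    if not retained or retained[0] < 1 or retained[-1] > n_introns:
        raise ValueError(f"retained ordinals {retained} out of 1..{n_introns}")
    if consequence not in ("NMD", "truncation", "none", "noncoding"):
        raise ValueError(f"unknown consequence {consequence!r}")
    if consequence == "truncation" and n_introns not in retained:
        raise ValueError("truncation requires the last intron to be retained")
    non_retained = set(range(1, n_introns + 1)) - set(retained)
    nmd_candidates = [
        r for r in retained if any(j > r for j in non_retained)
    ]
    if consequence == "NMD" and not nmd_candidates:
        raise ValueError("NMD requires a retained intron with a downstream junction")

    n_exons = n_introns + 1
    unit = exon_len + intron_len
    span = n_exons * exon_len + n_introns * intron_len

    # local (plus-orientation) exon coordinates
    idx_exons = [(i * unit, i * unit + exon_len) for i in range(n_exons)]
    retained0 = {r - 1 for r in retained}  # 0-based genomic intron indices
    var_exons: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(idx_exons):
        if var_exons and (i - 1) in retained0:
            var_exons[-1] = (var_exons[-1][0], e)  # merge across retained intron
        else:
            var_exons.append((s, e))

    seq = list(("GGC" * (span // 3 + 1))[:span])

    def plant(local_pos: int, codon: str) -> None:
        seq[local_pos : local_pos + 3] = list(codon)

    cds: Optional[tuple[int, int]] = None
    if consequence != "noncoding":
        plant(30, "ATG")
        if consequence == "none":
            stop_exon = retained[0]  # 1-based: the exon before the first retained intron
        else:
            stop_exon = n_exons
        stop_local = idx_exons[stop_exon - 1][0] + exon_len - 33
        plant(stop_local, "TAA")
        cds = (30, stop_local + 3)
        if consequence == "NMD":
            first = nmd_candidates[0]
            ptc_local = idx_exons[first - 1][1] + intron_len // 2
            ptc_local -= ptc_local % 3
            plant(ptc_local, "TAA")
        elif consequence == "truncation":
            ptc_local = idx_exons[n_introns - 1][1] + intron_len // 2
            ptc_local -= ptc_local % 3
            plant(ptc_local, "TAA")

    sequence = "".join(seq)
    if strand == "-":
        sequence = revcomp(sequence)
        idx_exons = [(span - e, span - s) for s, e in reversed(idx_exons)]
        var_exons = [(span - e, span - s) for s, e in reversed(var_exons)]
        if cds is not None:
            cds = (span - cds[1], span - cds[0])

    def lift(pairs: list[tuple[int, int]]) -> list[GenomicInterval]:
        return [GenomicInterval(chrom, offset + s, offset + e, strand) for s, e in pairs]

    gene = f"g_{index_id}"
    cds_g = (offset + cds[0], offset + cds[1]) if cds is not None else None
    index = TranscriptModel(index_id, gene, chrom, strand, lift(idx_exons),
                            cds=cds_g, source="reference")
    variant = TranscriptModel(variant_id, gene, chrom, strand, lift(var_exons),
                              source="isoseq")
    return RetentionPair(index, variant, sequence, retained, consequence)


# --------------------------------------------------------------------------
# count matrices

def paired_design(
    n_patients: int,
    group: str = "MDS",
    post: str = "C6",
    outcomes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """pre + post sample per patient, one row per sample."""
    meta: list[SampleMeta] = []
    for i in range(1, n_patients + 1):
        pid = f"P{i:03d}"
        outcome = outcomes[i - 1] if outcomes is not None else "NA"
        meta.append(SampleMeta(f"{pid}_pre", group, "pre", outcome, "HSC", pid))
        meta.append(SampleMeta(f"{pid}_{post}", group, post, outcome, "HSC", pid))
    return meta_to_frame(meta)


def multigroup_design(n_per_group: int, groups: Sequence[str] = ("healthy", "MDS", "CMML", "AML")) -> pd.DataFrame:
    meta = [
        SampleMeta(f"{g}_{i:02d}", g, "NA" if g == "healthy" else "pre")
        for g in groups
        for i in range(1, n_per_group + 1)
    ]
    return meta_to_frame(meta)


def simulate_counts(
    meta: pd.DataFrame,
    n_features: int = 2000,
    n_de: int = 0,
    log2fc: float = 2.0,
    contrast: tuple[str, str] = ("timepoint", "C6"),
    baseline_log_mean: float = 5.0,
    baseline_log_sd: float = 1.0,
    dispersion: float = 0.05,
    patient_sd: float = 0.2,
    depth_factor_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts with planted effects.

    Per-feature baselines are log-normal; each patient contributes a
    multiplicative random factor shared by their samples (honouring the
    paired design); each sample gets a log-normal depth factor. The first
    ``n_de`` features carry a 2^log2fc multiplier on the samples selected
    by ``contrast`` — a (meta column, level) pair, e.g. ("timepoint","C6")
    for post-treatment induction or ("outcome","FAIL") for a pre-treatment
    predictor. Counts are NB with var = mu + dispersion * mu^2.
    """
    rng = np.random.default_rng(seed)
    samples = meta["sample_id"].tolist()
    n_s = len(samples)
    if n_de > n_features:
        raise ValueError("n_de > n_features")

    base = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n_features)
    patients = meta["patient_id"].tolist()
    patient_factor: dict[str, float] = {}
    sample_factor = np.empty(n_s)
    for j, pid in enumerate(patients):
        if pid:
            if pid not in patient_factor:
                patient_factor[pid] = rng.lognormal(0.0, patient_sd)
            sample_factor[j] = patient_factor[pid]
        else:
            sample_factor[j] = rng.lognormal(0.0, patient_sd)
    depth = rng.lognormal(0.0, depth_factor_sd, size=n_s)

    col, level = contrast
    affected = (meta[col] == level).to_numpy()
    effect = np.ones((n_features, n_s))
    effect[:n_de, affected] = 2.0 ** log2fc

    mu = base[:, None] * sample_factor[None, :] * depth[None, :] * effect
    if dispersion > 1e-12:
        n_param = 1.0 / dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    else:
        counts = rng.poisson(mu)

    features = [f"feat{i:05d}" for i in range(1, n_features + 1)]
    counts_df = pd.DataFrame(counts, index=features, columns=samples)
    truth = pd.DataFrame(
        {
            "feature_id": features,
            "is_de": [i < n_de for i in range(n_features)],
            "log2fc": [log2fc if i < n_de else 0.0 for i in range(n_features)],
        }
    ).set_index("feature_id", drop=False)
    return counts_df, truth


# --------------------------------------------------------------------------
# read placements with a planted ERE fraction

def simulate_read_placements(
    repeats: Sequence[RepeatFeature],
    genome_length: int,
    target_ere_fraction: float,
    n_reads: int,
    unique_fraction: float = 0.9,
    read_len: int = 100,
    chrom: str = "chrS",
    seed: int = 0,
) -> tuple[list[ReadPlacement], pd.DataFrame]:
    """Place reads so that each overlaps a repeat with the target probability.

    Off-repeat reads are placed entirely inside repeat-free gaps, so the
    per-read Bernoulli draw recorded in the truth table is exact.
    """
    if not (0.0 <= target_ere_fraction <= 1.0):
        raise ValueError("target_ere_fraction must be in [0,1]")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    reps = [r for r in repeats if r.interval.chrom == chrom]
    if target_ere_fraction > 0 and not reps:
        raise ValueError("annotation has no repeats but target fraction > 0")

    # repeat-free gaps wide enough for a read plus a safety margin
    merged: list[tuple[int, int]] = []
    for r in sorted(reps, key=lambda r: r.interval.start):
        s, e = r.interval.start, r.interval.end
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    gaps: list[tuple[int, int]] = []
    prev = 0
    for s, e in merged + [(genome_length, genome_length)]:
        if s - prev >= read_len + 2:
            gaps.append((prev + 1, s - read_len - 1))  # start range, repeat-free
        prev = max(prev, e)
    if target_ere_fraction < 1.0 and not gaps:
        raise ValueError("no repeat-free gap wide enough for off-target reads")

    rng = np.random.default_rng(seed)
    placements: list[ReadPlacement] = []
    rows: list[dict] = []
    gap_sizes = np.array([hi - lo + 1 for lo, hi in gaps], dtype=float)
    gap_p = gap_sizes / gap_sizes.sum() if gaps else None
    for i in range(n_reads):
        on_repeat = bool(rng.random() < target_ere_fraction)
        unique = bool(rng.random() < unique_fraction)
        if on_repeat:
            r = reps[rng.integers(0, len(reps))]
            lo = max(0, r.interval.start - read_len + 1)
            hi = r.interval.end - 1
            start = int(rng.integers(lo, hi + 1))
        else:
            g = int(rng.choice(len(gaps), p=gap_p))
            lo, hi = gaps[g]
            start = int(rng.integers(lo, hi + 1))
        rid = f"read{i:07d}"
        placements.append(
            ReadPlacement(rid, GenomicInterval(chrom, start, start + read_len), unique)
        )
        rows.append({"read_id": rid, "on_repeat": on_repeat, "unique": unique})
    truth = pd.DataFrame(rows).set_index("read_id", drop=False)
    return placements, truth
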