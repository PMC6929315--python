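"""De novo assembly contig filters.

The chain applied to raw assembly contigs before any downstream use:

1. polyA trimming — a trailing A-rich run (and, symmetrically, a leading
   T-rich run from reverse-complemented fragments) is removed;
2. sequence-complexity filter — normalized k-mer Shannon entropy >= 0.7;
3. expression filter — >= 0.05 TPM in at least one sample;
4. alignment filter — contigs aligning to the genome with <= 85% identity
   or over <= 85% of their length are removed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .config import PipelineConfig

_VALID_BASES = set("ACGTN")


@dataclass
class ContigRecord:
    contig_id: str
    sequence: str
    aln_identity: Optional[float] = None  # fraction identical, in [0,1]
    aln_coverage: Optional[float] = None  # fraction of contig length aligned
    tpm_by_sample: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.contig_id}: invalid bases {''.join(sorted(bad))!r}"
            )
        for name, v in (("aln_identity", self.aln_identity),
                        ("aln_coverage", self.aln_coverage)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.contig_id}: {name}={v} not in [0,1]")
        if any(v < 0 for v in self.tpm_by_sample.values()):
            raise ValueError(f"{self.contig_id}: negative TPM")

    @property
    def max_tpm(self) -> float:
        return max(self.tpm_by_sample.values(), default=0.0)


def _trim_trailing(seq: str, base: str, min_run: int, min_frac: float) -> str:
    """Remove the longest suffix that starts with `base` and whose `base`
    content is >= min_frac, provided it is at least min_run long."""
    n = len(seq)
    count = 0  # occurrences of base in seq[i:]
    best = 0
    for i in range(n - 1, -1, -1):
        if seq[i] == base:
            count += 1
            length = n - i
            if count / length >= min_frac:
                best = length
    if best >= min_run:
        return seq[: n - best]
    return seq


def trim_polya(seq: str, min_run: int = 10, min_frac: float = 0.9) -> str:
    """Trim a trailing polyA run and a leading polyT run.

    A run is trimmed when it is at least ``min_run`` long and its A (resp.
    T) content is >= ``min_frac``; the trimmed block always begins/ends on
    the run base, so ordinary 3' sequence is never eaten. Idempotent.
    An all-tail contig trims to the empty string (degenerate).
    """
    seq = seq.upper()
    seq = _trim_trailing(seq, "A", min_run, min_frac)
    seq = _trim_trailing(seq[::-1], "T", min_run, min_frac)[::-1]
    return seq


def sequence_entropy(seq: str, k: int = 5) -> float:
    """Normalized k-mer Shannon entropy of a sequence, in [0, 1].

    H = -sum p log p over the k-mer frequency distribution, divided by
    log(min(4^k, L-k+1)) — the maximum achievable for the sequence length.
    A homopolymer (single distinct k-mer) scores 0; a sequence in which
    every possible k-mer occurs equally often scores 1.
    """
    seq = seq.upper()
    n_kmers = len(seq) - k + 1
    if n_kmers < 1:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    counts = Counter(seq[i : i + k] for i in range(n_kmers))
    if len(counts) == 1:
        return 0.0
    h = 0.0
    for c in counts.values():
        p = c / n_kmers
        h -= p * math.log(p)
    h_max = math.log(min(4 ** k, n_kmers))
    return h / h_max


def apply_contig_filters(
    contigs: Iterable[ContigRecord],
    cfg: PipelineConfig = PipelineConfig(),
    trim: bool = True,
) -> tuple[list[ContigRecord], dict[str, list[str]]]:
    """Run the full filter chain; returns (kept, rejection reasons).

    A contig is kept iff entropy >= entropy_min AND max sample TPM >=
    tpm_min AND identity > identity_min AND coverage > coverage_min
    (``aln_filter_mode="strict"``, the default; ``"lenient"`` removes only
    contigs failing BOTH alignment criteria). Rejection reasons enumerate
    every failed rule.
    """
    kept: list[ContigRecord] = []
    rejected: dict[str, list[str]] = {}
    for c in contigs:
        reasons: list[str] = []
        seq = trim_polya(c.sequence) if trim else c.sequence
        if not seq:
            c.degenerate = True
            reasons.append("degenerate")
            entropy = 0.0
        elif len(seq) < cfg.entropy_k:
            entropy = 0.0
        else:
            entropy = sequence_entropy(seq, cfg.entropy_k)
        if entropy < cfg.entropy_min:
            reasons.append("entropy")
        if c.max_tpm < cfg.tpm_min:
            reasons.append("expression")
        if c.aln_identity is None or c.aln_coverage is None:
            raise ValueError(f"{c.contig_id}: missing alignment identity/coverage")
        id_fail = c.aln_identity <= cfg.identity_min
        cov_fail = c.aln_coverage <= cfg.coverage_min
        if cfg.aln_filter_mode == "strict":
            if id_fail:
                reasons.append("identity")
            if cov_fail:
                reasons.append("coverage")
        else:  # lenient: removed only when both criteria fail
            if id_fail and cov_fail:
                reasons.append("identity+coverage")
        if reasons:
            rejected[c.contig_id] = reasons
        else:
            kept.append(c)
    return kept, rejected


def rejections_to_frame(rejected: dict[str, list[str]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig_id": list(rejected),
            "reasons": [",".join(v) for v in rejected.values()],
        }
    )
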