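"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval arithmetic: overlaps are
counted per base on explicit position vectors and the classification rules
are evaluated literally, so agreement is a meaningful cross-check.
"""

from __future__ import annotations

import numpy as np


def per_base_overlap_bp(exons: list[tuple[int, int]], iv: tuple[int, int], length: int) -> int:
    """Exonic overlap by explicit per-base membership."""
    exonic = np.zeros(length, dtype=bool)
    for s, e in exons:
        exonic[s:e] = True
    probe = np.zeros(length, dtype=bool)
    probe[max(0, iv[0]) : min(length, iv[1])] = True
    return int((exonic & probe).sum())


def classify_oracle(
    exons: list[tuple[int, int]],
    repeats: list[tuple[int, int, str]],  # (start, end, ere_class)
    length: int,
    min_overlap_bp: int = 10,
    standalone_cov_min: float = 0.80,
    terminal_exon_cov_min: float = 0.50,
    terminus_tolerance_bp: int = 10,
) -> tuple[str, str]:
    """(category, class label) by per-base coverage + literal rule evaluation."""
    exonic = np.zeros(length, dtype=bool)
    for s, e in exons:
        exonic[s:e] = True
    exonic_len = int(exonic.sum())

    retained = []
    for s, e, cls in repeats:
        mask = np.zeros(length, dtype=bool)
        mask[max(0, s) : min(length, e)] = True
        if int((mask & exonic).sum()) >= min_overlap_bp:
            retained.append((s, e, cls, mask))
    if not retained:
        return "none", "none"

    class_masks: dict[str, np.ndarray] = {}
    for s, e, cls, mask in retained:
        class_masks.setdefault(cls, np.zeros(length, dtype=bool))
        class_masks[cls] |= mask & exonic
    class_bp = {cls: int(m.sum()) for cls, m in class_masks.items()}
    contributing = sorted(c for c, bp in class_bp.items() if bp >= min_overlap_bp)
    label = "multiple" if len(contributing) >= 2 else contributing[0]

    if any(bp >= standalone_cov_min * exonic_len for bp in class_bp.values()):
        return "standalone", label

    exons_sorted = sorted(exons)
    first, last = exons_sorted[0], exons_sorted[-1]
    for s, e, cls, mask in retained:
        for exon, is_first in ((first, True), (last, False)):
            ebp = max(0, min(e, exon[1]) - max(s, exon[0]))
            if ebp < terminal_exon_cov_min * (exon[1] - exon[0]):
                continue
            if is_first and s <= exon[0] + terminus_tolerance_bp:
                return "terminal_exon", label
            if not is_first and e >= exon[1] - terminus_tolerance_bp:
                return "terminal_exon", label
    return "embedded", label


def tier_oracle(
    query: dict[str, dict],
    reference: dict[str, dict],
    monoexonic_reciprocal_min: float = 0.80,
) -> dict[str, str]:
    """All-pairs junction-set tiering.

    Transcripts are dicts with chrom, strand, exons (sorted list of
    half-open pairs). Returns query id -> tier.
    """

    def junctions(t):
        ex = t["exons"]
        return {(a[1], b[0]) for a, b in zip(ex, ex[1:])}

    def span(t):
        return t["exons"][0][0], t["exons"][-1][1]

    def exonic_bp(a, b):
        return sum(
            max(0, min(ea[1], eb[1]) - max(ea[0], eb[0]))
            for ea in a["exons"]
            for eb in b["exons"]
        )

    tiers = {}
    for qid, q in query.items():
        qj = junctions(q)
        tier = "novel"
        for r in reference.values():
            if (r["chrom"], r["strand"]) != (q["chrom"], q["strand"]):
                continue
            rj = junctions(r)
            if qj and qj == rj:
                tier = "full"
                break
            if not qj and not rj:
                qs, qe = span(q)
                rs, re_ = span(r)
                ov = max(0, min(qe, re_) - max(qs, rs))
                if ov and min(ov / (qe - qs), ov / (re_ - rs)) >= monoexonic_reciprocal_min:
                    tier = "full"
                    break
        if tier == "full":
            tiers[qid] = tier
            continue
        for r in reference.values():
            if (r["chrom"], r["strand"]) != (q["chrom"], q["strand"]):
                continue
            if (qj & junctions(r)) or exonic_bp(q, r) >= 1:
                tier = "partial"
                break
        tiers[qid] = tier
    return tiers


def size_factors_oracle(mat: np.ndarray) -> np.ndarray:
    """Median-of-ratios by explicit loops over a features x samples matrix."""
    n_feat, n_samp = mat.shape
    keep = [i for i in range(n_feat) if all(mat[i, j] > 0 for j in range(n_samp))]
    refs = []
    for i in keep:
        prod = 1.0
        for j in range(n_samp):
            prod *= mat[i, j]
        refs.append(prod ** (1.0 / n_samp))
    factors = []
    for j in range(n_samp):
        ratios = sorted(mat[i, j] / refs[k] for k, i in enumerate(keep))
        m = len(ratios)
        med = ratios[m // 2] if m % 2 else 0.5 * (ratios[m // 2 - 1] + ratios[m // 2])
        factors.append(med)
    return np.array(factors)


def de_bruijn_dna(k: int) -> str:
    """A de Bruijn sequence B(4, k) over ACGT, linearized so that every
    k-mer occurs exactly once (standard greedy prefer-largest construction)."""
    alphabet = "ACGT"
    n = len(alphabet)
    a = [0] * (n * k)
    seq: list[int] = []

    def db(t: int, p: int) -> None:
        if t > k:
            if k % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, n):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    cyc = "".join(alphabet[i] for i in seq)
    return cyc + cyc[: k - 1]
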