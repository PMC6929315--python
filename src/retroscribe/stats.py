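"""Differential-expression gates, signature scores and qRT-PCR quantification.

Two selection gates drive the analysis:

* treatment-responsive features: paired two-tailed t-test on
  log2(normalized + 1) between pre- and post-treatment samples of the same
  patient, selected at |fold change| >= 2 and p <= 0.006;
* multigroup features: one-way ANOVA on log2(normalized + 1) across sample
  groups, selected at Benjamini-Hochberg q <= 0.05.

Fold changes are ratios of linear-scale group means with a pseudocount
of 1. Signature gene sets are scored by the mean of log2(normalized + 1)
over their member genes ("average expression as an index"). qRT-PCR CT
values are converted to relative abundances by the delta-CT method,
2^-(CT_target - CT_reference), normalized to a reference gene (HPRT by
default), and summed into a per-sample cumulative score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig

GROUPS = ("healthy", "MDS", "CMML", "AML")
TIMEPOINTS = ("pre", "C1", "C6", "NA")
OUTCOMES = ("CR", "FAIL", "other", "NA")
CELL_TYPES = ("HSC", "CD4", "CD8")


@dataclass
class SampleMeta:
    sample_id: str
    group: str
    timepoint: str = "NA"
    outcome: str = "NA"
    cell_type: str = "HSC"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.sample_id}: unknown group {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"{self.sample_id}: unknown timepoint {self.timepoint!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"{self.sample_id}: unknown outcome {self.outcome!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"{self.sample_id}: unknown cell_type {self.cell_type!r}")
        if self.timepoint in ("C1", "C6") and not self.patient_id:
            raise ValueError(
                f"{self.sample_id}: post-treatment samples need a patient_id"
            )


def meta_to_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "group": [m.group for m in meta],
            "timepoint": [m.timepoint for m in meta],
            "outcome": [m.outcome for m in meta],
            "cell_type": [m.cell_type for m in meta],
            "patient_id": [m.patient_id for m in meta],
        }
    ).set_index("sample_id", drop=False)


@dataclass
class DEResult:
    feature_id: str
    log2_fold_change: float
    p_value: float
    q_value: float
    direction: str
    selected: bool = False


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2p1(x: pd.DataFrame | np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def _pair_samples(
    meta: pd.DataFrame, pre: str, post: str
) -> list[tuple[str, str]]:
    """(pre_sample, post_sample) per patient; errors on orphans."""
    pre_by_patient: dict[str, str] = {}
    post_by_patient: dict[str, str] = {}
    for _, row in meta.iterrows():
        if row["timepoint"] == pre and row["patient_id"]:
            pre_by_patient[row["patient_id"]] = row["sample_id"]
        elif row["timepoint"] == post and row["patient_id"]:
            post_by_patient[row["patient_id"]] = row["sample_id"]
    orphans = sorted(set(pre_by_patient) ^ set(post_by_patient))
    if orphans:
        raise ValueError(f"unpaired patients for {pre} vs {post}: {orphans}")
    patients = sorted(pre_by_patient)
    if len(patients) < 2:
        raise ValueError("paired test needs >= 2 complete pre/post pairs")
    return [(pre_by_patient[p], post_by_patient[p]) for p in patients]


def responsive_select(
    norm_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("pre", "C6"),
    cfg: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Select treatment-responsive features by a paired pre/post contrast.

    Returns one row per feature with log2_fold_change, p_value, q_value,
    direction and the boolean ``selected`` gate
    (|FC| >= fc_min and p <= p_responsive).
    """
    pre_tp, post_tp = contrast
    pairs = _pair_samples(meta, pre_tp, post_tp)
    pre_cols = [a for a, _ in pairs]
    post_cols = [b for _, b in pairs]
    pre_log = _log2p1(norm_matrix[pre_cols])
    post_log = _log2p1(norm_matrix[post_cols])

    with np.errstate(invalid="ignore", divide="ignore"):
        _t, p = sps.ttest_rel(post_log, pre_log, axis=1)

    pre_mean = norm_matrix[pre_cols].mean(axis=1).to_numpy()
    post_mean = norm_matrix[post_cols].mean(axis=1).to_numpy()
    fc = (post_mean + 1.0) / (pre_mean + 1.0)
    log2_fc = np.log2(fc)

    tested = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    abs_fc = np.maximum(fc, 1.0 / fc)
    selected = tested & (abs_fc >= cfg.fc_min) & (p <= cfg.p_responsive)
    return pd.DataFrame(
        {
            "feature_id": norm_matrix.index,
            "log2_fold_change": log2_fc,
            "p_value": p,
            "q_value": q,
            "direction": np.where(log2_fc >= 0, "up", "down"),
            "selected": selected,
        }
    ).set_index("feature_id", drop=False)


def multigroup_select(
    norm_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str = "group",
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, list[str]]:
    """One-way ANOVA across sample groups on log2(normalized + 1).

    Returns (results, excluded_feature_ids); zero-variance features are
    excluded from testing and listed separately. Selection gate:
    q <= q_de.
    """
    groups = meta.loc[norm_matrix.columns, grouping]
    levels = sorted(groups.dropna().unique())
    if len(levels) < 2:
        raise ValueError("multigroup comparison needs >= 2 groups")
    cols_by_level = {g: groups.index[groups == g].tolist() for g in levels}
    for g, cols in cols_by_level.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has {len(cols)} sample(s); need >= 2")

    log_mat = pd.DataFrame(
        _log2p1(norm_matrix), index=norm_matrix.index, columns=norm_matrix.columns
    )
    variances = log_mat.var(axis=1)
    excluded = variances.index[variances == 0].tolist()
    tested_ids = variances.index[variances > 0]

    arrays = [log_mat.loc[tested_ids, cols].to_numpy() for cols in cols_by_level.values()]
    if len(tested_ids):
        with np.errstate(invalid="ignore", divide="ignore"):
            _f, p = sps.f_oneway(*arrays, axis=1)
        q = bh_adjust(np.nan_to_num(p, nan=1.0))
    else:
        p = np.array([])
        q = np.array([])

    group_means = {
        g: norm_matrix.loc[tested_ids, cols].mean(axis=1).to_numpy()
        for g, cols in cols_by_level.items()
    }
    mean_mat = np.column_stack([group_means[g] for g in levels])
    hi = mean_mat.max(axis=1)
    lo = mean_mat.min(axis=1)
    log2_fc = np.log2((hi + 1.0) / (lo + 1.0))
    top_group = np.asarray(levels)[mean_mat.argmax(axis=1)]

    results = pd.DataFrame(
        {
            "feature_id": tested_ids,
            "log2_fold_change": log2_fc,
            "p_value": p,
            "q_value": q,
            "direction": top_group,
            "selected": q <= cfg.q_de,
        }
    ).set_index("feature_id", drop=False)
    return results, excluded


def family_aggregate(
    repeat_counts: pd.DataFrame,
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Sum repeat-locus counts into family groups.

    Locus ids of the form ``name|chrom:start-end`` are mapped by their
    name part; loci absent from the map land in an ``ungrouped`` row.
    Totals over mapped loci are conserved.
    """
    names = [str(ix).split("|", 1)[0] for ix in repeat_counts.index]
    group_of = [grouping.get(n, "ungrouped") for n in names]
    out = repeat_counts.groupby(pd.Index(group_of, name="family_group")).sum()
    return out.sort_index()


def prefix_grouping(names: Iterable[str], prefixes: Sequence[str]) -> dict[str, str]:
    """Build a name -> family-group map from family-name prefixes (longest
    prefix wins; e.g. LTR12C and LTR12E -> LTR12)."""
    ordered = sorted(prefixes, key=len, reverse=True)
    out: dict[str, str] = {}
    for n in names:
        for p in ordered:
            if n.startswith(p):
                out[n] = p
                break
    return out


def signature_index(
    norm_matrix: pd.DataFrame, gene_set: Iterable[str]
) -> tuple[pd.Series, list[str]]:
    """Per-sample signature score: mean log2(normalized + 1) over the set.

    Returns (scores, missing_genes); raises if no set gene is present.
    """
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in norm_matrix.index]
    missing = [g for g in gene_set if g not in norm_matrix.index]
    if not present:
        raise ValueError("no gene of the signature set is present in the matrix")
    scores = pd.Series(
        _log2p1(norm_matrix.loc[present]).mean(axis=0),
        index=norm_matrix.columns,
        name="signature_index",
    )
    return scores, missing


@dataclass
class QPCRResult:
    relative: pd.DataFrame  # 2^-(dCT) per target x sample, reference excluded
    cumulative: pd.Series  # sum of relative abundances per sample
    group_p_value: Optional[float] = None
    groups: Optional[tuple[str, str]] = None


def delta_ct_quantify(
    ct_table: pd.DataFrame,
    reference_gene: str = "HPRT",
    group_labels: Optional[pd.Series] = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> QPCRResult:
    """Delta-CT relative quantification against a reference gene.

    relative = 2^-(CT_target - CT_reference) per sample; the cumulative
    score is the sum over targets. When two-group labels are supplied, the
    cumulative scores are compared by a two-tailed t-test.
    """
    if reference_gene not in ct_table.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from CT table")
    ref = ct_table.loc[reference_gene]
    missing = ref.index[ref.isna()].tolist()
    if missing:
        raise ValueError(f"missing reference CT for sample(s): {missing}")
    targets = ct_table.drop(index=reference_gene)
    rel = np.power(2.0, -(targets - ref))
    cumulative = rel.sum(axis=0)
    cumulative.name = "cumulative_expression"

    p_value: Optional[float] = None
    pair: Optional[tuple[str, str]] = None
    if group_labels is not None:
        labels = group_labels.reindex(cumulative.index).dropna()
        levels = sorted(labels.unique())
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 groups for the t-test, got {levels}")
        a = cumulative[labels.index[labels == levels[0]]]
        b = cumulative[labels.index[labels == levels[1]]]
        _t, p_value = sps.ttest_ind(a, b, equal_var=not cfg.welch)
        pair = (levels[0], levels[1])
    return QPCRResult(rel, cumulative, p_value, pair)
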