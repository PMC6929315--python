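import numpy as np
import pandas as pd
import pytest

from retroscribe.stats import (
    SampleMeta,
    bh_adjust,
    delta_ct_quantify,
    family_aggregate,
    multigroup_select,
    prefix_grouping,
    responsive_select,
    signature_index,
)
from retroscribe.synth import multigroup_design, paired_design, simulate_counts


class TestBhAdjust:
    def test_hand_evaluated_step_up(self):
        # step-up: q_i = min over j>=i of p_j * n / j -> all 0.04
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_order_preserving_on_sorted_p(self):
        p = np.sort(np.random.default_rng(0).uniform(size=50))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()


class TestResponsiveSelect:
    def _matrix(self, pre_vals, post_vals, n_pairs):
        meta = paired_design(n_pairs)
        cols = meta["sample_id"].tolist()
        data = {}
        for i in range(n_pairs):
            data[f"P{i+1:03d}_pre"] = pre_vals[:, i]
            data[f"P{i+1:03d}_C6"] = post_vals[:, i]
        return pd.DataFrame(data)[cols], meta

    def test_planted_fourfold_induction_selected(self, cfg, rng):
        pre = rng.normal(100, 1, size=(1, 5)).clip(1)
        post = 4 * pre + rng.normal(0, 0.5, size=(1, 5))
        norm, meta = self._matrix(pre, post, 5)
        res = responsive_select(norm, meta, ("pre", "C6"), cfg)
        assert bool(res["selected"].iloc[0])
        assert res["log2_fold_change"].iloc[0] == pytest.approx(2.0, abs=0.1)

    def test_large_fc_with_noisy_pairs_fails_p_gate(self, cfg):
        # one pair up 16-fold, one pair down 16-fold: FC high but p ~ large
        pre = np.array([[10.0, 160.0, 40.0]])
        post = np.array([[160.0, 10.0, 40.0]])
        norm, meta = self._matrix(pre, post, 3)
        res = responsive_select(norm, meta, ("pre", "C6"), cfg)
        assert not bool(res["selected"].iloc[0])

    def test_constant_feature_not_selected(self, cfg):
        pre = np.full((1, 4), 50.0)
        post = np.full((1, 4), 50.0)
        norm, meta = self._matrix(pre, post, 4)
        res = responsive_select(norm, meta, ("pre", "C6"), cfg)
        assert res["log2_fold_change"].iloc[0] == pytest.approx(0.0)
        assert not bool(res["selected"].iloc[0])

    def test_unpaired_patients_error_lists_orphans(self, cfg):
        meta = paired_design(3)
        meta = meta[meta["sample_id"] != "P002_C6"]  # orphan pre sample
        norm = pd.DataFrame(
            np.ones((2, len(meta))), columns=meta["sample_id"].tolist()
        )
        with pytest.raises(ValueError, match="P002"):
            responsive_select(norm, meta, ("pre", "C6"), cfg)

    def test_null_calibration_at_gate(self, cfg):
        """Pure-null normal noise: the p <= 0.006 rate matches 0.006."""
        rng = np.random.default_rng(42)
        n_feat, n_pairs = 10_000, 5
        log_vals = rng.normal(8.0, 0.5, size=(n_feat, 2 * n_pairs))
        norm = pd.DataFrame(2.0 ** log_vals - 1.0)
        meta = paired_design(n_pairs)
        norm.columns = meta["sample_id"].tolist()
        res = responsive_select(norm, meta, ("pre", "C6"), cfg)
        rate = (res["p_value"] <= cfg.p_responsive).mean()
        se = np.sqrt(0.006 * 0.994 / n_feat)
        assert abs(rate - 0.006) <= 3 * se


class TestMultigroupSelect:
    def test_shifted_feature_selected_constant_excluded(self, cfg):
        meta = multigroup_design(5)
        rng = np.random.default_rng(1)
        n_feat = 200
        log_vals = rng.normal(8.0, 0.3, size=(n_feat, len(meta)))
        healthy = (meta["group"] == "healthy").to_numpy()
        log_vals[0, healthy] += 5 * 0.3  # 5 within-group SDs in one group
        norm = pd.DataFrame(
            2.0 ** log_vals - 1.0, columns=meta["sample_id"].tolist()
        )
        norm.iloc[1] = 7.0  # constant feature
        res, excluded = multigroup_select(norm, meta, "group", cfg)
        assert bool(res["selected"].iloc[0])
        assert res["direction"].iloc[0] == "healthy"
        assert norm.index[1] in excluded

    def test_small_group_rejected(self, cfg):
        meta = multigroup_design(5)
        meta = meta[~meta["sample_id"].isin([f"AML_{i:02d}" for i in range(2, 6)])]
        norm = pd.DataFrame(
            np.ones((3, len(meta))), columns=meta["sample_id"].tolist()
        )
        with pytest.raises(ValueError, match="AML"):
            multigroup_select(norm, meta, "group", cfg)

    def test_bh_controls_fdr_on_mixed_simulation(self, cfg):
        """10% non-null features: empirical FDR at q <= 0.05 stays within
        0.05 + 3 SE."""
        rng = np.random.default_rng(7)
        meta = multigroup_design(5, groups=("healthy", "MDS"))
        n_feat, frac_alt = 10_000, 0.10
        n_alt = int(n_feat * frac_alt)
        log_vals = rng.normal(8.0, 0.5, size=(n_feat, len(meta)))
        target = (meta["group"] == "MDS").to_numpy()
        log_vals[:n_alt, target] += 2.0
        norm = pd.DataFrame(
            2.0 ** log_vals - 1.0, columns=meta["sample_id"].tolist()
        )
        res, _ = multigroup_select(norm, meta, "group", cfg)
        sel = res[res["selected"]]
        truly_null = sel.index.get_indexer_for(sel.index).size and (
            np.asarray([int(str(ix)) >= n_alt for ix in sel["feature_id"]])
        )
        n_sel = len(sel)
        assert n_sel > 0
        fdr = truly_null.sum() / n_sel
        se = np.sqrt(0.05 * 0.95 / n_sel)
        assert fdr <= 0.05 + 3 * se


class TestFamilyAggregate:
    def test_prefix_grouping_sums_and_conserves(self):
        counts = pd.DataFrame(
            {"s1": [5, 7, 3, 2]},
            index=["LTR12C|chr1:0-100", "LTR12E|chr1:500-600",
                   "MER54A|chr2:0-50", "weird|chr3:0-10"],
        )
        grouping = prefix_grouping(
            ["LTR12C", "LTR12E", "MER54A", "weird"], ["LTR12", "MER54"]
        )
        fam = family_aggregate(counts, grouping)
        assert fam.loc["LTR12", "s1"] == 12
        assert fam.loc["MER54", "s1"] == 3
        assert fam.loc["ungrouped", "s1"] == 2
        assert fam["s1"].sum() == counts["s1"].sum()


class TestSignatureIndex:
    def test_uniform_value_maps_to_log2(self):
        norm = pd.DataFrame({"s1": [7.0, 7.0], "s2": [1.0, 3.0]}, index=["a", "b"])
        scores, missing = signature_index(norm, ["a", "b"])
        assert scores["s1"] == pytest.approx(np.log2(8.0))
        assert missing == []

    def test_planted_shift_recovered(self, rng):
        genes = [f"g{i}" for i in range(40)]
        base = rng.normal(8, 0.2, size=(40, 6))
        shifted = base.copy()
        shifted[:, 3:] += 2.0  # +2 on log2 scale in condition B
        norm = pd.DataFrame(2.0 ** shifted - 1.0, index=genes,
                            columns=[f"s{i}" for i in range(6)])
        scores, _ = signature_index(norm, genes)
        diff = scores[["s3", "s4", "s5"]].mean() - scores[["s0", "s1", "s2"]].mean()
        assert diff == pytest.approx(2.0, abs=0.15)

    def test_absent_genes_reported_all_absent_error(self):
        norm = pd.DataFrame({"s1": [1.0]}, index=["a"])
        _, missing = signature_index(norm, ["a", "zzz"])
        assert missing == ["zzz"]
        with pytest.raises(ValueError):
            signature_index(norm, ["zzz"])


class TestDeltaCt:
    def test_delta_ct_examples(self):
        ct = pd.DataFrame(
            {"s1": [25.0, 20.0, 20.0]}, index=["tgt", "eq", "HPRT"]
        )
        res = delta_ct_quantify(ct)
        assert res.relative.loc["tgt", "s1"] == pytest.approx(2 ** -5)  # 0.03125
        assert res.relative.loc["eq", "s1"] == pytest.approx(1.0)
        assert res.cumulative["s1"] == pytest.approx(2 ** -5 + 1.0)

    def test_missing_reference_ct_names_sample(self):
        ct = pd.DataFrame({"s1": [25.0, 20.0], "s2": [25.0, np.nan]},
                          index=["tgt", "HPRT"])
        with pytest.raises(ValueError, match="s2"):
            delta_ct_quantify(ct)

    def test_group_t_test_matches_independent_reference(self, rng):
        """Two-sided two-sample p agrees with statsmodels to 1e-10."""
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        samples = [f"s{i}" for i in range(8)]
        ct = pd.DataFrame(
            rng.normal(25, 1.5, size=(4, 8)), index=["a", "b", "c", "HPRT"],
            columns=samples,
        )
        labels = pd.Series(["CR"] * 4 + ["FAIL"] * 4, index=samples)
        res = delta_ct_quantify(ct, group_labels=labels)
        cum = res.cumulative
        _, p_ref, _ = sm_ttest(
            cum[labels == "CR"], cum[labels == "FAIL"], usevar="pooled"
        )
        assert res.group_p_value == pytest.approx(p_ref, abs=1e-10)


class TestSampleMeta:
    def test_post_treatment_sample_requires_patient(self):
        with pytest.raises(ValueError, match="patient_id"):
            SampleMeta("x", "MDS", "C6")

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            SampleMeta("x", "notagroup")
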