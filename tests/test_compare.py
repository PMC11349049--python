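"""Differential-comparison rules, normalizations, signature scoring and
over-representation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from trialomics.compare import (
    LAYER_RULES,
    ComparisonRule,
    EffectMetric,
    FeatureMatrix,
    GeneSet,
    Layer,
    Scale,
    baseline_normalize,
    differential_features,
    log2_transform,
    overrepresentation_test,
    quantile_normalize,
    signature_score,
    student_t_two_sample,
)
from trialomics.simulate import SimOmicsConfig, simulate_omics


def fm(values, layer=Layer.NPX, scale=Scale.LOG2, samples=None):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.index = [f"F{i}" for i in range(df.shape[0])]
    df.columns = samples or [f"S{i}" for i in range(df.shape[1])]
    return FeatureMatrix(values=df, layer=layer, scale=scale)


class TestStudentT:
    def test_identical_vectors(self):
        t, p = student_t_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form(self):
        """Hand-computed pooled-variance t for a=(1,2,3), b=(1..6)."""
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_exp = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p_exp = 2 * stats.t.sf(abs(t_exp), len(a) + len(b) - 2)
        t, p = student_t_two_sample(a, b)
        assert t == pytest.approx(t_exp, rel=1e-12)
        assert p == pytest.approx(p_exp, rel=1e-12)

    def test_parametric_p_near_permutation_p(self):
        """Exhaustive label-permutation p brackets the parametric p for
        symmetric noise at small n."""
        rng = np.random.default_rng(4)
        pooled = rng.normal(size=8)
        a_obs, b_obs = pooled[:4], pooled[4:]
        _, p_param = student_t_two_sample(a_obs, b_obs)
        obs = abs(a_obs.mean() - b_obs.mean())
        count = 0
        combos = list(itertools.combinations(range(8), 4))
        for idx in combos:
            sel = np.zeros(8, dtype=bool)
            sel[list(idx)] = True
            diff = abs(pooled[sel].mean() - pooled[~sel].mean())
            count += diff >= obs - 1e-12
        p_perm = count / len(combos)
        assert abs(p_param - p_perm) < 0.15

    def test_zero_pooled_variance_not_testable(self):
        t, p = student_t_two_sample([2.0, 2.0], [3.0, 3.0])
        assert np.isnan(t) and np.isnan(p)

    def test_min_group_size(self):
        with pytest.raises(ValueError):
            student_t_two_sample([1.0], [1.0, 2.0])


class TestTransforms:
    def test_log2_values(self):
        m = fm([[0.0, 7.0]], layer=Layer.RNA_TPM, scale=Scale.LINEAR)
        out = log2_transform(m, pseudocount=1.0)
        assert out.values.iloc[0, 0] == pytest.approx(0.0)
        assert out.values.iloc[0, 1] == pytest.approx(3.0)
        assert out.scale is Scale.LOG2

    def test_log2_preserves_order_and_rejects_relog(self):
        m = fm([[1.0, 5.0, 2.0]], layer=Layer.RNA_TPM, scale=Scale.LINEAR)
        out = log2_transform(m)
        assert list(out.values.iloc[0].rank()) == list(m.values.iloc[0].rank())
        with pytest.raises(ValueError, match="already"):
            log2_transform(out)

    def test_quantile_normalize_hand_case(self):
        m = fm([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_quantile_normalize_identical_columns_unchanged(self):
        m = fm([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_quantile_normalize_idempotent_and_equal_means(self):
        rng = np.random.default_rng(0)
        m = fm(rng.normal(size=(40, 6)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )
        means = once.values.mean(axis=0)
        np.testing.assert_allclose(means, means.iloc[0], atol=1e-12)

    def test_quantile_normalize_tie_handling(self):
        # column with a tie: both tied entries get the mean of the spanned refs
        m = fm([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(m)
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        assert out.values.iloc[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out.values.iloc[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_baseline_normalize(self):
        m = fm(
            [[10.0, 12.0, 7.0]],
            samples=["s_bl", "s_c2", "s_other_bl"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["s_bl", "s_c2", "s_other_bl"],
                "subject_id": ["A", "A", "B"],
                "timepoint": ["BL", "C2D1", "BL"],
            }
        )
        out = baseline_normalize(m, meta)
        assert list(out.values.columns) == ["s_c2"]
        assert out.values.iloc[0, 0] == pytest.approx(2.0)

    def test_baseline_normalize_missing_baseline_drops_subject(self):
        m = fm([[10.0, 12.0]], samples=["a_bl", "b_c2"])
        meta = pd.DataFrame(
            {
                "sample_id": ["a_bl", "b_c2"],
                "subject_id": ["A", "B"],
                "timepoint": ["BL", "C2D1"],
            }
        )
        with pytest.warns(UserWarning, match="lacks a baseline"):
            out = baseline_normalize(m, meta)
        assert out.values.shape[1] == 0


class TestDifferentialFeatures:
    def _meta(self, n_per_group):
        n = 2 * n_per_group
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "group_label": ["A"] * n_per_group + ["B"] * n_per_group,
            }
        )

    def test_planted_sensitivity_and_fpr(self):
        """RNA preset detects >= 45/50 planted log2 shifts of 2.0 and keeps
        the null false-positive rate <= 7% (20 seeded replicates)."""
        sens, fprs = [], []
        for seed in range(20):
            matrix, meta, truth = simulate_omics(SimOmicsConfig(seed=seed))
            m = FeatureMatrix(values=matrix, layer=Layer.RNA_TPM, scale=Scale.LOG2)
            res = differential_features(
                m, meta, ("A", "B"), LAYER_RULES[Layer.RNA_TPM]
            )
            hit = res[res["significant"]]["feature"]
            true_set = set(truth["true_features"])
            sens.append(len(set(hit) & true_set))
            n_null = len(res) - len(true_set)
            fprs.append(len(set(hit) - true_set) / n_null)
        assert np.mean(sens) >= 45
        assert np.mean(fprs) <= 0.07

    def test_all_null_significant_fraction_small(self):
        matrix, meta, _ = simulate_omics(
            SimOmicsConfig(n_true=0, n_features=2000, seed=1)
        )
        m = FeatureMatrix(values=matrix, layer=Layer.RNA_TPM, scale=Scale.LOG2)
        res = differential_features(m, meta, ("A", "B"), LAYER_RULES[Layer.RNA_TPM])
        assert res["significant"].mean() < 0.05

    def test_identical_groups_nothing_significant(self):
        vals = np.tile(np.arange(10.0)[:, None], (1, 8))
        m = fm(vals)
        meta = pd.DataFrame(
            {"sample_id": m.sample_ids, "group_label": ["A"] * 4 + ["B"] * 4}
        )
        res = differential_features(m, meta, ("A", "B"), LAYER_RULES[Layer.NPX])
        assert not res["significant"].any()

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(8)
        m = fm(rng.normal(size=(30, 10)))
        meta = self._meta(5)
        ab = differential_features(m, meta, ("A", "B"), LAYER_RULES[Layer.NPX])
        ba = differential_features(m, meta, ("B", "A"), LAYER_RULES[Layer.NPX])
        ab = ab.sort_values("feature").reset_index(drop=True)
        ba = ba.sort_values("feature").reset_index(drop=True)
        np.testing.assert_allclose(ab["effect"], -ba["effect"], atol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-12)

    def test_small_group_named_in_error(self):
        m = fm(np.ones((3, 3)))
        meta = pd.DataFrame(
            {"sample_id": m.sample_ids, "group_label": ["A", "A", "B"]}
        )
        with pytest.raises(ValueError, match="'B'"):
            differential_features(m, meta, ("A", "B"), LAYER_RULES[Layer.NPX])

    def test_log2fc_requires_log2_scale(self):
        m = fm(np.ones((3, 4)) + np.arange(4.0), layer=Layer.RNA_TPM, scale=Scale.LINEAR)
        meta = self._meta(2)
        meta["sample_id"] = m.sample_ids
        with pytest.raises(ValueError, match="log2"):
            differential_features(m, meta, ("A", "B"), LAYER_RULES[Layer.RNA_TPM])

    def test_type_one_error_of_p_gate_alone(self):
        """The p < 0.05 gate alone fires on 5% +/- 1% of 10,000 null features."""
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(10_000, 12))
        m = fm(vals)
        meta = self._meta(6)
        rule = ComparisonRule(0.05, EffectMetric.LOG2FC, 0.0)
        res = differential_features(m, meta, ("A", "B"), rule)
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestSignatureScore:
    def test_single_member_equals_zscore(self):
        rng = np.random.default_rng(1)
        m = fm(rng.normal(size=(5, 6)))
        score = signature_score(m, GeneSet("one", {"F2"}))
        row = m.values.loc["F2"]
        z = (row - row.mean()) / row.std(ddof=1)
        np.testing.assert_allclose(score, z)

    def test_scores_sum_to_zero(self):
        rng = np.random.default_rng(2)
        m = fm(rng.normal(size=(8, 5)))
        score = signature_score(m, GeneSet("s", {"F0", "F3", "F7"}))
        assert abs(score.sum()) < 1e-9

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(4, 6))
        m1 = fm(vals)
        vals2 = vals.copy()
        vals2[1] = 7.0 * vals2[1] - 3.0  # rescale one member
        m2 = fm(vals2)
        gs = GeneSet("s", {"F0", "F1", "F2"})
        np.testing.assert_allclose(
            signature_score(m1, gs), signature_score(m2, gs), atol=1e-12
        )

    def test_union_is_count_weighted_mean(self):
        rng = np.random.default_rng(9)
        m = fm(rng.normal(size=(10, 7)))
        s1 = signature_score(m, GeneSet("a", {"F0", "F1"}))
        s2 = signature_score(m, GeneSet("b", {"F2", "F3", "F4"}))
        su = signature_score(m, GeneSet("u", {"F0", "F1", "F2", "F3", "F4"}))
        np.testing.assert_allclose(su, (2 * s1 + 3 * s2) / 5, atol=1e-12)

    def test_no_usable_members(self):
        m = fm(np.ones((2, 4)))  # zero variance everywhere
        with pytest.raises(ValueError, match="usable"):
            signature_score(m, GeneSet("s", {"F0"}))


class TestOverrepresentation:
    def test_pathway_equals_universe(self):
        u = GeneSet("u", {f"g{i}" for i in range(10)})
        sig = GeneSet("sig", {"g0", "g1"})
        res = overrepresentation_test(sig, u, u)
        assert res["p"] == pytest.approx(1.0)

    def test_full_overlap_closed_form(self):
        u = GeneSet("u", {f"g{i}" for i in range(20)})
        path = GeneSet("p", {f"g{i}" for i in range(5)})
        sig = GeneSet("s", {f"g{i}" for i in range(5)})
        res = overrepresentation_test(sig, path, u)
        assert res["p"] == pytest.approx(1 / comb(20, 5), rel=1e-9)
        assert res["significant"]

    def test_matches_enumeration_small_universe(self):
        """Upper-tail p equals exhaustive enumeration over all significant-set
        draws for a universe of 12."""
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(12)]
        u = GeneSet("u", set(genes))
        for _ in range(10):
            path = set(rng.choice(genes, size=5, replace=False))
            sig = set(rng.choice(genes, size=4, replace=False))
            res = overrepresentation_test(GeneSet("s", sig), GeneSet("p", path), u)
            k_obs = len(sig & path)
            total = hits = 0
            for combo in itertools.combinations(genes, len(sig)):
                total += 1
                hits += len(set(combo) & path) >= k_obs
            assert res["p"] == pytest.approx(hits / total, rel=1e-9)

    def test_disjoint_pathway_not_testable(self):
        u = GeneSet("u", {"a", "b", "c"})
        res = overrepresentation_test(
            GeneSet("s", {"a"}), GeneSet("p", {"zzz"}), u
        )
        assert not res["testable"]


def test_layer_presets_match_reporting_rules():
    assert LAYER_RULES[Layer.RNA_TPM].effect_threshold == 1.0
    assert LAYER_RULES[Layer.NPX].effect_threshold == 0.75
    assert LAYER_RULES[Layer.PCT_PARENT_CYTOF].p_threshold == 0.01
    assert LAYER_RULES[Layer.PCT_PARENT_X50].effect_threshold == 20.0
    assert LAYER_RULES[Layer.PCT_MIF].effect_threshold == 5.0
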