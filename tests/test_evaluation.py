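import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slesa import (ConfusionCounts, FeatureMatrix, PipelineConfig,
                   SyntheticSpec, acc, auc, confusion, cross_validate,
                   export_score_histograms, generate,
                   kl_component_divergence, tnr, tpr)
from slesa.classify import DecisionRecord
from slesa.evaluation import kl_from_masses


def concordance_auc(scores, truth):
    """Exhaustive pairwise concordance: P(s_pos > s_neg) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, truth) if t == "m"]
    neg = [s for s, t in zip(scores, truth) if t == "n"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionAndRates:
    def test_all_correct_has_no_errors(self):
        c = confusion(["m", "n", "m"], ["m", "n", "m"])
        assert (c.FP, c.FN) == (0, 0) and c.total == 3

    def test_all_wrong_has_no_hits(self):
        c = confusion(["n", "m"], ["m", "n"])
        assert (c.TP, c.TN) == (0, 0)

    def test_hand_counted_cells(self):
        preds = ["m", "m", "n", "n", "m", "n", "m", "n"]
        truth = ["m", "n", "m", "n", "m", "n", "n", "m"]
        c = confusion(preds, truth)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 2, 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["m"], ["m", "n"])

    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(3, 0, 0, 1), 0.75),
        (ConfusionCounts(62, 82, 18, 38), 0.72),
    ])
    def test_rate_formulas(self, counts, expected):
        if counts.TN + counts.FP == 0:
            assert tpr(counts) == pytest.approx(expected)
        else:
            assert acc(counts) == pytest.approx(expected)

    def test_zero_denominator_reports_absent_not_zero(self):
        assert tnr(ConfusionCounts(3, 0, 0, 1)) is None
        assert tnr(ConfusionCounts(0, 0, 5, 0)) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(st.integers(0, 50), st.integers(0, 50),
                     st.integers(0, 50), st.integers(0, 50)))
    def test_accuracy_decomposes_over_class_rates(self, cells):
        """ACC = (TPR*P + TNR*N) / (P + N) exactly, whenever defined."""
        c = ConfusionCounts(*cells)
        if c.total == 0:
            return
        P, N = c.TP + c.FN, c.TN + c.FP
        lhs = acc(c) * (P + N)
        rhs = (tpr(c) or 0.0) * P + (tnr(c) or 0.0) * N
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3, 2, -1, -2], ["m", "m", "n", "n"]) == 1.0

    def test_constant_scores_are_chance(self):
        assert auc([1, 1, 1, 1], ["m", "n", "m", "n"]) == 0.5

    def test_hand_concordance_example(self):
        assert auc([2, 1, 1.5, 0], ["m", "m", "n", "n"]) == \
            pytest.approx(0.75)

    def test_single_class_is_undefined(self):
        assert auc([1, 2], ["m", "m"]) is None

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(4, 60))
    def test_matches_exhaustive_pairwise_concordance(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.standard_normal(n), 1)  # force some ties
        truth = np.where(rng.random(n) < 0.5, "m", "n")
        if len(set(truth)) < 2:
            return
        assert auc(scores, truth) == pytest.approx(
            concordance_auc(scores, truth), abs=1e-12)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(30)
        truth = np.array(["m"] * 15 + ["n"] * 15)
        a = auc(scores, truth)
        b = auc(np.exp(2.0 * scores) + 5.0, truth)
        assert a == pytest.approx(b, abs=1e-12)


SMALL_SPEC = SyntheticSpec(n_per_class=15, l=32, atoms_per_class=4,
                           sparsity=2, noise_sigma=0.01, seed=21)
SMALL_CONFIG = PipelineConfig(mode="blockboost", block_length=8)


class TestCrossValidate:
    def test_folds_partition_and_stratify(self):
        feats, _ = generate(SMALL_SPEC)
        report = cross_validate(feats, SMALL_CONFIG, folds=5, seed=1)
        assert report.per_fold["n"].sum() == feats.k
        # class ratio per fold within one sample of the global split
        for _, row in report.per_fold.iterrows():
            pos = row.TP + row.FN
            assert abs(pos - row.n / 2) <= 1

    def test_same_seed_reproduces_metrics(self):
        feats, _ = generate(SMALL_SPEC)
        a = cross_validate(feats, SMALL_CONFIG, folds=5, seed=3)
        b = cross_validate(feats, SMALL_CONFIG, folds=5, seed=3)
        assert a.acc == b.acc and a.auc == b.auc
        assert a.per_fold.equals(b.per_fold)

    def test_near_clean_data_classifies_accurately(self):
        feats, _ = generate(SMALL_SPEC)
        report = cross_validate(feats, SMALL_CONFIG, folds=5, seed=0)
        assert report.acc >= 0.9

    def test_too_few_samples_per_class_rejected(self):
        feats, _ = generate(SMALL_SPEC)
        with pytest.raises(ValueError, match="at least"):
            cross_validate(feats, SMALL_CONFIG, folds=20)

    def _fold_hashes(self, artifacts):
        out = []
        for art in artifacts:
            h = hashlib.sha256()
            if art[0] == "blockboost":
                for b in art[1].blocks:
                    h.update(np.ascontiguousarray(b).tobytes())
            elif art[0] == "patchsample":
                h.update(np.ascontiguousarray(art[1].matrix).tobytes())
            else:
                h.update(np.ascontiguousarray(art[1]).tobytes())
            out.append(h.hexdigest())
        return out

    @pytest.mark.parametrize("config", [
        SMALL_CONFIG,
        PipelineConfig(mode="patchsample", block_length=8),
        PipelineConfig(mode="src", pca_components=5),
    ])
    def test_held_out_samples_never_touch_fitted_artifacts(self, config):
        """Perturbing a held-out sample's values must not change any
        training-fold dictionary, PCA fit or learned atoms (hash check)."""
        feats, _ = generate(SMALL_SPEC)
        _, arts_a = cross_validate(feats, config, folds=5, seed=2,
                                   return_artifacts=True)
        # find one sample of fold 0's test set by rerunning the same split
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=2)
        y = (feats.labels == "m").astype(int)
        _, test_idx = next(iter(skf.split(feats.values, y)))
        perturbed = feats.values.copy()
        perturbed[test_idx[0]] += 37.0
        feats_b = FeatureMatrix(perturbed, feats.labels, feats.sample_ids)
        _, arts_b = cross_validate(feats_b, config, folds=5, seed=2,
                                   return_artifacts=True)
        assert self._fold_hashes(arts_a)[0] == self._fold_hashes(arts_b)[0]


class TestKlDivergence:
    def test_identical_distributions_have_zero_divergence(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((40, 3))
        f = FeatureMatrix(np.vstack([vals, vals]),
                          np.array(["m"] * 40 + ["n"] * 40, dtype=object))
        np.testing.assert_allclose(kl_component_divergence(f), 0.0, atol=1e-6)

    def test_prebinned_mass_example(self):
        assert kl_from_masses([0.5, 0.5], [0.9, 0.1]) == pytest.approx(
            0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1), abs=1e-12)
        assert kl_from_masses([0.5, 0.5], [0.9, 0.1]) == pytest.approx(
            0.510825624, abs=1e-6)

    def test_disjoint_supports_grow_as_smoothing_shrinks(self):
        f = FeatureMatrix(
            np.concatenate([np.zeros(20), np.ones(20)])[:, None],
            np.array(["m"] * 20 + ["n"] * 20, dtype=object))
        coarse = kl_component_divergence(f, smoothing=1e-6)[0]
        fine = kl_component_divergence(f, smoothing=1e-10)[0]
        assert fine > coarse > 1.0

    def test_constant_component_is_zero_by_convention(self):
        f = FeatureMatrix(np.ones((10, 2)),
                          np.array(["m", "n"] * 5, dtype=object))
        np.testing.assert_array_equal(kl_component_divergence(f), 0.0)


def record(ells, label):
    return DecisionRecord("s", np.array([ells]), ells, "m", [(1.0, 1.0)],
                          label)


class TestScoreHistograms:
    def test_two_classes_give_two_groups(self, tmp_path):
        df = export_score_histograms([record(1.0, "m"), record(-1.0, "n")],
                                     tmp_path / "h.csv")
        assert set(df["true_label"]) == {"m", "n"}
        assert (tmp_path / "h.csv").exists()

    def test_empty_records_warn_and_write_empty_table(self):
        with pytest.warns(RuntimeWarning):
            df = export_score_histograms([])
        assert df.empty

    def test_bin_counts_sum_to_record_count(self):
        rng = np.random.default_rng(4)
        recs = [record(float(rng.standard_normal()),
                       "m" if i % 2 else "n") for i in range(20)]
        df = export_score_histograms(recs)
        assert df["count"].sum() == 20
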