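"""Training-set construction, classifier CV, thresholding, plausibility."""

import numpy as np
import pandas as pd
import pytest

import cofracnet as cf
from cofracnet.ppi import CvReport, ModelCv, TrainingSet
from cofracnet.similarity import PairFeatureTable


def feature_table(pairs, values, metric="m1"):
    idx = pd.MultiIndex.from_tuples(pairs, names=["protein_a", "protein_b"])
    return PairFeatureTable(pd.DataFrame({metric: values}, index=idx))


def separable_training(n=60, seed=0):
    """Positives at feature ~1, negatives at ~0: perfectly separable."""
    rng = np.random.default_rng(seed)
    pos = [(f"A{i:03d}", f"B{i:03d}") for i in range(n)]
    neg = [(f"C{i:03d}", f"D{i:03d}") for i in range(n)]
    feats = feature_table(
        pos + neg,
        np.concatenate([0.9 + 0.1 * rng.random(n), 0.1 * rng.random(n)]))
    return feats, TrainingSet(pos, neg, {}, 1.0)


class TestBuildTraining:
    def test_single_complex_complete_graph(self):
        ref = cf.ComplexCatalog({"C1": frozenset("ABC"),
                                 "C2": frozenset("DEF")})
        tr = cf.build_training(ref, "ABCDEF", seed=0)
        assert set(tr.positives) >= {("A", "B"), ("A", "C"), ("B", "C")}

    def test_pair_in_two_overlapping_complexes_counted_once(self):
        ref = cf.ComplexCatalog({"C1": frozenset("ABC"), "C2": frozenset("ABD")})
        tr = cf.build_training(ref, "ABCD", seed=0)
        assert tr.positives.count(("A", "B")) == 1
        assert sorted(tr.provenance[("A", "B")]) == ["C1", "C2"]

    def test_negatives_cross_complex_at_ratio(self):
        ref = cf.ComplexCatalog({"C1": frozenset("ABC"), "C2": frozenset("DEF")})
        tr = cf.build_training(ref, "ABCDEF", negative_ratio=1.0, seed=1)
        assert len(tr.negatives) == len(tr.positives) == 6
        intra = ref.intra_pairs()
        for pair in tr.negatives:
            assert pair not in intra
            assert pair[0] != pair[1]

    def test_no_overlap_with_detected_rejected(self):
        ref = cf.ComplexCatalog({"C1": frozenset("ABC")})
        with pytest.raises(ValueError, match="does not overlap"):
            cf.build_training(ref, ["X", "Y"], seed=0)

    def test_deterministic_given_seed(self):
        ref = cf.ComplexCatalog({f"C{i}": frozenset({f"P{i}a", f"P{i}b", f"P{i}c"})
                                 for i in range(10)})
        det = ref.members()
        t1 = cf.build_training(ref, det, seed=9)
        t2 = cf.build_training(ref, det, seed=9)
        assert t1.negatives == t2.negatives


class TestTrainAndScore:
    def test_separable_features_reach_perfect_auroc(self):
        feats, tr = separable_training()
        scores, report = cf.train_and_score(feats, tr, seed=0)
        assert report.per_model["ensemble"].pooled_auroc == pytest.approx(1.0)

    def test_permuted_labels_are_chance_level(self):
        """Label-permutation control: pooled CV auROC ~ 0.5 at n = 2000."""
        rng = np.random.default_rng(7)
        n = 1000
        pairs = [(f"X{i:04d}", f"Y{i:04d}") for i in range(2 * n)]
        feats = feature_table(pairs, rng.random(2 * n))
        labels = rng.permutation([1] * n + [0] * n)
        tr = TrainingSet([p for p, y in zip(pairs, labels) if y == 1],
                         [p for p, y in zip(pairs, labels) if y == 0], {}, 1.0)
        _, report = cf.train_and_score(feats, tr, models=("glm", "ensemble"),
                                       seed=0)
        assert abs(report.per_model["ensemble"].pooled_auroc - 0.5) < 0.1

    def test_same_seed_identical_scores(self):
        feats, tr = separable_training()
        s1, _ = cf.train_and_score(feats, tr, seed=3)
        s2, _ = cf.train_and_score(feats, tr, seed=3)
        pd.testing.assert_frame_equal(s1, s2)

    def test_no_leakage_scores_come_from_held_out_fold(self):
        """A labeled pair's score must come from the fold holding it out:
        retraining without that fold's data reproduces its score."""
        feats, tr = separable_training(n=30)
        scores, report = cf.train_and_score(feats, tr, models=("glm",), seed=0)
        labels = tr.labels()
        fold_of = report.fold_of_pair
        assert set(fold_of.values()) == set(range(5))
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        x = feats.table.loc[labels.index].to_numpy()
        y = labels.to_numpy()
        folds = np.array([fold_of[tuple(p)] for p in labels.index])
        for f in range(5):
            clf = make_pipeline(StandardScaler(),
                                LogisticRegression(max_iter=2000))
            clf.fit(x[folds != f], y[folds != f])
            expect = clf.predict_proba(x[folds == f])[:, 1]
            got = scores["glm"].loc[labels.index].to_numpy()[folds == f]
            assert np.allclose(got, expect)

    def test_single_class_fold_rejected(self):
        pairs = [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")]
        feats = feature_table(pairs, [1.0, 0.9, 0.1, 0.0])
        tr = TrainingSet(pairs[:2], pairs[2:], {}, 1.0)
        with pytest.raises(ValueError, match="folds|fold"):
            cf.train_and_score(feats, tr, k_folds=4, seed=0)

    def test_unlabeled_pairs_scored_by_full_refit(self):
        feats, tr = separable_training(n=20)
        extra = feature_table([("Z1", "Z2")], [0.95])
        feats.table = pd.concat([feats.table, extra.table])
        scores, _ = cf.train_and_score(feats, tr, seed=0)
        assert scores.loc[("Z1", "Z2"), "ensemble"] > 0.5


class TestSelectThreshold:
    @staticmethod
    def report(fpr, tpr, cut):
        cv = ModelCv([], 1.0, np.array(fpr), np.array(tpr), np.array(cut))
        return CvReport({"ensemble": cv}, 5, {})

    def test_separable_case_youden_perfect(self):
        feats, tr = separable_training()
        scores, report = cf.train_and_score(feats, tr, seed=0)
        thr = cf.select_threshold(report, "youden")
        labels = tr.labels()
        s = scores["ensemble"].loc[labels.index]
        tpr = (s[labels == 1] >= thr).mean()
        fpr = (s[labels == 0] >= thr).mean()
        assert (tpr, fpr) == (1.0, 0.0)

    def test_fixed_rule_passthrough(self):
        assert cf.select_threshold(self.report([0], [0], [1.0]),
                                   "fixed:0.84") == 0.84

    def test_youden_tie_breaks_to_higher_cutoff(self):
        rep = self.report([0.0, 0.1, 0.3], [0.6, 0.7, 0.8], [0.9, 0.6, 0.3])
        # J = 0.6 at cutoffs 0.9 and 0.6 (0.5 at 0.3); higher cutoff wins
        assert cf.select_threshold(rep, "youden") == 0.9

    def test_fpr_at_rule(self):
        rep = self.report([0.0, 0.05, 0.2], [0.5, 0.8, 1.0], [0.9, 0.7, 0.4])
        assert cf.select_threshold(rep, "fpr_at:0.1") == 0.7

    def test_empty_roc_rejected(self):
        rep = self.report([], [], [])
        with pytest.raises(ValueError, match="empty ROC"):
            cf.select_threshold(rep, "youden")

    def test_edge_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(0)
        pairs = [(f"A{i}", f"B{i}") for i in range(200)]
        s = pd.Series(rng.random(200),
                      index=pd.MultiIndex.from_tuples(pairs))
        counts = [len(cf.network_from_scores(s, t)) for t in
                  np.linspace(0, 1, 11)]
        assert counts == sorted(counts, reverse=True)


class TestFilterImplausible:
    comp = {"M1": "matrix", "O1": "OMM", "I1": "IMS", "I2": "IMS",
            "N1": "inner_membrane"}

    def test_forbidden_pairs_removed_with_reason(self):
        net = cf.ScoredNetwork({("M1", "O1"): 0.9, ("I1", "M1"): 0.8})
        out, report = cf.filter_implausible(net, self.comp)
        assert len(out) == 0
        reasons = {r for _, _, r in report.removed}
        assert reasons == {"OMM–matrix", "IMS–matrix"}

    def test_within_compartment_and_allowed_pairs_retained(self):
        net = cf.ScoredNetwork({("I1", "I2"): 0.9, ("M1", "N1"): 0.7})
        out, report = cf.filter_implausible(net, self.comp)
        assert len(out) == 2
        assert report.removed == []

    def test_unannotated_endpoint_passes_flagged(self):
        net = cf.ScoredNetwork({("M1", "UNKNOWN"): 0.9})
        out, report = cf.filter_implausible(net, self.comp)
        assert ("M1", "UNKNOWN") in out.edges
        assert report.flagged_unannotated == [("M1", "UNKNOWN")]
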