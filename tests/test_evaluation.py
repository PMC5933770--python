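"""Metrics, ROC, sequence-identity clustering, and clustered CV plumbing."""

import numpy as np
import pytest

from truncvar import (
    ConfusionCounts,
    FeatureSchema,
    Hyperparams,
    TruncatingVariant,
    auc,
    cluster_sequences,
    clustered_kfold,
    confusion,
    crossvalidate,
    metrics,
    pairwise_identity,
    reduce_features,
    roc_points,
)
from truncvar.evaluation import ClusterPartition, merge_to_k_clusters


class TestConfusion:
    def test_basic_counting(self):
        c = confusion([0.6, 0.4], ["pathogenic", "neutral"], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_all_neutral_called_positive(self):
        c = confusion([0.9] * 5, ["neutral"] * 5, 0.5)
        assert c.fp == 5 and c.tp == c.tn == c.fn == 0

    def test_cutoff_above_everything(self):
        c = confusion([0.3, 0.2], ["pathogenic", "neutral"], 0.99)
        assert c.tp == c.fp == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            confusion([0.5], ["maybe"], 0.5)


class TestMetrics:
    def test_perfect_classifier(self):
        report = metrics(ConfusionCounts(tp=10, fp=0, tn=20, fn=0))
        assert report.mcc == 1.0 and report.f_score == 1.0
        assert report.fpr == 0.0 and report.fdr == 0.0

    def test_degenerate_counts_fall_back_to_zero(self):
        report = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert report.mcc == 0.0 and report.f_score == 0.0

    def test_identities_fpr_and_fdr(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 40, size=4)
            if tn + fp == 0 or tp + fp == 0:
                continue
            report = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert report.fpr == pytest.approx(1 - report.specificity)
            precision = tp / (tp + fp)
            assert report.fdr + precision == pytest.approx(1.0)

    def test_mcc_equals_pearson_of_indicators(self):
        # independent oracle: the point correlation of call/label vectors
        rng = np.random.default_rng(1)
        for _ in range(25):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            report = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            calls = np.r_[np.ones(tp + fp), np.zeros(tn + fn)]
            truth = np.r_[np.ones(tp), np.zeros(fp), np.zeros(tn), np.ones(fn)]
            assert report.mcc == pytest.approx(np.corrcoef(calls, truth)[0, 1])


class TestRoc:
    def test_separating_scores_pass_through_corner(self):
        pts = roc_points([0.9, 0.8, 0.2, 0.1],
                         ["pathogenic", "pathogenic", "neutral", "neutral"])
        assert (0.0, 1.0) in pts
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_identical_scores_collapse(self):
        pts = roc_points([0.5, 0.5, 0.5], ["pathogenic", "neutral", "neutral"])
        assert set(pts) == {(0.0, 0.0), (1.0, 1.0)}

    def test_monotone_in_both_coordinates(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = ["pathogenic" if b else "neutral" for b in rng.random(50) < 0.4]
        pts = np.asarray(roc_points(scores, labels))
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.random(2000)
        labels = ["pathogenic" if b else "neutral" for b in rng.random(2000) < 0.5]
        assert auc(roc_points(scores, labels)) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_points([0.5, 0.6], ["neutral", "neutral"])


class TestIdentityAndClustering:
    def test_identity_examples(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKL") == 1.0
        assert pairwise_identity("ACDE", "ACDF") == pytest.approx(0.75)
        assert pairwise_identity("AAAA", "CCCC") == 0.0
        assert pairwise_identity("ACDE", "ACDF") == pairwise_identity("ACDF", "ACDE")

    def test_single_linkage_transitivity(self):
        rng = np.random.default_rng(4)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        shared_ab = "".join(rng.choice(list(aa), 50))
        shared_bc = "".join(rng.choice(list(aa), 50))
        rand = lambda n: "".join(rng.choice(list(aa), n))
        seqs = {
            "A": shared_ab + rand(50),
            "B": shared_ab + shared_bc,
            "C": rand(50) + shared_bc,
            "D": rand(100),
        }
        assert pairwise_identity(seqs["A"], seqs["C"]) < 0.35
        part = cluster_sequences(seqs)
        assert {"A", "B", "C"} in part.clusters and {"D"} in part.clusters

    def test_dissimilar_set_stays_singleton(self):
        rng = np.random.default_rng(5)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        seqs = {f"P{i}": "".join(rng.choice(list(aa), 120)) for i in range(6)}
        part = cluster_sequences(seqs)
        assert len(part.clusters) == 6

    def test_duplicates_co_cluster(self):
        part = cluster_sequences({"A": "MKV" * 20, "B": "MKV" * 20})
        assert part.clusters == [{"A", "B"}]

    def test_merge_to_k(self):
        part = ClusterPartition([{"A"}, {"B"}, {"C", "D"}, {"E"}], 0.35)
        merged = merge_to_k_clusters(part, 2)
        assert len(merged.clusters) == 2
        assert set().union(*merged.clusters) == {"A", "B", "C", "D", "E"}


class TestClusteredKfold:
    def _singletons(self, n):
        return ClusterPartition([{f"P{i}"} for i in range(n)], 0.35)

    def test_even_deal(self):
        folds = clustered_kfold(self._singletons(20), 10, seed=0)
        assert all(len(f) == 2 for f in folds)

    def test_partition_property(self):
        part = ClusterPartition([{"A", "B"}, {"C"}, {"D"}, {"E", "F"}], 0.35)
        folds = clustered_kfold(part, 2, seed=1)
        union = set().union(*folds)
        assert union == {"A", "B", "C", "D", "E", "F"}
        assert sum(len(f) for f in folds) == len(union)
        # clusters never straddle folds
        for cluster in part.clusters:
            assert sum(cluster <= fold for fold in folds) == 1

    def test_deterministic_given_seed(self):
        part = self._singletons(15)
        assert clustered_kfold(part, 5, 3) == clustered_kfold(part, 5, 3)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            clustered_kfold(self._singletons(3), 5)


@pytest.fixture(scope="module")
def cv_setup(small_cohort):
    hp = Hyperparams(shrinkage=0.2, n_trees=10, max_depth=3)
    return small_cohort, hp


class TestCrossvalidate:
    def test_eval_subset_filters_only_evaluation(self, cv_setup):
        cohort, hp = cv_setup
        both = crossvalidate(cohort.proteins, cohort.variants,
                             FeatureSchema.final46(), k=3, seed=0, hyperparams=hp)
        fs = crossvalidate(cohort.proteins, cohort.variants,
                           FeatureSchema.final46(), k=3, seed=0, hyperparams=hp,
                           eval_subset="frameshift")
        assert all(v.vtype == "frameshift" for v in fs.variants)
        # training is unchanged: the frameshift subset of the pooled scores
        # is identical between the two runs
        both_scores = {
            (v.protein_id, v.k, v.vtype): s
            for v, s in zip(both.variants, both.scores)
        }
        for v, s in zip(fs.variants, fs.scores):
            assert both_scores[(v.protein_id, v.k, v.vtype)] == s

    def test_leave_one_cluster_out_when_k_equals_clusters(self, cv_setup):
        cohort, hp = cv_setup
        used = {v.protein_id for v in cohort.variants}
        part = cluster_sequences({p: cohort.proteins[p].sequence for p in used})
        res = crossvalidate(cohort.proteins, cohort.variants,
                            FeatureSchema.final46(), k=len(part.clusters),
                            seed=0, hyperparams=hp)
        assert len(res.folds) == len(part.clusters)
        for fold in res.folds:
            assert any(fold == c for c in part.clusters)

    def test_single_class_training_fold_named(self, small_cohort):
        # relabel so one protein carries every pathogenic variant
        target = small_cohort.variants[0].protein_id
        variants = [
            TruncatingVariant(v.protein_id, v.k, v.vtype,
                              "pathogenic" if v.protein_id == target else "neutral")
            for v in small_cohort.variants
        ]
        with pytest.raises(ValueError, match=r"fold \d+"):
            crossvalidate(small_cohort.proteins, variants,
                          FeatureSchema.final46(), k=3, seed=0,
                          hyperparams=Hyperparams(n_trees=2))


class TestReduceFeatures:
    def test_ledger_and_fold_invariance(self, cv_setup):
        cohort, hp = cv_setup
        schema = FeatureSchema.candidate66()
        result = reduce_features(cohort.proteins, cohort.variants,
                                 candidate_schema=schema, seed=0,
                                 hyperparams=hp, n_clusters=3)
        assert [g for g, _ in result.ledger] == list(schema.groups)
        assert len(result.ledger) == len(schema.groups)
        for group, mcc in result.ledger:
            assert -1.0 <= mcc <= 1.0
        assert set(result.final_schema.groups) == (
            set(schema.groups) - set(result.discarded)
        )
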