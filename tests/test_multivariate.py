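"""PERMANOVA, dispersion, and LDA against closed forms and external oracles."""

import numpy as np
import pytest
from scipy import stats

from aacsia import (FeatureMatrix, dispersion_homogeneity,
                    fingerprint_classify, lda_classify, lda_fit,
                    loocv_accuracy, pairwise_permanova, permanova)
from aacsia.exceptions import (DegenerateDataError, DomainError,
                               InsufficientDataError, SchemaError)


def fm(values, labels, names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(labels):
        values = values.T
    names = names or [f"f{i}" for i in range(values.shape[1])]
    return FeatureMatrix([f"s{i}" for i in range(len(labels))], names,
                         values, list(labels))


class TestPermanova:
    def test_univariate_equals_anova_f(self):
        res = permanova(fm([[0.0], [1.0], [10.0], [11.0]], "AABB"),
                        with_dispersion=False)
        assert res.pseudo_f == pytest.approx(200.0, abs=1e-8)
        assert res.exhaustive and res.n_perm == 6

    def test_univariate_equals_anova_f_random(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            sizes = rng.integers(3, 7, size=3)
            vals = rng.normal(size=sizes.sum())
            labels = np.repeat(list("abc"), sizes)
            f_classic = stats.f_oneway(*(vals[labels == g] for g in "abc")).statistic
            res = permanova(fm(vals[:, None], labels), n_perm=99, seed=1,
                            with_dispersion=False, method="sampled")
            assert res.pseudo_f == pytest.approx(f_classic, abs=1e-8)

    def test_exhaustive_mirror_partition(self):
        """Coincident pairs (0,0)x2 vs (10,10)x2: of the 6 equal-size
        assignments only the observed partition and its mirror attain
        the maximal F, so p = 2/6."""
        res = permanova(fm([[0, 0], [0, 0], [10, 10], [10, 10]], "AABB"),
                        with_dispersion=False)
        assert res.p == pytest.approx(1 / 3)

    def test_exhaustive_vs_sampled_agreement(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 2))
        x[4:] += 1.5
        features = fm(x, "AAAABBBB")
        exact = permanova(features, with_dispersion=False, method="exhaustive")
        sampled = permanova(features, n_perm=9999, seed=3,
                            with_dispersion=False, method="sampled")
        se = np.sqrt(exact.p * (1 - exact.p) / 9999)
        assert abs(sampled.p - exact.p) <= 3 * se + 1e-4

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(12, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        labels = "AAAABBBBCCCC"
        f1 = permanova(fm(x, labels), n_perm=99, seed=0,
                       with_dispersion=False, method="sampled").pseudo_f
        f2 = permanova(fm(x @ rot.T, labels), n_perm=99, seed=0,
                       with_dispersion=False, method="sampled").pseudo_f
        assert f1 == pytest.approx(f2, abs=1e-8)

    def test_matches_skbio(self):
        """Cross-check pseudo-F and sampled p against scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(23)
        x = rng.normal(size=(18, 4))
        x[9:] += 1.0
        labels = ["A"] * 9 + ["B"] * 9
        dm = skbio_stats.DistanceMatrix(
            np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)),
            [f"s{i}" for i in range(18)])
        ref = skbio_stats.permanova(dm, grouping=labels, permutations=999)
        res = permanova(fm(x, labels), n_perm=999, seed=0,
                        with_dispersion=False, method="sampled")
        assert res.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-8)
        se = np.sqrt(ref["p-value"] * (1 - ref["p-value"]) / 999)
        assert abs(res.p - ref["p-value"]) <= 4 * se + 0.01

    def test_degenerate_identical_points(self):
        with pytest.raises(DegenerateDataError):
            permanova(fm(np.zeros((6, 2)), "AAABBB"), with_dispersion=False)

    def test_null_calibration_smoke(self):
        """Under a single-cluster null the test is roughly calibrated
        (full 1000-replicate calibration lives in the acceptance suite)."""
        rng = np.random.default_rng(30)
        rejections = 0
        for i in range(100):
            x = rng.normal(size=(15, 2))
            res = permanova(fm(x, "AAAAABBBBBCCCCC"), n_perm=199,
                            seed=int(rng.integers(2**31)),
                            with_dispersion=False, method="sampled")
            rejections += res.p <= 0.05
        assert rejections <= 15


class TestDispersion:
    def test_translated_copies_not_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        features = fm(np.vstack([a, a + 5.0]), ["A"] * 20 + ["B"] * 20)
        assert dispersion_homogeneity(features, 999, seed=2) > 0.05

    def test_scaled_group_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3)) * 10
        features = fm(np.vstack([a, b]), ["A"] * 20 + ["B"] * 20)
        assert dispersion_homogeneity(features, 999, seed=2) < 0.05

    def test_single_point_group_degenerate(self):
        with pytest.raises((DegenerateDataError, InsufficientDataError)):
            dispersion_homogeneity(fm([[0.0], [1.0], [2.0]], "AAB"), 99, 0)


class TestPairwise:
    def _three_clusters(self, rng, sep=8.0):
        x = np.vstack([rng.normal(0, 1, (8, 2)),
                       rng.normal([sep, 0], 1, (8, 2)),
                       rng.normal([0, sep], 1, (8, 2))])
        return fm(x, ["A"] * 8 + ["B"] * 8 + ["C"] * 8)

    def test_all_pairs_significant_when_separated(self):
        contrasts = pairwise_permanova(
            self._three_clusters(np.random.default_rng(6)),
            n_perm=999, seed=0)
        assert len(contrasts) == 3
        assert all(c.p_adj < 0.05 for c in contrasts)
        assert all(c.p_adj >= c.p_raw - 1e-12 for c in contrasts)

    def test_coincident_pair_only_distant_contrasts_significant(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(10, 2))
        b = rng.normal(size=(10, 2))          # same distribution as A
        c = rng.normal([50, 50], 1, (10, 2))  # far away
        features = fm(np.vstack([a, b, c]), ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        contrasts = {tuple(x.pair): x.p_adj
                     for x in pairwise_permanova(features, 999, seed=1)}
        assert contrasts[("A", "C")] < 0.05
        assert contrasts[("B", "C")] < 0.05
        assert contrasts[("A", "B")] > 0.05

    def test_two_groups_rejected(self):
        with pytest.raises(DomainError, match="permanova"):
            pairwise_permanova(fm([[0.0], [1.0], [5.0], [6.0]], "AABB"), 99, 0)


class TestLdaFit:
    def test_fisher_direction_two_classes(self):
        rng = np.random.default_rng(14)
        a = rng.normal([0, 0], [1.0, 2.0], (30, 2))
        b = rng.normal([4, 1], [1.0, 2.0], (30, 2))
        model = lda_fit(fm(np.vstack([a, b]), ["A"] * 30 + ["B"] * 30))
        x = np.vstack([a, b])
        ma, mb = a.mean(0), b.mean(0)
        pooled = (np.cov(a.T, ddof=1) * 29 + np.cov(b.T, ddof=1) * 29) / 58
        fisher = np.linalg.solve(pooled, mb - ma)
        axis = model.axes[:, 0]
        cos = abs(fisher @ axis) / (np.linalg.norm(fisher) * np.linalg.norm(axis))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_collinear_class_means_rank_one(self):
        rng = np.random.default_rng(15)
        x = np.vstack([rng.normal([m, m], 0.3, (6, 2)) for m in (0, 5, 10)])
        # project noise so the class means are exactly collinear: use means
        # on a line with symmetric noise; proportions concentrate on LD1
        model = lda_fit(fm(x, ["A"] * 6 + ["B"] * 6 + ["C"] * 6))
        assert model.variance_proportions[0] > 0.99
        assert model.variance_proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(16)
        x = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(2, 1, (10, 3)),
                       rng.normal([0, 4, 0], 1, (10, 3))])
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        base = lda_fit(fm(x, labels))
        shifted = lda_fit(fm(x + 100.0, labels))
        assert np.allclose(np.abs(base.axes), np.abs(shifted.axes), atol=1e-6)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = lda_fit(fm(x @ q, labels))
        assert np.allclose(base.variance_proportions,
                           rotated.variance_proportions, atol=1e-8)

    def test_matches_sklearn_proportions(self):
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(19)
        x = np.vstack([rng.normal(0, 1, (12, 4)), rng.normal(1.5, 1, (12, 4)),
                       rng.normal([0, 3, 0, 0], 1, (12, 4))])
        labels = ["A"] * 12 + ["B"] * 12 + ["C"] * 12
        model = lda_fit(fm(x, labels))
        ref = sklearn_da.LinearDiscriminantAnalysis(solver="eigen").fit(x, labels)
        assert np.allclose(model.variance_proportions,
                           ref.explained_variance_ratio_[:2], atol=1e-6)

    def test_sign_convention(self):
        rng = np.random.default_rng(20)
        x = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(3, 1, (10, 3))])
        model = lda_fit(fm(x, ["A"] * 10 + ["B"] * 10))
        for j in range(model.axes.shape[1]):
            lead = np.argmax(np.abs(model.axes[:, j]))
            assert model.axes[lead, j] > 0


class TestClassify:
    def _model(self, rng=None):
        rng = rng or np.random.default_rng(22)
        a = rng.normal([0, 0], 1, (20, 2))
        b = rng.normal([10, 0], 1, (20, 2))
        features = fm(np.vstack([a, b]), ["A"] * 20 + ["B"] * 20)
        return lda_fit(features), features

    def test_sample_at_class_mean(self):
        model, _ = self._model()
        labels, post = lda_classify(model, model.class_means[0:1])
        assert labels == ["A"]
        assert post[0, 0] > 0.99

    def test_equidistant_sample_splits_posterior(self):
        model, _ = self._model()
        model.priors = np.array([0.5, 0.5])
        mid = model.class_means.mean(axis=0, keepdims=True)
        _, post = lda_classify(model, mid)
        assert np.allclose(post, [[0.5, 0.5]], atol=1e-9)

    def test_posteriors_sum_to_one(self):
        model, _ = self._model()
        rng = np.random.default_rng(1)
        _, post = lda_classify(model, rng.normal(0, 20, (50, 2)))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_gaussian_bayes_oracle(self):
        """Posteriors equal an independent Bayes computation from
        multivariate-normal densities with the same means, pooled
        covariance, and priors."""
        mvn = pytest.importorskip("scipy.stats").multivariate_normal
        rng = np.random.default_rng(27)
        x = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(2, 1, (15, 3))])
        labels = ["A"] * 15 + ["B"] * 15
        model = lda_fit(fm(x, labels))
        query = rng.normal(1, 2, (10, 3))
        _, post = lda_classify(model, query)
        dens = np.column_stack([
            model.priors[k] * mvn.pdf(query, mean=model.class_means[k],
                                      cov=model.pooled_cov)
            for k in range(2)])
        oracle = dens / dens.sum(axis=1, keepdims=True)
        assert np.allclose(post, oracle, atol=1e-9)

    def test_feature_mismatch(self):
        model, _ = self._model()
        other = fm(np.zeros((2, 2)), "AB", names=["x", "y"])
        with pytest.raises(SchemaError, match="feature mismatch"):
            lda_classify(model, other)


class TestLoocv:
    def _clusters(self, rng, sep=10.0, n=8):
        x = np.vstack([rng.normal(0, 1, (n, 2)),
                       rng.normal([sep, 0], 1, (n, 2)),
                       rng.normal([0, sep], 1, (n, 2))])
        return x, ["A"] * n + ["B"] * n + ["C"] * n

    def test_perfect_separation(self):
        x, labels = self._clusters(np.random.default_rng(31))
        assert loocv_accuracy(fm(x, labels)) == 1.0

    def test_shuffled_labels_near_chance(self):
        x, labels = self._clusters(np.random.default_rng(32))
        rng = np.random.default_rng(33)
        accs = []
        for _ in range(20):
            shuffled = list(labels)
            rng.shuffle(shuffled)
            accs.append(loocv_accuracy(fm(x, shuffled)))
        assert abs(np.mean(accs) - 1 / 3) < 0.12

    def test_feature_order_invariance(self):
        x, labels = self._clusters(np.random.default_rng(34))
        acc1 = loocv_accuracy(fm(x, labels, names=["a", "b"]))
        acc2 = loocv_accuracy(fm(x[:, ::-1], labels, names=["b", "a"]))
        assert acc1 == acc2

    def test_no_leakage_of_held_out_sample(self):
        """A wildly displaced duplicate of a training point must be
        classified from the refit model, not memorized: it lands with
        the class whose mean is nearest under the fold's model, which
        here is decided by geometry, not by its own label."""
        rng = np.random.default_rng(35)
        x, labels = self._clusters(rng)
        outlier = np.array([[500.0, 500.0]])
        features = fm(np.vstack([x, outlier]), labels + ["A"])
        acc_with = loocv_accuracy(features)
        # the outlier is misclassified (far from every class mean but
        # closest to the direction of C at (0, sep)); if it were
        # memorized, accuracy would be (n_correct+1)/(n+1)
        base = loocv_accuracy(fm(x, labels))
        assert acc_with < (base * len(labels) + 1) / (len(labels) + 1)

    def test_too_small_group(self):
        with pytest.raises(InsufficientDataError):
            loocv_accuracy(fm([[0.0], [1.0], [5.0], [6.0], [7.0]], "AABBB"))


class TestFingerprint:
    def test_consumer_at_training_mean(self):
        rng = np.random.default_rng(36)
        means = {"diatom": [3.0, -3.0], "prasinophyte": [-3.0, 3.0]}
        rows, labels = [], []
        for name, m in means.items():
            rows.append(rng.normal(m, 0.3, (10, 2)))
            labels += [name] * 10
        training = fm(np.vstack(rows), labels, names=["Leu", "Thr"])
        consumers = fm(np.array([means["diatom"]]), ["?"], names=["Leu", "Thr"])
        result = fingerprint_classify(training, consumers)
        assert result.labels == ["diatom"]
        assert result.posteriors[0, result.model.classes.index("diatom")] > 0.99

    def test_mixture_splits_posterior_across_parents(self):
        rng = np.random.default_rng(37)
        means = {"a": [8.0, 0.0], "b": [-8.0, 0.0], "c": [0.0, 20.0]}
        rows, labels = [], []
        for name, m in means.items():
            rows.append(rng.normal(m, 1.0, (12, 2)))
            labels += [name] * 12
        training = fm(np.vstack(rows), labels, names=["x", "y"])
        mix = 0.5 * np.array(means["a"]) + 0.5 * np.array(means["b"])
        result = fingerprint_classify(training, fm([mix], ["?"], names=["x", "y"]))
        post = dict(zip(result.model.classes, result.posteriors[0]))
        assert post["a"] > post["c"] and post["b"] > post["c"]

    def test_eaa_set_mismatch(self):
        t = fm(np.zeros((4, 2)) + [[0, 1], [0, 1], [1, 0], [1, 0]],
               "AABB", names=["Leu", "Thr"])
        c = fm(np.zeros((1, 2)), "?", names=["Leu", "Val"])
        with pytest.raises(SchemaError, match="mismatch"):
            fingerprint_classify(t, c)
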