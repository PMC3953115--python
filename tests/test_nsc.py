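"""Nearest-shrunken-centroid classifier: formula oracles, shrinkage limits,
monotonicity, cross-validation behaviour."""

import numpy as np
import pytest

from nsclcmir.cohort import CohortDesign, default_truth, generate_mrna_arrays
from nsclcmir.errors import ConfigurationError
from nsclcmir.nsc import (cv_select_delta, fit_nsc, predict_nsc,
                          signature_genes)


def random_instance(rng, n_genes=10, n_per_class=(5, 6)):
    labels = np.array(["A"] * n_per_class[0] + ["B"] * n_per_class[1])
    values = rng.normal(0, 1, size=(n_genes, labels.size))
    values[:3, labels == "B"] += rng.normal(1, 0.5)
    return values, labels


def brute_force_dik(values, labels):
    """Straight re-computation of the standardized centroid differences."""
    classes = sorted(set(labels))
    n = values.shape[1]
    overall = values.mean(axis=1)
    s2 = np.zeros(values.shape[0])
    cents = {}
    for c in classes:
        xc = values[:, labels == c]
        cents[c] = xc.mean(axis=1)
        s2 += ((xc - cents[c][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(s2 / (n - len(classes)))
    s0 = np.median(s)
    out = {}
    for c in classes:
        nk = (labels == c).sum()
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        out[c] = (cents[c] - overall) / (mk * (s + s0))
    return out


class TestFit:
    def test_delta_zero_keeps_raw_centroids(self):
        rng = np.random.default_rng(0)
        values, labels = random_instance(rng)
        model = fit_nsc(values, labels, delta=0.0)
        np.testing.assert_allclose(model.shrunken_centroids,
                                   model.class_centroids, atol=1e-12)

    def test_huge_delta_collapses_to_overall_centroid(self):
        rng = np.random.default_rng(1)
        values, labels = random_instance(rng)
        model = fit_nsc(values, labels, delta=1e6)
        for j in range(len(model.classes)):
            np.testing.assert_allclose(model.shrunken_centroids[:, j],
                                       model.overall_centroid, atol=1e-12)
        assert model.survivors().sum() == 0
        assert signature_genes(model) == []

    def test_dik_matches_brute_force(self):
        rng = np.random.default_rng(2)
        values, labels = random_instance(rng)
        model = fit_nsc(values, labels, delta=0.7)
        ref = brute_force_dik(values, labels)
        for j, c in enumerate(model.classes):
            np.testing.assert_allclose(model.dik[:, j], ref[c], atol=1e-12)

    def test_class_with_one_sample_rejected(self):
        values = np.zeros((3, 3))
        with pytest.raises(ConfigurationError, match="< 2 samples"):
            fit_nsc(values, np.array(["A", "A", "B"]))

    def test_survivors_shrink_monotonically(self):
        rng = np.random.default_rng(3)
        values, labels = random_instance(rng, n_genes=40)
        prev = None
        for delta in [0.0, 0.2, 0.5, 1.0, 2.0, 4.0]:
            surv = set(np.flatnonzero(fit_nsc(values, labels, delta=delta)
                                      .survivors()))
            if prev is not None:
                assert surv <= prev
            prev = surv


class TestPredict:
    def brute_scores(self, model, x):
        out = {}
        for j, c in enumerate(model.classes):
            out[c] = float(np.sum((x - model.shrunken_centroids[:, j]) ** 2
                                  / (model.s + model.s0) ** 2)
                           - 2 * np.log(model.priors[j]))
        return out

    def test_centroid_sample_classified_to_its_class(self):
        rng = np.random.default_rng(4)
        values, labels = random_instance(rng)
        model = fit_nsc(values, labels, delta=0.0,
                        priors=[0.5, 0.5])
        for j, c in enumerate(model.classes):
            pred, _ = predict_nsc(model, model.shrunken_centroids[:, j])
            assert pred == c

    def test_scores_match_brute_force(self):
        rng = np.random.default_rng(5)
        values, labels = random_instance(rng)
        model = fit_nsc(values, labels, delta=0.4)
        for _ in range(10):
            x = rng.normal(0, 1, size=values.shape[0])
            pred, scores = predict_nsc(model, x)
            ref = self.brute_scores(model, x)
            for c in model.classes:
                assert scores[c] == pytest.approx(ref[c], abs=1e-12)
            assert pred == min(model.classes, key=lambda c: (ref[c], c))

    def test_prior_only_limit_predicts_majority(self):
        rng = np.random.default_rng(6)
        values, labels = random_instance(rng, n_per_class=(4, 8))
        model = fit_nsc(values, labels, delta=1e6)  # no surviving genes
        for _ in range(5):
            x = rng.normal(0, 1, size=values.shape[0])
            assert predict_nsc(model, x)[0] == "B"

    def test_equivalent_to_diagonal_nearest_centroid_at_delta_zero(self):
        # with delta=0 and equal priors the discriminant reduces to the
        # (s_i+s0)-standardised euclidean distance to the raw centroid
        rng = np.random.default_rng(7)
        for _ in range(50):
            values, labels = random_instance(
                rng, n_genes=int(rng.integers(4, 12)))
            model = fit_nsc(values, labels, delta=0.0, priors=[0.5, 0.5])
            x = rng.normal(0, 1, size=values.shape[0])
            pred, _ = predict_nsc(model, x)
            w = 1.0 / (model.s + model.s0) ** 2
            dists = {c: np.sum(w * (x - model.class_centroids[:, j]) ** 2)
                     for j, c in enumerate(model.classes)}
            assert pred == min(model.classes, key=lambda c: (dists[c], c))

    def test_prediction_invariant_under_gene_reordering(self):
        rng = np.random.default_rng(8)
        values, labels = random_instance(rng)
        perm = rng.permutation(values.shape[0])
        model = fit_nsc(values, labels, delta=0.3)
        model_p = fit_nsc(values[perm], labels, delta=0.3)
        for _ in range(5):
            x = rng.normal(0, 1, size=values.shape[0])
            assert predict_nsc(model, x)[0] == predict_nsc(model_p, x[perm])[0]

    def test_missing_profile_value_names_gene(self):
        rng = np.random.default_rng(9)
        values, labels = random_instance(rng, n_genes=4)
        model = fit_nsc(values, labels)
        with pytest.raises(ConfigurationError, match="g2"):
            predict_nsc(model, {"g0": 0.0, "g1": 0.0, "g3": 0.0})

    def test_mk_variant_changes_scale_not_direction(self):
        rng = np.random.default_rng(10)
        values, labels = random_instance(rng)
        a = fit_nsc(values, labels, mk="minus")
        b = fit_nsc(values, labels, mk="plus")
        assert np.all(np.sign(a.dik) == np.sign(b.dik))
        assert np.all(np.abs(a.dik) >= np.abs(b.dik))  # minus normaliser smaller


class TestCrossValidation:
    def test_separated_data_has_zero_cv_error_at_delta_zero(self):
        rng = np.random.default_rng(11)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        values = rng.normal(0, 0.1, size=(5, 20))
        values[:, labels == "B"] += 5.0
        delta_star, curve = cv_select_delta(values, labels, folds=5, seed=1)
        assert curve.loc[curve["delta"] == 0.0, "cv_error"].iloc[0] == 0.0

    def test_parsimony_picks_largest_delta_at_min_error(self):
        rng = np.random.default_rng(12)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        values = rng.normal(0, 0.1, size=(5, 20))
        values[:, labels == "B"] += 5.0
        delta_star, curve = cv_select_delta(values, labels, folds=5, seed=1)
        best = curve["cv_error"].min()
        assert delta_star == curve.loc[curve["cv_error"] == best, "delta"].max()

    def test_label_permutation_gives_chance_error(self):
        rng = np.random.default_rng(13)
        labels = np.array(["A"] * 12 + ["B"] * 12)
        values = rng.normal(0, 1, size=(30, 24))  # pure noise
        _, curve = cv_select_delta(values, labels, folds=4, seed=2)
        # error should hover near the 50% majority-class rate, never near 0
        assert curve["cv_error"].min() > 0.2

    def test_seeded_fold_assignment_reproducible(self):
        rng = np.random.default_rng(14)
        values, labels = random_instance(rng, n_genes=15)
        a = cv_select_delta(values, labels, folds=3, seed=5)
        b = cv_select_delta(values, labels, folds=3, seed=5)
        assert a[0] == b[0]
        assert a[1].equals(b[1])

    def test_fold_lacking_class_rejected(self):
        values = np.zeros((3, 6))
        labels = np.array(["A", "A", "B", "B", "B", "B"])
        with pytest.raises(ConfigurationError, match="folds"):
            cv_select_delta(values, labels, folds=3)


class TestSignature:
    def test_planted_genes_outrank_null_genes(self):
        design = CohortDesign(seed=1, n_genes=300)
        truth = default_truth(design, n_de_genes=20, n_decoy_pairs=0)
        x = generate_mrna_arrays(design, truth)
        model = fit_nsc(x, delta=2.0)
        sig = signature_genes(model)
        planted = {g for g, _, _ in truth.de_genes}
        assert planted <= set(sig[:len(planted) + 5])

    def test_delta_zero_signature_is_every_gene(self):
        rng = np.random.default_rng(15)
        values, labels = random_instance(rng)
        model = fit_nsc(values, labels, delta=0.0)
        assert len(signature_genes(model)) == values.shape[0]
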