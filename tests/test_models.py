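"""Training-set assembly, random-forest training, cross validation, bundles."""

from collections import Counter

import numpy as np
import pytest

from presyncodon.corpus import CodingSequence
from presyncodon.csi import build_csi, extract_fragments
from presyncodon.genetics import STANDARD_CODE, translate
from presyncodon.matching import MatchConfig
from presyncodon.models import (
    BundleFormatError,
    ClassifierSpec,
    TrainingSet,
    assemble_training_data,
    cross_validate,
    load_bundle,
    save_bundle,
    train_classifier,
    train_grid,
)


def _planted_training_set(strength, n, seed, window=5):
    """Known-Bayes-rate simulation for a two-codon amino acid.

    Each sample's first two features are the context-conditional codon
    distribution ((strength, 1-strength) or its mirror); the label is drawn
    from that same distribution, so the Bayes accuracy equals ``strength``.
    """
    rng = np.random.default_rng(seed)
    context = rng.random(n) < 0.5
    p_aag = np.where(context, strength, 1.0 - strength)
    features = np.column_stack(
        [1.0 - p_aag, p_aag, rng.random((n, window))]
    )
    labels = np.where(rng.random(n) < p_aag, "AAG", "AAA").astype(object)
    return TrainingSet("K", window, 1.0, features, labels, ("g",) * n)


class TestAssembleTrainingData:
    def test_cutoff_one_labels_are_the_genes_own_codons(self):
        codons = ("ATG", "AAA", "AAG", "AAA", "GGA", "AAA", "TGG")
        gene = CodingSequence("g", codons, translate(codons))
        index = build_csi([gene], 5)
        ts = assemble_training_data([gene], index, MatchConfig(cutoff=1.0), "K")
        # eligible K positions: indices 2 and 3 (window must fit)
        assert sorted(ts.labels) == ["AAA", "AAG"]
        assert ts.n_skipped == 0

    def test_nondegenerate_amino_acid_rejected(self, small_records):
        index = build_csi(small_records[:2], 5)
        with pytest.raises(ValueError, match="degenerate"):
            assemble_training_data(small_records[:2], index, MatchConfig(cutoff=1.0), "M")

    def test_label_marginal_matches_interior_codon_counts(self, small_records):
        # at c=1 every position matches itself, so labels must reproduce the
        # exact multiset of interior codons per amino acid (counting oracle)
        window = 5
        corpus = small_records[:8]
        index = build_csi(corpus, window)
        for aa in ("K", "L", "S"):
            ts = assemble_training_data(corpus, index, MatchConfig(cutoff=1.0), aa)
            oracle = Counter(
                mid
                for gene in corpus
                for frag, mid, _ in extract_fragments(gene, window)
                if frag[window // 2] == aa
            )
            assert Counter(ts.labels) == oracle

    def test_feature_rows_align_with_labels(self, small_records):
        index = build_csi(small_records[:4], 5)
        ts = assemble_training_data(small_records[:4], index, MatchConfig(cutoff=1.0), "K")
        assert ts.features.shape == (len(ts.labels), 2 + 5)
        assert len(ts.gene_ids) == len(ts.labels)


class TestTrainClassifier:
    def test_separable_toy_problem(self):
        ts = _planted_training_set(1.0, 400, seed=1)
        model = train_classifier(ts, ClassifierSpec("K", 5, 1.0, n_trees=50, seed=2))
        pred = model.predict(ts.features)
        assert np.mean(pred == ts.labels) == 1.0

    def test_single_label_gives_flagged_constant_predictor(self):
        features = np.random.default_rng(0).random((10, 7))
        ts = TrainingSet("K", 5, 1.0, features, np.array(["AAA"] * 10, object), ("g",) * 10)
        model = train_classifier(ts, ClassifierSpec("K", 5, 1.0, n_trees=10))
        assert model.degenerate
        assert set(model.predict(features)) == {"AAA"}

    def test_wrong_feature_dimension_rejected(self):
        ts = _planted_training_set(1.0, 50, seed=1)
        with pytest.raises(ValueError, match="dimension"):
            train_classifier(ts, ClassifierSpec("L", 5, 1.0, n_trees=10))  # L needs k=6

    def test_predictions_always_synonymous(self, small_records):
        index = build_csi(small_records[:6], 5)
        ts = assemble_training_data(small_records[:6], index, MatchConfig(cutoff=0.8), "L")
        model = train_classifier(ts, ClassifierSpec("L", 5, 0.8, n_trees=30, seed=5))
        rng = np.random.default_rng(11)
        pred = model.predict(rng.random((50, 6 + 5)))
        assert set(pred) <= set(STANDARD_CODE.codons_for("L"))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ClassifierSpec("M", 5, 1.0)
        with pytest.raises(ValueError):
            ClassifierSpec("K", 5, 0.0)


class TestCrossValidate:
    def test_constant_labels_give_perfect_accuracy(self):
        features = np.random.default_rng(3).random((40, 7))
        ts = TrainingSet("K", 5, 1.0, features, np.array(["AAA"] * 40, object), ("g",) * 40)
        cv = cross_validate(ts, ClassifierSpec("K", 5, 1.0, n_trees=10, seed=1))
        assert cv.accuracy == 1.0

    def test_null_features_give_chance_accuracy(self):
        # labels independent of features, two equiprobable codons
        rng = np.random.default_rng(8)
        features = rng.random((2000, 7))
        labels = np.where(rng.random(2000) < 0.5, "AAA", "AAG").astype(object)
        ts = TrainingSet("K", 5, 1.0, features, labels, ("g",) * 2000)
        cv = cross_validate(ts, ClassifierSpec("K", 5, 1.0, n_trees=50, seed=4))
        assert cv.accuracy == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("strength", [0.8, 1.0])
    def test_planted_rule_recovers_bayes_accuracy(self, strength):
        ts = _planted_training_set(strength, 2000, seed=9)
        cv = cross_validate(ts, ClassifierSpec("K", 5, 1.0, n_trees=50, seed=6))
        assert cv.accuracy == pytest.approx(strength, abs=0.05)

    def test_too_few_samples_rejected(self):
        ts = _planted_training_set(1.0, 5, seed=1)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(ts, ClassifierSpec("K", 5, 1.0, n_trees=10), folds=10)

    def test_reproducible_from_seed(self):
        ts = _planted_training_set(0.8, 300, seed=2)
        spec = ClassifierSpec("K", 5, 1.0, n_trees=30, seed=7)
        assert cross_validate(ts, spec) == cross_validate(ts, spec)


@pytest.fixture(scope="module")
def bundle(small_corpus):
    return train_grid(
        small_corpus, windows=(5,), cutoffs=(0.8, 1.0), n_trees=20, seed=3,
        host_name="synthetic-host",
    )


class TestTrainGrid:
    def test_grid_cardinality(self, bundle):
        assert bundle.n_slots == 18 * 1 * 2
        assert len(bundle.models) + len(bundle.skipped) == bundle.n_slots

    def test_models_keyed_by_cell(self, bundle):
        for (aa, window, cutoff), model in bundle.models.items():
            assert model.spec.amino_acid == aa
            assert model.spec.window == window
            assert model.spec.cutoff == cutoff

    def test_round_trip_preserves_predictions(self, bundle, tmp_path):
        save_bundle(bundle, tmp_path / "bundle")
        back = load_bundle(tmp_path / "bundle")
        assert set(back.models) == set(bundle.models)
        rng = np.random.default_rng(19)
        for key in sorted(bundle.models)[:6]:
            k = STANDARD_CODE.degeneracy(key[0])
            X = rng.random((100, k + 5))
            assert np.array_equal(bundle.models[key].predict(X), back.models[key].predict(X))
        assert back.background.counts == bundle.background.counts

    def test_empty_bundle_refuses_to_save(self, bundle, tmp_path):
        import copy

        empty = copy.copy(bundle)
        empty.models = {}
        with pytest.raises(ValueError, match="refus"):
            save_bundle(empty, tmp_path / "empty")

    def test_version_mismatch_rejected(self, bundle, tmp_path):
        import json

        save_bundle(bundle, tmp_path / "bundle")
        manifest = json.loads((tmp_path / "bundle" / "manifest.json").read_text())
        manifest["version"] = 99
        (tmp_path / "bundle" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(BundleFormatError, match="version"):
            load_bundle(tmp_path / "bundle")
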