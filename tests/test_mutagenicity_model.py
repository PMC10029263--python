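import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutarules import mutagenicity_model as mm
from mutarules.chem_io import LabeledDataset, POSITIVE
from mutarules.synthetic_fixtures import FixtureSpec, generate


@pytest.fixture(scope="module")
def separable_dataset():
    """Noiseless fixture: label == alert presence, learnable from bits."""
    dataset, _ = generate(FixtureSpec(n_molecules=100, label_noise=0.0, seed=5))
    return dataset


class TestFeaturize:
    @pytest.mark.parametrize("kind, length", [("maccs", 166), ("rdk", 2048), ("ecfp", 1024)])
    def test_lengths(self, kind, length):
        vec = mm.featurize("c1ccccc1O", kind)
        assert vec.shape == (length,)
        assert set(np.unique(vec)) <= {0, 1}

    def test_deterministic(self):
        a = mm.featurize("CC(=O)Nc1ccc(O)cc1", "ecfp")
        b = mm.featurize("CC(=O)Nc1ccc(O)cc1", "ecfp")
        assert np.array_equal(a, b)

    def test_benzene_differs_from_cyclohexane(self):
        assert not np.array_equal(
            mm.featurize("c1ccccc1", "ecfp"), mm.featurize("C1CCCCC1", "ecfp")
        )

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            mm.featurize("CCO", "daylight")


class TestMetrics:
    @given(
        tp=st.integers(0, 500),
        fp=st.integers(0, 500),
        tn=st.integers(0, 500),
        fn=st.integers(0, 500),
    )
    @settings(deadline=None, max_examples=80)
    def test_confusion_identities(self, tp, fp, tn, fn):
        m = mm.metrics_from_confusion(tp, fp, tn, fn)
        if tp + fn:
            assert m.se == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m.sp == pytest.approx(tn / (tn + fp))
        if tp + fp + tn + fn:
            assert m.acc == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            assert 0.0 <= m.acc <= 1.0
        if 2 * tp + fp + fn:
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_external_validation_confusion(self):
        # 290 of 376 positives and 211 of 239 negatives correct
        m = mm.metrics_from_confusion(tp=290, fp=28, tn=211, fn=86)
        assert round(m.se, 3) == 0.771
        assert round(m.sp, 3) == 0.883
        assert round(m.acc, 3) == 0.815


class TestTrainBase:
    def test_separable_rf_perfect(self, separable_dataset):
        spec = mm.BaseClassifierSpec("rf", "ecfp")
        mm.train_base(separable_dataset, spec, folds=5, seed=3)
        accs = [f["acc"] for f in spec.fold_metrics]
        assert np.mean(accs) == pytest.approx(1.0)
        assert spec.cv_auc == pytest.approx(1.0)

    def test_fold_count(self, separable_dataset):
        spec = mm.BaseClassifierSpec("gb", "maccs", grid={"n_estimators": [50]})
        mm.train_base(separable_dataset, spec, folds=5, seed=3)
        assert len(spec.fold_metrics) == 5

    def test_single_class_raises(self, separable_dataset):
        pos_only = LabeledDataset(
            tuple(r for r in separable_dataset if r.label == POSITIVE)
        )
        with pytest.raises(ValueError):
            mm.train_base(pos_only, mm.BaseClassifierSpec("rf", "ecfp"), seed=0)

    def test_shuffled_labels_chance_auc(self, separable_dataset):
        rng = np.random.default_rng(17)
        labels = [r.label for r in separable_dataset]
        shuffled = list(rng.permutation(labels))
        from mutarules.chem_io import MoleculeRecord

        ds = LabeledDataset(
            tuple(
                MoleculeRecord(r.record_id, r.smiles, lab)
                for r, lab in zip(separable_dataset, shuffled)
            )
        )
        spec = mm.BaseClassifierSpec("rf", "ecfp", grid={"n_estimators": [100]})
        mm.train_base(ds, spec, folds=5, seed=17)
        assert 0.3 <= spec.cv_auc <= 0.7


@pytest.fixture(scope="module")
def stacked(separable_dataset):
    from mutarules.chem_io import split

    train, holdout = split(separable_dataset, 0.2, seed=9)
    specs = [
        mm.BaseClassifierSpec("rf", "ecfp", grid={"n_estimators": [100]}),
        mm.BaseClassifierSpec("gb", "maccs", grid={"n_estimators": [50]}),
    ]
    for s in specs:
        mm.train_base(train, s, folds=3, seed=9)
    model = mm.stack_consensus(train, specs, folds=3, seed=9)
    return model, specs, train, holdout


class TestStacking:
    def test_needs_two_bases(self, separable_dataset):
        spec = mm.BaseClassifierSpec("rf", "ecfp", grid={"n_estimators": [50]})
        with pytest.raises(ValueError):
            mm.stack_consensus(separable_dataset, [spec], folds=3, seed=0)

    def test_probabilities_in_unit_interval(self, stacked):
        model, _, _, holdout = stacked
        probs = model.predict_proba([r.smiles for r in holdout])
        assert np.all((probs >= 0) & (probs <= 1))

    def test_consensus_at_least_worst_base(self, stacked):
        model, specs, _, holdout = stacked
        consensus = mm.evaluate(model, holdout)
        base_aucs = []
        for spec in specs:
            X, y = mm.dataset_arrays(holdout, spec.fingerprint)
            probs = spec.estimator.predict_proba(X)[:, 1]
            from sklearn.metrics import roc_auc_score

            base_aucs.append(roc_auc_score(y, probs))
        assert consensus.auc >= min(base_aucs) - 0.05
        assert consensus.auc <= 1.0

    def test_deterministic_refit(self, separable_dataset):
        def fit_once():
            specs = [
                mm.BaseClassifierSpec("rf", "ecfp", grid={"n_estimators": [50]}),
                mm.BaseClassifierSpec("gb", "maccs", grid={"n_estimators": [50]}),
            ]
            model = mm.stack_consensus(separable_dataset, specs, folds=3, seed=4)
            return model.meta.coef_.copy()

        assert np.array_equal(fit_once(), fit_once())

    def test_save_load_roundtrip(self, stacked, tmp_path):
        model, _, _, holdout = stacked
        path = tmp_path / "model.bin"
        model.save(path)
        loaded = mm.ConsensusModel.load(path)
        smiles = [r.smiles for r in holdout]
        assert np.allclose(loaded.predict_proba(smiles), model.predict_proba(smiles))


class TestEvaluateMetrics:
    def test_perfect_and_constant_auc(self):
        from sklearn.metrics import roc_auc_score

        y = np.array([1, 1, 0, 0])
        assert roc_auc_score(y, [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert roc_auc_score(y, [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_evaluate_on_holdout(self, separable_dataset):
        from mutarules.chem_io import split

        train, holdout = split(separable_dataset, 0.2, seed=9)
        specs = [
            mm.BaseClassifierSpec("rf", "ecfp", grid={"n_estimators": [100]}),
            mm.BaseClassifierSpec("gb", "maccs", grid={"n_estimators": [50]}),
        ]
        for s in specs:
            mm.train_base(train, s, folds=3, seed=9)
        model = mm.stack_consensus(train, specs, folds=3, seed=9)
        m = mm.evaluate(model, holdout)
        assert m.tp + m.fp + m.tn + m.fn == len(holdout)
        assert m.auc is not None and 0.5 <= m.auc <= 1.0

    def test_single_class_auc_missing(self, separable_dataset):
        from mutarules.chem_io import split

        train, holdout = split(separable_dataset, 0.2, seed=9)
        specs = [
            mm.BaseClassifierSpec("rf", "ecfp", grid={"n_estimators": [50]}),
            mm.BaseClassifierSpec("gb", "maccs", grid={"n_estimators": [50]}),
        ]
        model = mm.stack_consensus(train, specs, folds=3, seed=9)
        pos_only = LabeledDataset(tuple(r for r in holdout if r.label == POSITIVE))
        m = mm.evaluate(model, pos_only)
        assert m.auc is None
        assert m.tn == 0 and m.fp == 0
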