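"""Endpoint classifier/regressor training, Youden threshold calibration and
the cross-endpoint predictivity matrix."""

import numpy as np
import pytest

from dilinet.data_model import EndpointDataset
from dilinet.endpoint_models import (
    SearchSpace,
    cross_predict_matrix,
    predict_endpoint,
    train_cmax_regressor,
    train_endpoint_classifier,
    youden_threshold,
)
from dilinet.featurization import FeatureBlock


def exhaustive_youden(probs, labels):
    """Oracle: scan every candidate cutoff directly."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(probs)
    cands = [0.0, 1.0] + ((uniq[:-1] + uniq[1:]) / 2).tolist()
    best_t, best_j = None, -np.inf
    for t in sorted(cands):
        calls = probs >= t
        sens = (calls & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~calls & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


class TestYouden:
    def test_separable_case(self):
        t = youden_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)
        # J at that threshold is 1 (perfect)
        _, j = exhaustive_youden([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert j == pytest.approx(1.0)

    def test_anti_ranked_warns(self):
        with pytest.warns(UserWarning, match="chance"):
            youden_threshold([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])

    def test_degenerate_equal_probs(self):
        with pytest.warns(UserWarning):
            assert youden_threshold([0.3, 0.3, 0.3], [0, 1, 1]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            youden_threshold([0.2, 0.8], [1, 1])

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            probs = rng.random(n).round(3)
            expected_t, expected_j = exhaustive_youden(probs, labels)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = youden_threshold(probs, labels)
            # same J; ties resolve to the smallest threshold in both
            assert got == pytest.approx(expected_t)


def _toy_dataset(n, seed, signal=True, numeric=False):
    """Dataset + features where the label is a function of one column."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, 10))
    names = [f"f{i}" for i in range(10)]
    if numeric:
        y = 3.0 * X[:, 0] - 1.0
    else:
        y = (X[:, 0] > 0.5).astype(int)
        if not signal:
            y = rng.permutation(y)
    from dilinet.chemprep import StandardizedCompound

    compounds = [
        StandardizedCompound(
            smiles_std="C", smiles_ph7="C", key14=f"KEY{i:011d}", label=float(yy)
        )
        for i, yy in enumerate(y)
    ]
    ds = EndpointDataset(
        "toy", compounds, kind="numeric" if numeric else "binary"
    )
    return ds, FeatureBlock("toy_features", X, names)


class TestClassifier:
    def test_separable_high_auc(self):
        ds, feats = _toy_dataset(150, 1)
        model = train_endpoint_classifier(ds, feats, SearchSpace.fast(), seed=0)
        from sklearn.model_selection import cross_val_score

        auc = cross_val_score(
            model.estimator, feats.matrix, ds.labels(), cv=5, scoring="roc_auc"
        ).mean()
        assert auc >= 0.95
        assert 0.0 <= model.threshold <= 1.0

    def test_null_labels_chance_auc(self):
        ds, feats = _toy_dataset(500, 2, signal=False)
        model = train_endpoint_classifier(ds, feats, SearchSpace.fast(), seed=0)
        from sklearn.model_selection import cross_val_score

        auc = cross_val_score(
            model.estimator, feats.matrix, ds.labels(), cv=5, scoring="roc_auc"
        ).mean()
        assert 0.4 <= auc <= 0.6

    def test_determinism(self):
        ds, feats = _toy_dataset(100, 3)
        a = train_endpoint_classifier(ds, feats, SearchSpace.fast(), seed=5)
        b = train_endpoint_classifier(ds, feats, SearchSpace.fast(), seed=5)
        pa, _ = predict_endpoint(a, feats)
        pb, _ = predict_endpoint(b, feats)
        assert np.array_equal(pa, pb)
        assert a.threshold == b.threshold
        assert a.training_digest == b.training_digest

    def test_tiny_class_errors(self):
        ds, feats = _toy_dataset(100, 4)
        for c in ds.compounds:
            c.label = 0.0
        ds.compounds[0].label = 1.0
        with pytest.raises(ValueError):
            train_endpoint_classifier(ds, feats, SearchSpace.fast(), seed=0)

    def test_probability_sanity_band(self):
        ds, feats = _toy_dataset(150, 6)
        model = train_endpoint_classifier(ds, feats, SearchSpace.fast(), seed=0)
        probs, _ = predict_endpoint(model, feats)
        rate = ds.labels().mean()
        assert rate - 0.25 <= probs.mean() <= rate + 0.25
        assert np.all((probs >= 0) & (probs <= 1))


class TestRegressor:
    def test_linear_target_high_r2(self):
        ds, feats = _toy_dataset(200, 7, numeric=True)
        model = train_cmax_regressor(ds, feats, SearchSpace.fast(), seed=0)
        # held-out check on fresh rows from the same generator
        ds2, feats2 = _toy_dataset(200, 99, numeric=True)
        from sklearn.metrics import r2_score

        r2 = r2_score(ds2.labels(), model.estimator.predict(feats2.matrix))
        assert r2 >= 0.8

    def test_permuted_labels_low_r2(self):
        rng = np.random.default_rng(8)
        ds, feats = _toy_dataset(200, 8, numeric=True)
        perm = rng.permutation(len(ds))
        for c, v in zip(ds.compounds, ds.labels()[perm]):
            c.label = float(v)
        model = train_cmax_regressor(ds, feats, SearchSpace.fast(), seed=0)
        ds2, feats2 = _toy_dataset(200, 100, numeric=True)
        from sklearn.metrics import r2_score

        assert r2_score(ds2.labels(), model.estimator.predict(feats2.matrix)) <= 0.1

    def test_constant_labels_warn(self):
        ds, feats = _toy_dataset(50, 9, numeric=True)
        for c in ds.compounds:
            c.label = 1.5
        with pytest.warns(UserWarning, match="constant"):
            train_cmax_regressor(ds, feats, SearchSpace.fast(), seed=0)

    def test_too_few_rows_error(self):
        ds, feats = _toy_dataset(10, 10, numeric=True)
        with pytest.raises(ValueError, match="20"):
            train_cmax_regressor(ds, feats, SearchSpace.fast(), seed=0)


class TestPredictEndpoint:
    def test_threshold_tie_positive(self):
        ds, feats = _toy_dataset(100, 11)
        model = train_endpoint_classifier(ds, feats, SearchSpace.fast(), seed=0)
        probs, calls = predict_endpoint(model, feats)
        at = probs >= model.threshold
        assert np.array_equal(calls.astype(bool), at)

    def test_empty_input(self):
        ds, feats = _toy_dataset(100, 12)
        model = train_endpoint_classifier(ds, feats, SearchSpace.fast(), seed=0)
        empty = FeatureBlock("toy_features", np.zeros((0, 10)), feats.feature_names)
        probs, calls = predict_endpoint(model, empty)
        assert len(probs) == 0 and len(calls) == 0

    def test_unfitted_errors(self):
        from sklearn.ensemble import RandomForestClassifier

        from dilinet.endpoint_models import EndpointModel

        m = EndpointModel(
            endpoint="x",
            estimator=RandomForestClassifier(),
            threshold=0.5,
            cv_config={},
            training_digest="",
            training_keys=frozenset(),
            feature_names=["f0"],
        )
        ds, feats = _toy_dataset(10, 13)
        with pytest.raises(ValueError, match="not fitted"):
            predict_endpoint(m, feats)


class TestCrossPredict:
    def test_matrix_contract(self, pipeline):
        models = {
            k: v for k, v in pipeline["models"].items() if v.is_classifier
        }
        out = cross_predict_matrix(models, pipeline["panel"], pipeline["featurize"])
        names = [p.name for p in pipeline["panel"].proxies]
        assert sorted(out) == sorted(names)
        for i in names:
            assert sorted(out[i]) == sorted(names)
            for j in names:
                cell = out[i][j]
                assert {"auc_roc", "f1", "lr_plus", "threshold"} <= set(cell)

    def test_shared_signal_beats_independent(self, pipeline):
        # endpoint_a and endpoint_b share the nitro toxicophore;
        # endpoint_c and endpoint_d carry unrelated ones
        models = {
            k: v for k, v in pipeline["models"].items() if v.is_classifier
        }
        out = cross_predict_matrix(models, pipeline["panel"], pipeline["featurize"])
        assert out["endpoint_b"]["endpoint_a"]["auc_roc"] > 0.5
        shared = out["endpoint_b"]["endpoint_a"]["auc_roc"]
        indep = out["endpoint_b"]["endpoint_c"]["auc_roc"]
        assert shared > indep
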