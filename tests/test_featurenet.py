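"""Stacked features, nested CV, final model, prediction and attribution."""

import numpy as np
import pytest

from dilinet.data_model import EndpointDataset
from dilinet.featurenet import (
    LeakError,
    NestedCVConfig,
    attribute,
    fit_final,
    nested_cv,
    predict_dili,
    top_structural_features,
)


@pytest.fixture(scope="module")
def trained(pipeline):
    builder = pipeline["builder"]
    gold_train = pipeline["gold_train"]
    stacked = builder.build(gold_train.compounds, combo="all")
    cfg = NestedCVConfig(repeats=2, space=pipeline["space"], seed=0)
    report = nested_cv(gold_train, stacked, cfg)
    final = fit_final(gold_train, stacked, builder, report.best_repeat_params(), seed=0)
    return {"stacked": stacked, "report": report, "final": final}


class TestBuildStacked:
    def test_width_identity_all(self, pipeline):
        fz = pipeline["featurizer"]
        builder = pipeline["builder"]
        stacked = builder.build(pipeline["gold_train"].compounds, combo="all")
        expected = fz.n_structural + fz.n_descriptor_features + len(builder.endpoint_models)
        assert stacked.width == expected

    def test_proxy_only_width(self, pipeline):
        builder = pipeline["builder"]
        stacked = builder.build(pipeline["gold_train"].compounds[:3], combo="proxy")
        assert stacked.width == len(builder.endpoint_models)
        names = set(stacked.feature_names)
        for name, model in builder.endpoint_models.items():
            tag = "proxy" if model.is_classifier else "pk"
            assert f"{tag}:{name}" in names

    def test_proxy_columns_are_probabilities(self, pipeline):
        builder = pipeline["builder"]
        stacked = builder.build(pipeline["gold_train"].compounds, combo="all")
        for j, prov in enumerate(stacked.provenance):
            if prov == "proxy":
                col = stacked.matrix[:, j]
                assert np.all((col >= 0) & (col <= 1))
            elif prov == "pk":
                assert np.all(np.isfinite(stacked.matrix[:, j]))

    def test_empty_compound_list(self, pipeline):
        stacked = pipeline["builder"].build([], combo="all")
        assert stacked.matrix.shape[0] == 0
        assert stacked.width == len(stacked.feature_names) > 0

    def test_leak_guard_raises(self, pipeline):
        builder = pipeline["builder"]
        # a compound from a proxy training set must be refused
        leaky = pipeline["panel"].proxies[0].compounds[:1]
        with pytest.raises(LeakError):
            builder.build(leaky, combo="all")

    def test_leak_guard_passes_gold(self, pipeline):
        # panel construction removed the overlap, so gold passes every run
        builder = pipeline["builder"]
        for model in builder.endpoint_models.values():
            if model.is_classifier:
                assert not (
                    set(pipeline["gold_train"].keys()) & model.training_keys
                )
        builder.leak_check(pipeline["gold_train"].compounds)

    def test_bad_combo(self, pipeline):
        with pytest.raises(ValueError):
            pipeline["builder"].build([], combo="everything")


class TestNestedCV:
    def test_row_count_folds_times_repeats(self, pipeline, trained):
        cfg = trained["report"].config
        assert len(trained["report"].rows) == cfg.outer_folds * cfg.repeats

    def test_thresholds_from_training_only(self, trained):
        for row in trained["report"].rows:
            assert 0.0 <= row["threshold"] <= 1.0

    def test_repeat_means_length(self, trained):
        assert len(trained["report"].repeat_means("auc_roc")) == 2


class TestFinalModel:
    def test_threshold_in_unit_interval(self, trained):
        assert 0.0 < trained["final"].threshold < 1.0

    def test_threshold_reproducible_from_oof(self, pipeline, trained):
        # threshold is a pure function of training data: recomputing from
        # the persisted out-of-fold probabilities reproduces it exactly
        from dilinet.endpoint_models import youden_threshold

        final = trained["final"]
        y = pipeline["gold_train"].labels()
        assert youden_threshold(final.oof_probs, y) == final.threshold

    def test_same_seed_same_model(self, pipeline, trained):
        final2 = fit_final(
            pipeline["gold_train"],
            trained["stacked"],
            pipeline["builder"],
            trained["report"].best_repeat_params(),
            seed=0,
        )
        a = trained["final"].estimator.predict_proba(trained["stacked"].matrix)
        b = final2.estimator.predict_proba(trained["stacked"].matrix)
        assert np.array_equal(a, b)
        assert final2.threshold == trained["final"].threshold


class TestPredictDili:
    def test_training_compound_reproducible(self, pipeline, trained):
        c = pipeline["gold_train"].compounds[0]
        res = predict_dili(trained["final"], [c.smiles_in or c.smiles_std])
        assert len(res["accepted"]) == 1
        stacked = pipeline["builder"].build([c], combo="all", check_leak=False)
        expected = trained["final"].estimator.predict_proba(stacked.matrix)[0, 1]
        assert res["accepted"][0]["probability"] == pytest.approx(expected, abs=1e-12)

    def test_invalid_smiles_rejected_no_crash(self, trained):
        res = predict_dili(trained["final"], ["C1CC"])
        assert res["accepted"] == []
        assert res["rejected"][0]["reason"] == "parse_failure"

    def test_mixed_batch(self, trained):
        res = predict_dili(trained["final"], ["CCO", "[Fe+2]", "c1ccccc1"])
        assert len(res["accepted"]) == 2 and len(res["rejected"]) == 1
        for a in res["accepted"]:
            assert 0.0 <= a["probability"] <= 1.0
            assert a["call"] in (0, 1)


class TestAttribute:
    def test_additivity(self, pipeline, trained):
        for c in pipeline["gold_test"].compounds[:5]:
            att = attribute(trained["final"], c)
            total = att["base_value"] + sum(v for _, _, v in att["contributions"])
            assert total == pytest.approx(att["probability"], abs=1e-6)

    def test_top_proxy_lists(self, pipeline, trained):
        att = attribute(trained["final"], pipeline["gold_test"].compounds[0])
        assert len(att["top_positive_proxy"]) <= 3
        assert len(att["top_negative_proxy"]) <= 3
        for _, v in att["top_positive_proxy"]:
            assert v > 0
        for _, v in att["top_negative_proxy"]:
            assert v < 0

    def test_highlight_or_note(self, pipeline, trained):
        att = attribute(trained["final"], pipeline["gold_test"].compounds[0])
        assert (att["highlight"] is not None) != (att["note"] is not None)
        if att["highlight"]:
            assert att["highlight"]["atoms"]

    def test_single_feature_model_all_mass_on_it(self):
        # train on one informative column; attribution must land there
        from sklearn.ensemble import RandomForestClassifier

        from dilinet.attribution import forest_contributions

        rng = np.random.default_rng(0)
        X = rng.random((300, 5))
        y = (X[:, 2] > 0.5).astype(int)
        X[:, [0, 1, 3, 4]] = 0.0  # other columns constant -> unusable
        clf = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        base, contrib = forest_contributions(clf, X[0])
        assert abs(contrib[2]) == pytest.approx(np.abs(contrib).sum())

    def test_forest_contributions_sum_regressor(self):
        from sklearn.ensemble import RandomForestRegressor

        from dilinet.attribution import forest_contributions

        rng = np.random.default_rng(1)
        X = rng.random((200, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0])
        reg = RandomForestRegressor(n_estimators=30, random_state=0).fit(X, y)
        x = X[7]
        base, contrib = forest_contributions(reg, x)
        assert base + contrib.sum() == pytest.approx(
            reg.predict(x[None, :])[0], abs=1e-8
        )

    def test_top_structural_features_positive_only(self, pipeline, trained):
        att = attribute(trained["final"], pipeline["gold_test"].compounds[0])
        names = top_structural_features(att, k=3)
        assert len(names) <= 3
        contribs = dict(
            ((n, v) for n, p, v in att["contributions"] if p == "structural")
        )
        for n in names:
            assert contribs[n] > 0
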