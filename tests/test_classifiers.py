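"""Model families: structure, training, evaluation."""

import numpy as np
import pytest

from perceptgap.classifiers import (ConfigurationError, GenericConvClassifier,
                                    LocalBagClassifier, ModelConfig,
                                    TrainConfig, build_model, evaluate,
                                    load_model, records_to_arrays, save_model,
                                    train)
from perceptgap.contour_stimuli import generate_dataset
from perceptgap.features import LOCAL_PLAN, LayerSpec


def test_build_model_families():
    assert isinstance(build_model(ModelConfig("local_bag")),
                      LocalBagClassifier)
    assert isinstance(build_model(ModelConfig("generic_cnn")),
                      GenericConvClassifier)
    with pytest.raises(ConfigurationError):
        build_model(ModelConfig("resnet50"))


def test_rf_limit_violation_is_a_configuration_error():
    # one extra 3x3 stage at jump 8 pushes the analytic RF to 49 > 33
    plan = LOCAL_PLAN + (LayerSpec(3, 1, 8, "random"),)
    with pytest.raises(ConfigurationError):
        LocalBagClassifier(plan=plan)._make_trunk()
    # raising the limit makes the same plan legal
    LocalBagClassifier(plan=plan, rf_limit=49)._make_trunk()


def test_predict_proba_is_a_distribution(local_model, test_records):
    X, _ = records_to_arrays(test_records[:8])
    p = local_model.predict_proba(X)
    assert p.shape == (8, 2)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all()


def test_training_sanity_and_history(local_model, generic_model):
    for m in (local_model, generic_model):
        h = m.history_
        assert {"epoch", "loss", "train_accuracy"} <= set(h.columns)
        assert np.isfinite(h["loss"]).all()
        assert h["train_accuracy"].iloc[-1] > 0.5


def test_models_learn_the_contour_task(local_model, generic_model,
                                       test_records):
    """Held-out accuracy above chance for both families; the generic model
    (strictly larger capacity) is not substantially worse than the local."""
    acc_local = evaluate(local_model, test_records).accuracy
    acc_generic = evaluate(generic_model, test_records).accuracy
    assert acc_local > 0.55
    assert acc_generic > 0.8
    assert acc_generic >= acc_local - 0.05


def test_shuffled_labels_give_chance_performance():
    """No-signal control: training on shuffled labels yields ~0.5."""
    recs, _ = generate_dataset(160, 0.5, seed=31)
    test, _ = generate_dataset(300, 0.5, seed=32)
    X, y = records_to_arrays(recs)
    rng = np.random.default_rng(0)
    y_shuf = rng.permutation(y)
    m = LocalBagClassifier(seed=0).fit(X, y_shuf)
    acc = evaluate(m, test).accuracy
    assert abs(acc - 0.5) < 0.08


def test_same_seed_identical_history():
    recs, _ = generate_dataset(60, 0.5, seed=33)
    X, y = records_to_arrays(recs)
    h1 = LocalBagClassifier(seed=4, n_epochs=5).fit(X, y).history_
    h2 = LocalBagClassifier(seed=4, n_epochs=5).fit(X, y).history_
    assert h1.equals(h2)
    g1 = GenericConvClassifier(seed=4, n_epochs=5).fit(X, y).history_
    g2 = GenericConvClassifier(seed=4, n_epochs=5).fit(X, y).history_
    assert g1.equals(g2)


def test_evaluate_exactness(oracle_model, constant_model, test_records):
    res = evaluate(oracle_model, test_records)
    assert res.accuracy == 1.0
    res_c = evaluate(constant_model, test_records)
    assert res_c.accuracy == 0.5          # balanced set, constant output
    # accuracy equals the mean of per-class accuracies on a balanced set
    assert res_c.accuracy == pytest.approx(
        np.mean(list(res_c.per_class_accuracy.values())))
    with pytest.raises(ValueError):
        evaluate(constant_model, [])


def test_train_wrapper_respects_n_train(test_records):
    model = LocalBagClassifier()
    fitted, hist = train(model, test_records,
                         TrainConfig(n_train=40, n_epochs=3, seed=1))
    assert len(hist) == 3
    with pytest.raises(ValueError):
        train(LocalBagClassifier(), test_records, TrainConfig(n_train=10**6))


def test_checkpoint_roundtrip(tmp_path, local_model, test_records):
    X, _ = records_to_arrays(test_records[:6])
    p = tmp_path / "m.joblib"
    save_model(local_model, p)
    clone = load_model(p)
    assert np.allclose(clone.predict_proba(X), local_model.predict_proba(X))


def test_sklearn_params_protocol():
    m = LocalBagClassifier(rf_limit=33, seed=3)
    params = m.get_params()
    assert params["rf_limit"] == 33 and params["seed"] == 3
    m.set_params(seed=5)
    assert m.seed == 5
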