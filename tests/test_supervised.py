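"""Metrics, splits, cross-validation and hyperparameter search."""

import numpy as np
import pandas as pd
import pytest

from aampnn.data_prep import generate_fixture
from aampnn.supervised import SEARCH_SPACE, CVResult, Metrics, ModelConfig, \
    SplitPlan, bayes_optimize, cross_validate, evaluate_metrics, \
    make_splits, scaffold_holdout_split, tpe_minimize, train
from oracle_utils import oracle_roc_auc


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def test_perfect_separation_gives_auc_one():
    m = evaluate_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert m.roc_auc == 1.0 and m.accuracy == 1.0


def test_confusion_matrix_metrics_hand_case():
    """TP=90, FP=10, TN=80, FN=20 at the 0.5 threshold."""
    probs = np.concatenate([np.full(90, 0.9), np.full(20, 0.1),   # positives
                            np.full(10, 0.9), np.full(80, 0.1)])  # negatives
    labels = np.concatenate([np.ones(110), np.zeros(90)])
    m = evaluate_metrics(probs, labels)
    assert m.accuracy == pytest.approx(0.85)
    assert m.precision == pytest.approx(0.90)
    assert m.sensitivity == pytest.approx(0.8182, abs=1e-4)
    assert m.specificity == pytest.approx(0.8889, abs=1e-4)


def test_roc_auc_matches_pairwise_concordance_oracle():
    rng = np.random.Generator(np.random.PCG64(3))
    for _ in range(100):
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # quantize some scores to force ties
        scores = np.round(rng.random(n), 1)
        m = evaluate_metrics(scores, labels)
        assert m.roc_auc == pytest.approx(oracle_roc_auc(scores, labels),
                                          abs=1e-12)


def test_single_class_labels_rejected():
    with pytest.raises(ValueError):
        evaluate_metrics([0.1, 0.9], [1, 1])


# ----------------------------------------------------------------------
# splits
# ----------------------------------------------------------------------

def test_splits_partition_and_stratify():
    rng = np.random.Generator(np.random.PCG64(0))
    labels = rng.integers(0, 2, size=200)
    splits = make_splits(labels, SplitPlan(seed=1))
    all_idx = np.concatenate(list(splits.values()))
    assert sorted(all_idx) == list(range(200))
    global_frac = labels.mean()
    for name, idx in splits.items():
        n_pos = labels[idx].sum()
        expect = global_frac * len(idx)
        assert abs(n_pos - expect) <= 1.0 + 1e-9, name
    assert abs(len(splits["test"]) - 30) <= 1
    assert abs(len(splits["validation"]) - 30) <= 1
    assert abs(len(splits["calibration"]) - 140) <= 2


def test_scaffold_holdout_excludes_training_scaffolds():
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    df = generate_fixture(120, seed=11)
    labels = df["label"].to_numpy()
    splits = scaffold_holdout_split(df["smiles"].tolist(), labels,
                                    SplitPlan(seed=0))
    scaff = [Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(
        Chem.MolFromSmiles(s))) for s in df["smiles"]]
    train_sc = {scaff[i] for i in np.concatenate(
        [splits["calibration"], splits["validation"]])}
    test_sc = {scaff[i] for i in splits["test"]}
    assert not train_sc & test_sc


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

SMALL = dict(hidden_dim=16, n_attention_heads=4, ecfp_bits=256,
             batch_size=128)


def test_training_loss_decreases(fixture_smiles):
    df = generate_fixture(80, seed=21)
    cfg = ModelConfig(epochs=10, **SMALL)
    res = train(df, cfg, SplitPlan(seed=0), seed=0)
    assert res.epoch_losses[-1] < res.epoch_losses[0]
    assert set(res.metrics) == {"calibration", "validation", "test"}


def test_training_reproducible_under_seed():
    df = generate_fixture(60, seed=22)
    cfg = ModelConfig(epochs=3, **SMALL)
    m1 = train(df, cfg, SplitPlan(seed=0), seed=5).metrics["test"]
    m2 = train(df, cfg, SplitPlan(seed=0), seed=5).metrics["test"]
    assert m1.to_dict() == m2.to_dict()


def test_training_with_and_without_pretrained_encoder():
    from aampnn.encoder import init_encoder_params

    df = generate_fixture(60, seed=23)
    cfg = ModelConfig(epochs=2, **SMALL)
    rng = np.random.Generator(np.random.PCG64(0))
    pre = init_encoder_params(rng, cfg.encoder_config())
    for encoder in (None, pre):
        res = train(df, cfg, SplitPlan(seed=0), seed=0,
                    pretrained_encoder=encoder)
        assert all(np.isfinite(list(m.to_dict().values())).all()
                   for m in res.metrics.values())


def test_single_class_dataset_rejected():
    df = pd.DataFrame({"smiles": ["CCO", "CCN", "CCC", "CO"] * 5,
                       "label": [1] * 20})
    with pytest.raises(ValueError):
        train(df, ModelConfig(epochs=1, **SMALL))


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------

def test_cv_folds_partition_dataset():
    df = generate_fixture(50, seed=24)
    cfg = ModelConfig(epochs=1, **SMALL)
    res = cross_validate(df, cfg, folds=5, seed=0)
    assert isinstance(res, CVResult)
    assert set(res.fold_assignment) == set(range(5))
    assert (res.fold_assignment >= 0).all()        # everyone in one fold
    assert len(res.fold_metrics) == 5


def test_cv_seed_fixes_fold_assignment():
    df = generate_fixture(40, seed=25)
    cfg = ModelConfig(epochs=1, **SMALL)
    a = cross_validate(df, cfg, folds=4, seed=3).fold_assignment
    b = cross_validate(df, cfg, folds=4, seed=3).fold_assignment
    np.testing.assert_array_equal(a, b)


def test_cv_stratification_error_when_class_too_small():
    df = pd.DataFrame({"smiles": ["CCO", "CCN", "CCC", "CCCC", "CO", "CN"],
                       "label": [1, 0, 0, 0, 0, 0]})
    with pytest.raises(ValueError):
        cross_validate(df, ModelConfig(epochs=1, **SMALL), folds=3)


# ----------------------------------------------------------------------
# hyperparameter search
# ----------------------------------------------------------------------

def test_tpe_finds_argmax_of_two_point_space():
    space = {"x": ("choice", [1, 5])}
    out = tpe_minimize(lambda c: float(c["x"]), space, n_iterations=12,
                       seed=0)
    assert out["best_config"]["x"] == 5
    assert len(out["trials"]) == 12


def test_tpe_reproducible_trial_sequence():
    space = {"x": ("choice", [0, 1, 2, 3]),
             "lr": ("loguniform", 1e-4, 1e-3)}

    def obj(c):
        return -abs(c["x"] - 2) - abs(np.log10(c["lr"]) + 3.5)

    t1 = tpe_minimize(obj, space, 15, seed=4)
    t2 = tpe_minimize(obj, space, 15, seed=4)
    assert t1["trials"] == t2["trials"]


def test_tpe_concentrates_on_good_region():
    space = {"x": ("choice", list(range(10)))}
    out = tpe_minimize(lambda c: -abs(c["x"] - 7), space, 30, seed=1)
    assert out["best_config"]["x"] == 7


def test_tpe_rejects_empty_space():
    with pytest.raises(ValueError):
        tpe_minimize(lambda c: 0.0, {}, 3)


def test_bayes_optimize_trials_stay_in_grid(tmp_path):
    df = generate_fixture(60, seed=26)
    base = ModelConfig(epochs=1, **SMALL)
    log = tmp_path / "trials.jsonl"
    best, trials = bayes_optimize(df, n_epochs=1, n_iterations=3, seed=0,
                                  base_config=base, trial_log_path=log)
    assert len(trials) == 3
    for t in trials:
        cfg = t["config"]
        assert cfg["message_iterations"] in SEARCH_SPACE["message_iterations"][1]
        assert cfg["batch_size"] in SEARCH_SPACE["batch_size"][1]
        assert cfg["dropout"] in SEARCH_SPACE["dropout"][1]
        assert cfg["ffn_layers"] in SEARCH_SPACE["ffn_layers"][1]
        assert 1e-4 <= cfg["learning_rate"] <= 1e-3
    assert log.exists() and len(log.read_text().splitlines()) == 3
    assert isinstance(best, ModelConfig)


def test_model_config_grid_validation():
    with pytest.raises(ValueError):
        ModelConfig(message_iterations=7)
    with pytest.raises(ValueError):
        ModelConfig(dropout=0.5)
    with pytest.raises(ValueError):
        ModelConfig(learning_rate=5e-3)
    with pytest.raises(ValueError):
        ModelConfig(ffn_layers=4)
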