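"""Fine-tuning, evaluation metrics, data splitting, cross-validation and
Bayesian hyperparameter search.

The evaluation scheme: a stratified random 70:15:15 split of the full
dataset into calibration (training), validation and test sets — i.e.
85% train+validation vs 15% held-out test — with stratified five-fold
cross-validation reported as mean ± sample standard deviation of the
metric suite (ROC-AUC, accuracy, precision, sensitivity, specificity).
Hyperparameters are tuned over a fixed grid (message-passing depth
2–6, batch size {128, 256, 512}, dropout 0–0.4 in 0.05 steps, 2–3 FFN
layers, Adam learning rate 1e-4…1e-3) with a tree-structured Parzen
estimator, selecting on validation ROC-AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encoder import EncoderConfig
from .featurization import featurize_molecule
from .model import PermeabilityModel, bce_with_logits
from .nn import Adam
from .tensor import Tensor

__all__ = ["ModelConfig", "SplitPlan", "Metrics", "evaluate_metrics",
           "make_splits", "train", "TrainResult", "cross_validate",
           "CVResult", "tpe_minimize", "bayes_optimize", "SEARCH_SPACE"]


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

_DROPOUT_GRID = [round(0.05 * i, 2) for i in range(9)]   # 0.0 … 0.4

#: the hyperparameter grid searched during tuning
SEARCH_SPACE: dict[str, tuple] = {
    "message_iterations": ("choice", [2, 3, 4, 5, 6]),
    "batch_size": ("choice", [128, 256, 512]),
    "dropout": ("choice", _DROPOUT_GRID),
    "ffn_layers": ("choice", [2, 3]),
    "learning_rate": ("loguniform", 1e-4, 1e-3),
}


@dataclass(frozen=True)
class ModelConfig:
    """Trainable-model hyperparameters; tuned fields must lie on the grid."""

    message_iterations: int = 3
    batch_size: int = 128
    dropout: float = 0.0
    ffn_layers: int = 2
    learning_rate: float = 5e-4
    use_ecfp: bool = True
    use_pretrained: bool = False
    hidden_dim: int = 300
    n_attention_heads: int = 4
    epochs: int = 30
    ecfp_radius: int = 2
    ecfp_bits: int = 2048

    def __post_init__(self):
        if self.message_iterations not in SEARCH_SPACE["message_iterations"][1]:
            raise ValueError("message_iterations must lie in 2..6")
        if not 0.0 <= self.dropout <= 0.4:
            raise ValueError("dropout must lie in [0.0, 0.4]")
        if self.ffn_layers not in (2, 3):
            raise ValueError("ffn_layers must be 2 or 3")
        if not 1e-4 <= self.learning_rate <= 1e-3:
            raise ValueError("learning_rate must lie in [1e-4, 1e-3]")

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(hidden_dim=self.hidden_dim,
                             message_iterations=self.message_iterations,
                             n_attention_heads=self.n_attention_heads)


@dataclass(frozen=True)
class SplitPlan:
    """Stratified random partition fractions of the FULL dataset.

    70% calibration (training), 15% validation, 15% test — the 85:15
    train/test division with the training side further split 70:15.
    """

    test_fraction: float = 0.15
    validation_fraction: float = 0.15
    cv_folds: int = 5
    seed: int = 0


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

@dataclass
class Metrics:
    roc_auc: float
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict[str, float]:
        return {"roc_auc": self.roc_auc, "accuracy": self.accuracy,
                "precision": self.precision, "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def evaluate_metrics(probabilities, labels,
                     threshold: float = 0.5) -> Metrics:
    """Metric suite from probabilities and binary labels.

    ROC-AUC is the probability that a random positive outranks a random
    negative (ties count one half); the confusion-matrix metrics use
    the fixed 0.5 decision threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC undefined: labels contain a single class")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return Metrics(
        roc_auc=float(roc_auc_score(y, p)),
        accuracy=(tp + tn) / len(y),
        precision=tp / (tp + fp) if tp + fp else 0.0,
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
    )


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------

def make_splits(labels: np.ndarray, plan: SplitPlan) -> dict[str, np.ndarray]:
    """Stratified calibration/validation/test index partition."""
    idx = np.arange(len(labels))
    rest, test = train_test_split(idx, test_size=plan.test_fraction,
                                  stratify=labels, random_state=plan.seed)
    val_of_rest = plan.validation_fraction / (1.0 - plan.test_fraction)
    calib, val = train_test_split(rest, test_size=val_of_rest,
                                  stratify=labels[rest],
                                  random_state=plan.seed)
    return {"calibration": np.sort(calib), "validation": np.sort(val),
            "test": np.sort(test)}


def scaffold_holdout_split(smiles: list[str], labels: np.ndarray,
                           plan: SplitPlan) -> dict[str, np.ndarray]:
    """Alternative split holding out whole Murcko scaffolds as the test set
    (every test compound's scaffold is absent from training)."""
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    scaffs = [Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(
        Chem.MolFromSmiles(s))) for s in smiles]
    uniq = sorted(set(scaffs))
    rng = np.random.Generator(np.random.PCG64(plan.seed))
    rng.shuffle(uniq)
    n = len(smiles)
    test_scaffs, count = set(), 0
    for sc in uniq:
        if count >= plan.test_fraction * n:
            break
        test_scaffs.add(sc)
        count += scaffs.count(sc)
    test = np.array([i for i, sc in enumerate(scaffs) if sc in test_scaffs])
    rest = np.array([i for i, sc in enumerate(scaffs) if sc not in test_scaffs])
    val_of_rest = plan.validation_fraction / (1.0 - plan.test_fraction)
    calib, val = train_test_split(rest, test_size=val_of_rest,
                                  stratify=labels[rest],
                                  random_state=plan.seed)
    return {"calibration": np.sort(calib), "validation": np.sort(val),
            "test": np.sort(test)}


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

@dataclass
class TrainResult:
    model: PermeabilityModel
    metrics: dict[str, Metrics]
    epoch_losses: list[float]
    splits: dict[str, np.ndarray] = field(default_factory=dict)


def _fit(model: PermeabilityModel, graphs, smiles, labels,
         config: ModelConfig, rng: np.random.Generator,
         log: list[float] | None = None,
         freeze_encoder: bool = False) -> list[float]:
    """Adam/BCE optimization loop; returns per-epoch mean losses."""
    if freeze_encoder:
        trainable = {k: v for k, v in model.params.items()
                     if k.startswith("ffn")}
    else:
        trainable = model.params
    opt = Adam(trainable, lr=config.learning_rate)
    n = len(graphs)
    losses: list[float] = log if log is not None else []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            if len(sel) == 0:
                continue
            logits, _ = model.forward_logits([graphs[i] for i in sel],
                                             [smiles[i] for i in sel],
                                             rng=rng)
            loss = bce_with_logits(logits, labels[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch.append(loss.item())
        losses.append(float(np.mean(epoch)))
    return losses


def train(dataset: pd.DataFrame, config: ModelConfig,
          plan: SplitPlan | None = None,
          pretrained_encoder: dict[str, Tensor] | None = None,
          seed: int = 0, freeze_encoder: bool = False,
          split_indices: dict[str, np.ndarray] | None = None) -> TrainResult:
    """Fine-tune a classifier on a ``smiles``/``label`` DataFrame.

    When pretrained encoder parameters are supplied the encoder starts
    from them (fully fine-tuned unless ``freeze_encoder``); the FFN head
    is always freshly initialized.  Metrics are reported per split.
    """
    labels = dataset["label"].to_numpy(dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes present")
    smiles = dataset["smiles"].tolist()
    plan = plan or SplitPlan(seed=seed)
    splits = split_indices or make_splits(labels, plan)

    rng = np.random.Generator(np.random.PCG64(seed))
    model = PermeabilityModel.initialize(
        rng, config.encoder_config(), ffn_layers=config.ffn_layers,
        dropout=config.dropout, use_ecfp=config.use_ecfp,
        ecfp_radius=config.ecfp_radius, ecfp_bits=config.ecfp_bits,
        pretrained_encoder=pretrained_encoder)

    graphs = [featurize_molecule(s) for s in smiles]
    cal = splits["calibration"]
    losses = _fit(model, [graphs[i] for i in cal], [smiles[i] for i in cal],
                  labels[cal], config, rng, freeze_encoder=freeze_encoder)

    metrics: dict[str, Metrics] = {}
    for name, idx in splits.items():
        probs = model.predict_graphs([graphs[i] for i in idx],
                                     [smiles[i] for i in idx])
        metrics[name] = evaluate_metrics(probs, labels[idx])
    return TrainResult(model=model, metrics=metrics, epoch_losses=losses,
                       splits=splits)


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------

@dataclass
class CVResult:
    mean: Metrics
    std: Metrics
    fold_metrics: list[Metrics]
    fold_assignment: np.ndarray


def cross_validate(dataset: pd.DataFrame, config: ModelConfig,
                   folds: int = 5, seed: int = 0,
                   pretrained_encoder: dict[str, Tensor] | None = None,
                   ) -> CVResult:
    """Stratified k-fold CV; mean and sample standard deviation per metric."""
    labels = dataset["label"].to_numpy(dtype=int)
    smiles = dataset["smiles"].tolist()
    if folds < 2:
        raise ValueError("cross-validation requires at least 2 folds")
    if len(dataset) < folds:
        raise ValueError("dataset smaller than the number of folds")
    counts = np.bincount(labels)
    if (counts[counts > 0] < folds).any():
        raise ValueError("stratification impossible: a class has fewer "
                         "members than folds")

    graphs = [featurize_molecule(s) for s in smiles]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.full(len(labels), -1)
    fold_metrics: list[Metrics] = []
    for k, (tr, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[va] = k
        rng = np.random.Generator(np.random.PCG64(seed * 1000 + k))
        model = PermeabilityModel.initialize(
            rng, config.encoder_config(), ffn_layers=config.ffn_layers,
            dropout=config.dropout, use_ecfp=config.use_ecfp,
            ecfp_radius=config.ecfp_radius, ecfp_bits=config.ecfp_bits,
            pretrained_encoder=pretrained_encoder)
        _fit(model, [graphs[i] for i in tr], [smiles[i] for i in tr],
             labels[tr], config, rng)
        probs = model.predict_graphs([graphs[i] for i in va],
                                     [smiles[i] for i in va])
        fold_metrics.append(evaluate_metrics(probs, labels[va]))

    names = ["roc_auc", "accuracy", "precision", "sensitivity", "specificity"]
    arr = np.array([[getattr(m, n) for n in names] for m in fold_metrics])
    mean = Metrics(**dict(zip(names, arr.mean(axis=0))))
    std = Metrics(**dict(zip(names, arr.std(axis=0, ddof=1))))
    return CVResult(mean=mean, std=std, fold_metrics=fold_metrics,
                    fold_assignment=fold_of)


# ----------------------------------------------------------------------
# tree-structured Parzen estimator
# ----------------------------------------------------------------------

def _tpe_sample(space, trials, rng, n_candidates=24, gamma=0.25,
                n_startup=8):
    """Propose one configuration by the TPE good/bad density ratio."""
    def random_point():
        pt = {}
        for name, spec in space.items():
            if spec[0] == "choice":
                pt[name] = spec[1][int(rng.integers(len(spec[1])))]
            else:
                lo, hi = spec[1], spec[2]
                pt[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return pt

    if len(trials) < n_startup:
        return random_point()

    scores = np.array([t["score"] for t in trials])
    n_good = max(1, int(np.ceil(gamma * len(trials))))
    good_idx = np.argsort(-scores)[:n_good]     # maximize score
    good = [trials[i]["config"] for i in good_idx]
    bad = [trials[i]["config"] for i in np.argsort(-scores)[n_good:]]

    def density(values, x, spec):
        if spec[0] == "choice":
            cats = spec[1]
            counts = np.array([sum(v == c for v in values) + 1.0
                               for c in cats])
            return counts[cats.index(x)] / counts.sum()
        logs = np.log(np.array(values, dtype=float))
        width = np.log(spec[2]) - np.log(spec[1])
        bw = max(logs.std(), width / 10.0) if len(logs) > 1 else width / 4.0
        return float(np.mean(np.exp(-0.5 * ((np.log(x) - logs) / bw) ** 2))
                     / bw + 1e-12)

    best_pt, best_ratio = None, -np.inf
    for _ in range(n_candidates):
        # sample each coordinate from the good set (with exploration)
        pt = {}
        for name, spec in space.items():
            donor = good[int(rng.integers(len(good)))]
            if spec[0] == "choice":
                if rng.random() < 0.2:
                    pt[name] = spec[1][int(rng.integers(len(spec[1])))]
                else:
                    pt[name] = donor[name]
            else:
                lo, hi = spec[1], spec[2]
                logs = np.log([g[name] for g in good])
                bw = max(np.std(logs), (np.log(hi) - np.log(lo)) / 10.0)
                x = np.exp(np.log(donor[name]) + rng.normal(0.0, bw))
                pt[name] = float(np.clip(x, lo, hi))
        ratio = 1.0
        for name, spec in space.items():
            lg = density([g[name] for g in good], pt[name], spec)
            lb = density([b[name] for b in bad], pt[name], spec) if bad else 1.0
            ratio *= lg / (lb + 1e-12)
        if ratio > best_ratio:
            best_pt, best_ratio = pt, ratio
    return best_pt


def tpe_minimize(objective, space: dict[str, tuple], n_iterations: int,
                 seed: int = 0, maximize: bool = True) -> dict:
    """Sequential model-based search over a mixed discrete/continuous space.

    ``objective(config) -> float``; returns ``{"best_config", "best_score",
    "trials"}`` with the full trial log.
    """
    if not space:
        raise ValueError("empty search space")
    rng = np.random.Generator(np.random.PCG64(seed))
    trials: list[dict] = []
    for _ in range(n_iterations):
        cfg = _tpe_sample(space, trials, rng)
        score = float(objective(cfg))
        trials.append({"config": cfg,
                       "score": score if maximize else -score})
    best = max(trials, key=lambda t: t["score"])
    return {"best_config": best["config"],
            "best_score": best["score"] if maximize else -best["score"],
            "trials": [{"config": t["config"],
                        "score": t["score"] if maximize else -t["score"]}
                       for t in trials]}


def bayes_optimize(dataset: pd.DataFrame,
                   search_space: dict[str, tuple] | None = None,
                   n_epochs: int = 20, n_iterations: int = 20,
                   seed: int = 0, base_config: ModelConfig | None = None,
                   plan: SplitPlan | None = None,
                   pretrained_encoder: dict[str, Tensor] | None = None,
                   trial_log_path=None) -> tuple[ModelConfig, list[dict]]:
    """Tune hyperparameters by validation ROC-AUC over the standard grid.

    Every evaluated configuration lies in the search space; the trial
    log (config + score per iteration) is returned and optionally
    persisted as JSON lines.
    """
    space = search_space or SEARCH_SPACE
    base = base_config or ModelConfig()
    plan = plan or SplitPlan(seed=seed)
    labels = dataset["label"].to_numpy(dtype=int)
    splits = make_splits(labels, plan)

    def objective(cfg: dict) -> float:
        full = replace(base, epochs=n_epochs, **cfg)
        result = train(dataset, full, plan, seed=seed,
                       pretrained_encoder=pretrained_encoder,
                       split_indices=splits)
        return result.metrics["validation"].roc_auc

    out = tpe_minimize(objective, space, n_iterations, seed=seed)
    if trial_log_path is not None:
        with open(trial_log_path, "w") as fh:
            for t in out["trials"]:
                fh.write(json.dumps(t) + "\n")
    best = replace(base, **out["best_config"])
    return best, out["trials"]
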