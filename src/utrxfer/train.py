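"""Losses, plateau learning-rate schedule, early stopping, training,
hyperparameter search and the data-efficiency (scaling) experiment.

Training protocol: Adam on mini-batches with seeded shuffling, the
validation loss monitored once per epoch, a reduce-on-plateau schedule
(relative threshold), early stopping, and restoration of the weights of
the best epoch. Defaults mirror the pre-training protocol (maximum 20
epochs, early-stop patience 5; scheduler mode 'min', factor 0.5,
patience 3, relative threshold 0.01, minimum learning rate 1e-5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .data import DataSplit, ExpressionDataset, select_training_subset
from .model import ModelSpec, SequenceRegressor, build_model, encode_batch

__all__ = [
    "SchedulerConfig",
    "TrainConfig",
    "TrainingHistory",
    "small_study_config",
    "mse_loss",
    "lognormal_kl",
    "PlateauScheduler",
    "train",
    "TrialPruned",
    "hyperparameter_search",
    "log_spaced_sizes",
    "scaling_experiment",
]


@dataclass(frozen=True)
class SchedulerConfig:
    mode: str = "min"
    factor: float = 0.5
    patience: int = 3
    threshold: float = 0.01       # relative improvement threshold
    min_lr: float = 1e-5

    def __post_init__(self):
        if not (0.0 < self.factor < 1.0):
            raise ValueError("factor must be in (0, 1)")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "mse"             # mse | lognormal_kl
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 20
    early_stop_patience: int = 5
    scheduler: SchedulerConfig = field(default_factory=SchedulerConfig)
    kl_direction: str = "truth_to_pred"   # KL(truth || prediction)
    seed: int = 0

    def __post_init__(self):
        if self.loss not in ("mse", "lognormal_kl"):
            raise ValueError(f"unknown loss: {self.loss}")
        if self.scheduler.min_lr > self.learning_rate:
            raise ValueError("min_lr must not exceed the initial learning rate")
        if self.kl_direction not in ("truth_to_pred", "pred_to_truth"):
            raise ValueError(f"unknown KL direction: {self.kl_direction}")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "learning_rate": self.learning_rate,
        })


# Training settings paired with model.SMALL_CNN_LSTM_SPEC in the
# simulation studies (learning rate from the same validation sweep that
# fixed that architecture; everything else is the default protocol).
def small_study_config(seed: int = 0, **overrides) -> TrainConfig:
    overrides.setdefault("learning_rate", 3e-3)
    return TrainConfig(seed=seed, **overrides)


def mse_loss(predictions, targets) -> float:
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape or predictions.size == 0:
        raise ValueError("predictions and targets must have equal nonzero length")
    return float(np.mean((predictions - targets) ** 2))


def lognormal_kl(true_params, predicted_params) -> float:
    """KL(LogNormal(mu1, s1) || LogNormal(mu2, s2)).

    Equals the KL between the underlying normals:
    ln(s2/s1) + (s1^2 + (mu1-mu2)^2) / (2 s2^2) - 1/2.
    """
    mu1, s1 = true_params
    mu2, s2 = predicted_params
    if s1 <= 0 or s2 <= 0:
        raise ValueError("sigma must be positive")
    return float(math.log(s2 / s1) + (s1 ** 2 + (mu1 - mu2) ** 2) / (2 * s2 ** 2) - 0.5)


class PlateauScheduler:
    """Reduce-on-plateau with a relative improvement threshold.

    An epoch improves when the monitored loss drops below
    best * (1 - threshold); after more than ``patience`` consecutive
    non-improving epochs the learning rate is multiplied by ``factor``
    (floored at ``min_lr``) and the wait counter resets.
    """

    def __init__(self, initial_lr: float, config: SchedulerConfig | None = None):
        self.config = config or SchedulerConfig()
        if self.config.mode != "min":
            raise ValueError("only mode='min' is supported")
        self.lr = float(initial_lr)
        self.best = math.inf
        self.num_bad_epochs = 0

    def step(self, value: float) -> float:
        cfg = self.config
        improved = value < self.best * (1.0 - cfg.threshold) \
            if math.isfinite(self.best) else True
        if improved:
            self.best = value
            self.num_bad_epochs = 0
        else:
            self.num_bad_epochs += 1
            if self.num_bad_epochs > cfg.patience:
                self.lr = max(self.lr * cfg.factor, cfg.min_lr)
                self.num_bad_epochs = 0
        return self.lr


def _loss_and_grad(model: SequenceRegressor, raw: np.ndarray,
                   mu_t: np.ndarray, sigma_t: np.ndarray | None,
                   config: TrainConfig) -> tuple[float, np.ndarray]:
    """Batch loss and its gradient w.r.t. the raw model outputs."""
    n = raw.shape[0]
    mu_hat, sigma_hat = model.transform_outputs(raw)
    grad = np.zeros_like(raw)
    if config.loss == "mse":
        diff = mu_hat - mu_t
        loss = float(np.mean(diff ** 2))
        grad[:, 0] = 2.0 * diff / n
        return loss, grad
    if sigma_hat is None:
        raise ValueError("lognormal_kl loss requires a mean_and_sigma head")
    if sigma_t is None:
        raise ValueError("lognormal_kl loss requires target sigmas")
    z = raw[:, 1]
    dsig_dz = nn.sigmoid(z)  # d softplus / dz
    if config.kl_direction == "truth_to_pred":
        # KL(N(mu_t, s_t) || N(mu_hat, s_hat))
        loss_vec = (np.log(sigma_hat / sigma_t)
                    + (sigma_t ** 2 + (mu_t - mu_hat) ** 2) / (2 * sigma_hat ** 2)
                    - 0.5)
        dmu = (mu_hat - mu_t) / sigma_hat ** 2
        dsig = (1.0 / sigma_hat
                - (sigma_t ** 2 + (mu_t - mu_hat) ** 2) / sigma_hat ** 3)
    else:
        # KL(N(mu_hat, s_hat) || N(mu_t, s_t))
        loss_vec = (np.log(sigma_t / sigma_hat)
                    + (sigma_hat ** 2 + (mu_hat - mu_t) ** 2) / (2 * sigma_t ** 2)
                    - 0.5)
        dmu = (mu_hat - mu_t) / sigma_t ** 2
        dsig = -1.0 / sigma_hat + sigma_hat / sigma_t ** 2
    grad[:, 0] = dmu / n
    grad[:, 1] = dsig * dsig_dz / n
    return float(np.mean(loss_vec)), grad


def _eval_loss(model, X, mu_t, sigma_t, config, batch_size=512) -> float:
    total = 0.0
    for start in range(0, len(X), batch_size):
        sl = slice(start, start + batch_size)
        raw = model.forward(X[sl])
        loss, _ = _loss_and_grad(model, raw, mu_t[sl],
                                 None if sigma_t is None else sigma_t[sl], config)
        total += loss * (min(start + batch_size, len(X)) - start)
    return total / len(X)


class TrainingDiverged(RuntimeError):
    def __init__(self, message: str, history: TrainingHistory):
        super().__init__(message)
        self.history = history


def train(model: SequenceRegressor, dataset: ExpressionDataset, split: DataSplit,
          config: TrainConfig | None = None) -> tuple[SequenceRegressor, TrainingHistory]:
    """Train (in place) on the split's train set, monitoring validation
    loss for scheduling and early stopping; returns the model restored
    to its best epoch, plus the history."""
    config = config or TrainConfig()
    if not split.train_ids or not split.val_ids:
        raise ValueError("train and validation sets must be non-empty")
    need_sigma = config.loss == "lognormal_kl"

    def arrays(ids):
        sub = dataset.subset(ids)
        X = encode_batch(list(sub.frame["sequence"]), model.spec.max_len)
        mu = sub.mu
        sigma = None
        if need_sigma:
            if "sigma" not in sub.frame.columns or sub.frame["sigma"].isna().any():
                raise ValueError("lognormal_kl loss requires per-record sigma")
            sigma = sub.frame["sigma"].to_numpy(dtype=float)
        return X, mu, sigma

    Xtr, mu_tr, sg_tr = arrays(split.train_ids)
    Xva, mu_va, sg_va = arrays(split.val_ids)

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.layers)
    scheduler = PlateauScheduler(config.learning_rate, config.scheduler)
    history = TrainingHistory()
    best_val = math.inf
    best_state = model.get_state()
    epochs_since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            raw = model.forward(Xtr[idx])
            loss, grad = _loss_and_grad(
                model, raw, mu_tr[idx],
                None if sg_tr is None else sg_tr[idx], config)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}", history)
            model.backward(grad)
            optimizer.step(scheduler.lr)
            epoch_loss += loss * len(idx)
        val_loss = _eval_loss(model, Xva, mu_va, sg_va, config)
        if not np.isfinite(val_loss):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}",
                                   history)
        history.train_loss.append(epoch_loss / len(order))
        history.val_loss.append(val_loss)
        history.learning_rate.append(scheduler.lr)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.early_stop_patience:
                history.stopped_early = True
                break
        scheduler.step(val_loss)
    model.set_state(best_state)
    return model, history


# -- hyperparameter search ---------------------------------------------

class TrialPruned(Exception):
    """Raised inside an objective (via report) to abandon the trial."""


@dataclass
class Trial:
    number: int
    params: dict
    value: float | None = None
    pruned: bool = False
    intermediate: list = field(default_factory=list)


def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "uniform":
            params[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "loguniform":
            params[name] = float(np.exp(rng.uniform(np.log(spec[1]),
                                                    np.log(spec[2]))))
        elif kind == "int":
            params[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "categorical":
            params[name] = spec[1][int(rng.integers(0, len(spec[1])))]
        else:
            raise ValueError(f"unknown parameter kind: {kind}")
    return params


def hyperparameter_search(space: dict, objective, budget: int = 25,
                          pruning: bool = True, seed: int = 0):
    """Seeded random search with intermediate-value (median) pruning.

    ``objective(params, report)`` returns the validation loss; it may
    call ``report(step, value)`` after each epoch, which raises
    :class:`TrialPruned` when the trial's intermediate loss is worse
    than the median intermediate loss of earlier trials at that step.
    Returns (best_params, best_value, trials).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    step_values: dict[int, list[float]] = {}
    for number in range(budget):
        trial = Trial(number=number, params=_sample_params(space, rng))

        def report(step: int, value: float, _trial=trial):
            _trial.intermediate.append((step, value))
            history = step_values.setdefault(step, [])
            if pruning and history and value > float(np.median(history)):
                history.append(value)
                raise TrialPruned
            history.append(value)

        try:
            trial.value = float(objective(trial.params, report))
        except TrialPruned:
            trial.pruned = True
        trials.append(trial)
    completed = [t for t in trials if not t.pruned]
    if not completed:
        raise RuntimeError("all trials pruned")
    best = min(completed, key=lambda t: t.value)
    return best.params, best.value, trials


def make_training_objective(dataset: ExpressionDataset, split: DataSplit,
                            spec: ModelSpec, base_config: TrainConfig):
    """Objective mapping sampled params (learning_rate, batch_size,
    lstm_hidden, n_filters, ...) onto a model training run; reports the
    per-epoch validation loss for pruning."""

    def objective(params: dict, report) -> float:
        cfg = replace(
            base_config,
            learning_rate=float(params.get("learning_rate",
                                           base_config.learning_rate)),
            batch_size=int(params.get("batch_size", base_config.batch_size)),
        )
        spec_kwargs = spec.to_dict()
        if "lstm_hidden" in params:
            spec_kwargs["lstm_hidden"] = int(params["lstm_hidden"])
        if "n_filters" in params:
            width = spec_kwargs["conv_blocks"][0][1]
            act = spec_kwargs["conv_blocks"][0][2]
            spec_kwargs["conv_blocks"] = tuple(
                (int(params["n_filters"]), width, act)
                for _ in spec_kwargs["conv_blocks"])
        if "mlp_hidden" in params:
            spec_kwargs["mlp_hidden"] = (int(params["mlp_hidden"]),)
        model = build_model(ModelSpec(**spec_kwargs), seed=cfg.seed)
        best = math.inf
        # per-epoch training so intermediate values can be reported
        cfg_one = replace(cfg, max_epochs=1, early_stop_patience=cfg.max_epochs + 1)
        scheduler = PlateauScheduler(cfg.learning_rate, cfg.scheduler)
        for epoch in range(cfg.max_epochs):
            cfg_epoch = replace(cfg_one, learning_rate=scheduler.lr,
                                seed=cfg.seed + epoch)
            model, hist = train(model, dataset, split, cfg_epoch)
            val = hist.val_loss[-1]
            best = min(best, val)
            scheduler.step(val)
            report(epoch, best)
        return best

    return objective


# -- scaling (data-efficiency) experiment -------------------------------

def log_spaced_sizes(n_max: int, n_points: int, n_min: int = 10) -> list[int]:
    """Geometrically spaced training-set sizes from n_min to n_max,
    rounded and de-duplicated."""
    sizes = np.geomspace(n_min, n_max, n_points)
    return sorted({int(round(s)) for s in sizes})


def scaling_experiment(dataset: ExpressionDataset, sizes, spec: ModelSpec,
                       config: TrainConfig, compositions=("random", "uniform"),
                       seeds=(3, 7, 13, 15, 16), test_ids=None,
                       test_frac: float = 0.2) -> pd.DataFrame:
    """Train from scratch on subsets of varying size and composition,
    evaluating every run on one fixed test set.

    Each (size, seed, composition) cell selects ``size`` examples from
    the non-test pool (random sampling or mu-uniform coverage), splits
    them 80/20 into train/validation, trains a fresh model and records
    the test MAPE alongside MSE, Spearman rho and the ratio of
    prediction to target spread (near zero in the constant-prediction
    regime).
    """
    from .evaluate import metrics

    if test_ids is None:
        holdout = stratified_split_for_test(dataset, test_frac=test_frac, seed=0)
        test_ids = holdout
    test_ids = list(test_ids)
    test_set = dataset.subset(test_ids)
    pool_ids = [i for i in dataset.ids if i not in set(test_ids)]
    pool = dataset.subset(pool_ids)
    test_seqs = list(test_set.frame["sequence"])
    test_mu = test_set.mu
    rows = []
    for composition in compositions:
        strategy = "random" if composition == "random" else "uniform_truth"
        for size in sizes:
            if size > len(pool):
                raise ValueError(f"size {size} exceeds available pool {len(pool)}")
            for seed in seeds:
                chosen = select_training_subset(pool, size, strategy=strategy,
                                                seed=seed)
                rng = np.random.default_rng(seed)
                chosen = list(np.asarray(chosen, dtype=object)[
                    rng.permutation(len(chosen))])
                n_train = max(int(round(0.8 * size)), 1)
                if n_train >= size:
                    n_train = size - 1
                split = DataSplit(train_ids=chosen[:n_train],
                                  val_ids=chosen[n_train:], test_ids=[])
                model = build_model(spec, seed=seed)
                cfg = replace(config, seed=seed)
                model, _ = train(model, dataset, split, cfg)
                X = encode_batch(test_seqs, spec.max_len)
                preds = model.predict_mu(X)
                rep = metrics(preds, test_mu)
                pred_sd = float(np.std(preds))
                target_sd = float(np.std(test_mu))
                rows.append({
                    "size": size, "seed": seed, "composition": composition,
                    "mape": rep.mape_log, "mse": rep.mse,
                    "spearman": rep.spearman_rho,
                    "pred_sd_ratio": pred_sd / target_sd if target_sd > 0
                    else np.nan,
                })
    return pd.DataFrame(rows)


def stratified_split_for_test(dataset: ExpressionDataset, test_frac: float = 0.2,
                              seed: int = 0) -> list:
    """Carve a stratified fixed test set; the remainder is the training
    pool used by the scaling and transfer experiments."""
    from .data import stratified_split
    split = stratified_split(dataset, ratios=(1 - test_frac, 0.0, test_frac),
                             seed=seed)
    return list(split.test_ids)
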