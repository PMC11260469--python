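"""Transfer-learning: fine-tuning procedures and the fine-tune-vs-scratch
benchmark.

Fine-tuning continues training of a pretrained network on a small
calibration set from a new context, with the published protocol: Adam,
learning rate 3e-5, batch size 32, up to 600 epochs, early stopping
with patience 80, and the same reduce-on-plateau schedule as
pre-training. ``mode='frozen_backbone'`` updates only the dense MLP
layers, keeping the convolutional and recurrent feature extractor
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import DataSplit, ExpressionDataset, select_training_subset
from .model import SequenceRegressor, build_model, encode_batch
from .train import SchedulerConfig, TrainConfig, TrainingHistory, train

CONSTANT_PREDICTION_SD_FRACTION = 0.01

__all__ = [
    "FinetuneConfig",
    "finetune",
    "freeze_backbone",
    "transfer_benchmark",
]


@dataclass(frozen=True)
class FinetuneConfig:
    learning_rate: float = 3e-5
    batch_size: int = 32
    max_epochs: int = 600
    early_stop_patience: int = 80
    scheduler: SchedulerConfig = field(default_factory=SchedulerConfig)
    mode: str = "full"            # full | frozen_backbone
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("full", "frozen_backbone"):
            raise ValueError(f"unknown fine-tuning mode: {self.mode}")
        if self.scheduler.min_lr > self.learning_rate:
            raise ValueError("min_lr must not exceed the learning rate")

    def to_train_config(self) -> TrainConfig:
        return TrainConfig(
            loss="mse", learning_rate=self.learning_rate,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            scheduler=self.scheduler, seed=self.seed)


def freeze_backbone(model: SequenceRegressor) -> SequenceRegressor:
    """Mark all conv/LSTM layers non-trainable; only the MLP learns."""
    return model.freeze_backbone()


def finetune(pretrained: SequenceRegressor, dataset: ExpressionDataset,
             split: DataSplit, config: FinetuneConfig | None = None
             ) -> tuple[SequenceRegressor, TrainingHistory]:
    """Fine-tune a copy of the pretrained model (copy-on-tune: the input
    model is never mutated) with the MSE-on-mu loss."""
    config = config or FinetuneConfig()
    if not split.train_ids:
        raise ValueError("empty calibration set")
    model = pretrained.copy()
    if config.mode == "frozen_backbone":
        freeze_backbone(model)
    return train(model, dataset, split, config.to_train_config())


def _evaluate(model: SequenceRegressor, test_set: ExpressionDataset):
    from .evaluate import metrics
    X = encode_batch(list(test_set.frame["sequence"]), model.spec.max_len)
    preds = model.predict_mu(X)
    rep = metrics(preds, test_set.mu)
    target_sd = float(np.std(test_set.mu))
    pred_sd = float(np.std(preds))
    constant = target_sd > 0 and pred_sd < CONSTANT_PREDICTION_SD_FRACTION * target_sd
    return rep, constant


def transfer_benchmark(pretrained: SequenceRegressor,
                       dataset: ExpressionDataset,
                       n_grid, seeds=(3, 7, 13, 15, 16),
                       finetune_config: FinetuneConfig | None = None,
                       scratch_config: TrainConfig | None = None,
                       selection: str = "random",
                       test_ids=None, val_frac: float = 0.2) -> pd.DataFrame:
    """Fine-tuned vs from-scratch comparison on one fixed test set.

    For every calibration size n and seed, n examples are drawn from
    the non-test pool (strategy ``selection``), split 80/20 into
    train/validation, and used both to fine-tune the pretrained model
    and to train a same-architecture model from random initialisation.
    n = 0 emits the zero-shot row (the pretrained model evaluated
    unchanged; no scratch arm). ``constant_prediction`` flags runs
    whose test-prediction spread is below 1% of the target spread.
    """
    from .train import stratified_split_for_test

    finetune_config = finetune_config or FinetuneConfig()
    # the scratch arm runs the same low-learning-rate protocol as the
    # fine-tuned arm, just from random initial weights
    scratch_config = scratch_config or finetune_config.to_train_config()
    if test_ids is None:
        test_ids = stratified_split_for_test(dataset, test_frac=0.2, seed=0)
    test_ids = list(test_ids)
    test_set = dataset.subset(test_ids)
    pool = dataset.subset([i for i in dataset.ids if i not in set(test_ids)])
    rows = []
    for n in n_grid:
        if n > len(pool):
            raise ValueError(f"n = {n} exceeds available pool {len(pool)}")
        for seed in seeds:
            if n == 0:
                rep, constant = _evaluate(pretrained, test_set)
                rows.append({"n": 0, "seed": seed, "arm": "finetuned",
                             "mape": rep.mape_log, "mse": rep.mse,
                             "spearman": rep.spearman_rho,
                             "constant_prediction": constant})
                continue
            chosen = select_training_subset(
                pool, n, strategy=selection,
                predictor=pretrained if selection == "uniform_predicted" else None,
                seed=seed)
            rng = np.random.default_rng(seed)
            chosen = list(np.asarray(chosen, dtype=object)[
                rng.permutation(len(chosen))])
            n_train = max(int(round((1 - val_frac) * n)), 1)
            if n_train >= n:
                n_train = n - 1
            split = DataSplit(train_ids=chosen[:n_train],
                              val_ids=chosen[n_train:], test_ids=[])
            ft_cfg = replace(finetune_config, seed=seed)
            tuned, _ = finetune(pretrained, dataset, split, ft_cfg)
            rep, constant = _evaluate(tuned, test_set)
            rows.append({"n": n, "seed": seed, "arm": "finetuned",
                         "mape": rep.mape_log, "mse": rep.mse,
                         "spearman": rep.spearman_rho,
                         "constant_prediction": constant})
            scratch = build_model(pretrained.spec, seed=seed)
            sc_cfg = replace(scratch_config, seed=seed)
            scratch, _ = train(scratch, dataset, split, sc_cfg)
            rep, constant = _evaluate(scratch, test_set)
            rows.append({"n": n, "seed": seed, "arm": "scratch",
                         "mape": rep.mape_log, "mse": rep.mse,
                         "spearman": rep.spearman_rho,
                         "constant_prediction": constant})
    return pd.DataFrame(rows)
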