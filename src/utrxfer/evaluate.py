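"""Metrics and uncertainty procedures for sequence-to-expression models.

MAPE is computed on log-fluorescence ("log") and on the exponentiated
fluorescence ("raw", using exp(mu), i.e. the geometric-mean
fluorescence); Spearman's rho uses average ranks on ties; the
four-category accuracy is agreement between the categorised prediction
and the categorised truth. Uncertainty comes from nonparametric
bootstrap (percentile CI) and from a paired sign-flip permutation test
of the improvement hypothesis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import StrengthCategories, categorize

MAPE_EPS = 1e-6

__all__ = [
    "EvaluationReport",
    "PermutationTestResult",
    "metrics",
    "bootstrap_se",
    "paired_permutation_test",
    "activity_cliff_report",
]


@dataclass
class EvaluationReport:
    n: int
    mse: float
    mae: float
    mape_log: float               # percent, on log-fluorescence
    mape_raw: float               # percent, on exp-scale fluorescence
    spearman_rho: float           # NaN when undefined (constant input)
    spearman_defined: bool
    category_accuracy: float      # NaN when no categories supplied
    ape: np.ndarray = field(repr=False, default=None)
    n_mape_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mse": self.mse, "mae": self.mae,
            "mape_log": self.mape_log, "mape_raw": self.mape_raw,
            "spearman_rho": self.spearman_rho,
            "category_accuracy": self.category_accuracy,
            "n_mape_excluded": self.n_mape_excluded,
        }

    def to_json(self, path) -> None:
        def clean(v):
            return None if isinstance(v, float) and not np.isfinite(v) else v
        with open(path, "w") as fh:
            json.dump({k: clean(v) for k, v in self.to_dict().items()}, fh,
                      indent=1)


@dataclass(frozen=True)
class PermutationTestResult:
    observed_statistic: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def metrics(predictions, targets,
            categories: StrengthCategories | None = None) -> EvaluationReport:
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets must have equal length")
    n = len(targets)
    if n == 0:
        raise ValueError("empty input")
    diff = predictions - targets
    mse = float(np.mean(diff ** 2))
    mae = float(np.mean(np.abs(diff)))
    ok = np.abs(targets) > MAPE_EPS
    ape = np.abs(diff[ok]) / np.abs(targets[ok]) * 100.0
    mape_log = float(np.mean(ape)) if ok.any() else float("nan")
    raw_t = np.exp(targets)
    raw_p = np.exp(predictions)
    mape_raw = float(np.mean(np.abs(raw_p - raw_t) / raw_t) * 100.0)
    if np.ptp(predictions) == 0 or np.ptp(targets) == 0 or n < 2:
        rho, defined = float("nan"), False
    else:
        rho = float(stats.spearmanr(predictions, targets).statistic)
        defined = np.isfinite(rho)
    if categories is not None:
        agree = [categorize(p, categories) == categorize(t, categories)
                 for p, t in zip(predictions, targets)]
        cat_acc = float(np.mean(agree))
    else:
        cat_acc = float("nan")
    return EvaluationReport(
        n=n, mse=mse, mae=mae, mape_log=mape_log, mape_raw=mape_raw,
        spearman_rho=rho, spearman_defined=defined,
        category_accuracy=cat_acc, ape=ape,
        n_mape_excluded=int(n - ok.sum()),
    )


def bootstrap_se(metric, data, B: int = 500, seed: int = 0,
                 ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Bootstrap SE and percentile CI of ``metric(resampled data)``.

    ``data`` is an (n, ...) array (or tuple of aligned arrays) resampled
    with replacement along the first axis.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if isinstance(data, tuple):
        arrays = [np.asarray(a) for a in data]
    else:
        arrays = [np.asarray(data)]
    n = len(arrays[0])
    if n < 2:
        raise ValueError("need at least 2 records")
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sample = tuple(a[idx] for a in arrays)
        values[b] = metric(*sample) if isinstance(data, tuple) \
            else metric(sample[0])
    alpha = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(values, alpha)),
          float(np.quantile(values, 1.0 - alpha)))
    return float(np.std(values)), ci


def paired_permutation_test(errors_before, errors_after,
                            n_permutations: int = 10_000,
                            seed: int = 0) -> PermutationTestResult:
    """One-sided paired sign-flip test of H0: no improvement.

    Statistic: mean(errors_before - errors_after). The null flips the
    sign of each paired difference independently. All 2^n assignments
    are enumerated when 2^n <= n_permutations (exact p = #{>= obs}/2^n);
    otherwise random flips with the add-one rule
    p = (1 + #{>= obs}) / (n_permutations + 1).
    """
    before = np.asarray(errors_before, dtype=float)
    after = np.asarray(errors_after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("paired vectors must have equal length")
    n = len(before)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = before - after
    observed = float(np.mean(d))
    if n <= 30 and 2 ** n <= n_permutations:
        codes = np.arange(2 ** n, dtype=np.int64)[:, None]
        signs = ((codes >> np.arange(n)) & 1) * 2.0 - 1.0
        null = signs @ d / n
        count = int(np.sum(null >= observed - 1e-12))
        p = count / len(null)
        return PermutationTestResult(observed, float(p), len(null), True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        flip = rng.integers(0, 2, size=n) * 2 - 1
        if np.mean(flip * d) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PermutationTestResult(observed, float(p), n_permutations, False)


def activity_cliff_report(model, pairs, dataset) -> dict:
    """Single-base-resolution check on activity-cliff pairs.

    Returns the fraction of pairs whose predicted ordering is correct
    (mu_hat_strong > mu_hat_weak; ties count as incorrect), the MAPE
    computed separately over the weak and strong members, and summary
    statistics of the predicted strong/weak ratio on the raw (exp)
    fluorescence scale.
    """
    from .model import predict_mean

    if not pairs:
        raise ValueError("empty pair list")
    seq_by_id = dict(zip(dataset.frame["id"], dataset.frame["sequence"]))
    mu_by_id = dict(zip(dataset.frame["id"], dataset.frame["mu"]))
    ids = sorted({p.id_weak for p in pairs} | {p.id_strong for p in pairs})
    seqs = [seq_by_id[i] for i in ids]
    if hasattr(model, "spec"):
        preds = predict_mean(model, seqs, ids=ids)
        mu_hat = {p.variant_id: p.mu_hat for p in preds}
    else:
        # any callable mapping a list of sequences to predicted mu values
        mu_hat = dict(zip(ids, np.asarray(model(seqs), dtype=float)))
    correct = [mu_hat[p.id_strong] > mu_hat[p.id_weak] for p in pairs]
    ratios = [float(np.exp(mu_hat[p.id_strong] - mu_hat[p.id_weak]))
              for p in pairs]
    weak_ids = sorted({p.id_weak for p in pairs})
    strong_ids = sorted({p.id_strong for p in pairs})
    weak_rep = metrics([mu_hat[i] for i in weak_ids],
                       [mu_by_id[i] for i in weak_ids])
    strong_rep = metrics([mu_hat[i] for i in strong_ids],
                         [mu_by_id[i] for i in strong_ids])
    return {
        "n_pairs": len(pairs),
        "ordering_correct_fraction": float(np.mean(correct)),
        "ratio_median": float(np.median(ratios)),
        "ratio_max": float(np.max(ratios)),
        "mape_weak": weak_rep.mape_log,
        "mape_strong": strong_rep.mape_log,
    }
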