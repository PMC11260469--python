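"""Canonical packaged simulation studies.

These functions assemble the package's end-to-end experiments at desk
scale: inference-precision recovery, the data-efficiency (learning
curve) study, the cross-context transfer study and the statistical
calibration checks. The ground-truth mapping is the fixed study object
returned by :func:`utrxfer.synthetic.make_study_ground_truth`; the
``seed`` argument drives every other source of randomness (library
sampling, Flow-seq simulation, splits, weight initialisation, training
shuffles, bootstrap and permutation draws).

Problem sizes (5000-variant pre-training library, 1500-variant new
context, calibration sizes up to 200, five training seeds) are the
package's CPU-scale rendering of the corresponding full-size
experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .data import DataSplit, stratified_split
from .evaluate import bootstrap_se, metrics, paired_permutation_test
from .flowseq import (BinnedReadCounts, bin_log_likelihood, dataset_precision,
                      infer_lognormal_mle, lognormal_bin_probs, quality_filter)
from .model import SMALL_CNN_LSTM_SPEC, build_model, encode_batch
from .synthetic import (DEFAULT_BIN_EDGES, LibrarySpec, make_study_ground_truth,
                        sample_library, simulate_flowseq)
from .train import (TrainConfig, scaling_experiment, small_study_config,
                    stratified_split_for_test, train)
from .transfer import FinetuneConfig, transfer_benchmark

TRAINING_SEEDS = (3, 7, 13, 15, 16)

__all__ = [
    "mle_recovery_study",
    "pretrain_model",
    "scaling_study",
    "transfer_study",
    "stats_calibration_study",
    "closed_form_checks",
]


def mle_recovery_study(seed: int = 0) -> dict:
    """Recover LogNormal(5, 1) from one simulated sort-seq variant:
    1e5 cells, 1e4 reads, 8 log-uniform bins on [10, 1e5]."""
    mu_true, sigma_true = 5.0, 1.0
    rng = np.random.default_rng(seed)
    logf = rng.normal(mu_true, sigma_true, 100_000)
    edges = DEFAULT_BIN_EDGES
    idx = np.clip(np.searchsorted(np.log(edges)[1:-1], logf, side="right"),
                  0, len(edges) - 2)
    cells = np.bincount(idx, minlength=len(edges) - 1)
    reads = rng.multinomial(10_000, cells / cells.sum())
    est = infer_lognormal_mle(BinnedReadCounts("recovery", reads, edges))
    return {
        "mu_true": mu_true, "sigma_true": sigma_true,
        "mu_hat": est.mu, "sigma_hat": est.sigma,
        "mu_abs_error": abs(est.mu - mu_true),
        "sigma_abs_error": abs(est.sigma - sigma_true),
        "ci_width": est.ci_mu_997[1] - est.ci_mu_997[0],
        "converged": est.converged,
        "hessian_invertible": est.hessian_invertible,
    }


def library_precision_study(seed: int = 0, n_variants: int = 200,
                            n_cells: int = 1000, n_reads: int = 20_000) -> dict:
    """Library-level inference quality under default simulator settings."""
    gt = make_study_ground_truth()
    lib = sample_library(gt, LibrarySpec(n_variants=n_variants), "A",
                         seed=seed + 1)
    counts = simulate_flowseq(gt, lib, n_cells, n_reads, seed=seed + 2)
    estimates = [infer_lognormal_mle(c) for c in counts if c.total_reads > 0]
    kept = quality_filter(estimates)
    mu_true = dict(zip(lib.frame["id"], lib.mu))
    errors = [abs(e.mu - mu_true[e.variant_id]) for e in kept]
    return {
        "n_variants": n_variants,
        "fraction_kept": len(kept) / len(estimates),
        "median_ci_width": dataset_precision(kept),
        "median_mu_abs_error": float(np.median(errors)),
    }


def pretrain_model(seed: int = 0, n_variants: int = 5000):
    """Train the study CNN-LSTM on the pre-training context "A"."""
    gt = make_study_ground_truth()
    lib = sample_library(gt, LibrarySpec(n_variants=n_variants), "A",
                         seed=seed + 1)
    split = stratified_split(lib, seed=seed)
    model = build_model(SMALL_CNN_LSTM_SPEC, seed=seed)
    model, history = train(model, lib, split, small_study_config(seed=seed))
    test = lib.subset(split.test_ids)
    X = encode_batch(list(test.frame["sequence"]), model.spec.max_len)
    report = metrics(model.predict_mu(X), test.mu)
    return model, lib, split, report


def scaling_study(seed: int = 0, n_variants: int = 5000,
                  sizes=(10, 38, 141, 532, 2000),
                  seeds=TRAINING_SEEDS) -> tuple[pd.DataFrame, float]:
    """Learning-curve study: train from scratch at log-spaced sizes with
    random vs mu-uniform training-set composition, against one fixed
    stratified test set; returns the grid and the constant-mean
    baseline MAPE on that test set."""
    gt = make_study_ground_truth()
    lib = sample_library(gt, LibrarySpec(n_variants=n_variants), "A",
                         seed=seed + 1)
    test_ids = stratified_split_for_test(lib, test_frac=0.2, seed=seed)
    test = lib.subset(test_ids)
    pool = lib.subset([i for i in lib.ids if i not in set(test_ids)])
    baseline = metrics(np.full(len(test), pool.mu.mean()), test.mu).mape_log
    table = scaling_experiment(lib, list(sizes), SMALL_CNN_LSTM_SPEC,
                               small_study_config(), seeds=seeds,
                               test_ids=test_ids)
    return table, float(baseline)


def transfer_study(seed: int = 0, n_grid=(0, 90, 200),
                   seeds=TRAINING_SEEDS) -> pd.DataFrame:
    """Cross-context transfer: pre-train on context "A", then compare
    fine-tuning against same-architecture scratch training on the
    shifted context "B" across calibration sizes."""
    gt = make_study_ground_truth()
    pretrained, _, _, _ = pretrain_model(seed=seed)
    lib_b = sample_library(gt, LibrarySpec(n_variants=1500), "B",
                           seed=seed + 5)
    return transfer_benchmark(pretrained, lib_b, list(n_grid), seeds=seeds,
                              finetune_config=FinetuneConfig())


def stats_calibration_study(seed: int = 0, n_null_tests: int = 1000) -> dict:
    """Calibration of the uncertainty machinery: the exhaustive 3-pair
    permutation case, type-I error under an exchangeable null, and the
    bootstrap SE of a mean against the analytic s/sqrt(n)."""
    three_pair = paired_permutation_test([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    rejections = 0
    for t in range(n_null_tests):
        before = rng.normal(0, 1, 12)
        after = rng.normal(0, 1, 12)
        res = paired_permutation_test(before, after, n_permutations=4096,
                                      seed=seed + t)
        if res.p_value <= 0.05:
            rejections += 1
    data = np.random.default_rng(seed + 1).normal(0, 1, 100)
    se, _ = bootstrap_se(np.mean, data, B=500, seed=seed + 2)
    analytic = float(np.std(data, ddof=1) / np.sqrt(len(data)))
    return {
        "three_pair_p": three_pair.p_value,
        "type1_rate": rejections / n_null_tests,
        "bootstrap_se_mean": float(se),
        "analytic_se_mean": analytic,
        "bootstrap_se_rel_error": abs(se - analytic) / analytic,
    }


def closed_form_checks(seed: int = 0, n_pairs: int = 20) -> dict:
    """Numerical agreement checks: log-normal KL against quadrature and
    conditioned bin-probability normalisation."""
    from .train import lognormal_kl

    rng = np.random.default_rng(seed)
    worst_kl = 0.0
    for _ in range(n_pairs):
        mu1, mu2 = rng.normal(0, 2, 2)
        s1, s2 = rng.uniform(0.2, 2.0, 2)
        p = stats.norm(mu1, s1)
        q = stats.norm(mu2, s2)
        quad, _ = integrate.quad(
            lambda x: p.pdf(x) * (p.logpdf(x) - q.logpdf(x)),
            mu1 - 12 * s1, mu1 + 12 * s1, limit=200)
        worst_kl = max(worst_kl, abs(lognormal_kl((mu1, s1), (mu2, s2)) - quad))
    self_kl = lognormal_kl((1.3, 0.7), (1.3, 0.7))
    worst_norm = 0.0
    for _ in range(50):
        mu = rng.uniform(2.5, 11.0)
        sigma = rng.uniform(0.1, 2.0)
        probs = lognormal_bin_probs(mu, sigma, DEFAULT_BIN_EDGES)
        worst_norm = max(worst_norm, abs(probs.sum() - 1.0))
    return {
        "kl_vs_quadrature_max_abs_dev": float(worst_kl),
        "kl_self_divergence": float(self_kl),
        "bin_prob_sum_max_abs_dev": float(worst_norm),
    }
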