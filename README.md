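# utrxfer

Predicting protein expression from bacterial 5'UTR sequence, and
adapting those predictions across genetic and experimental contexts
with transfer learning.

Massively parallel reporter assays such as Flow-seq sort a library of
5'UTR variants into fluorescence bins and sequence each bin, yielding
per-variant read counts over bins. Modelling each variant's cell
fluorescence as LogNormal(μ, σ), `utrxfer` infers (μ, σ) per variant by
maximum likelihood over the binned counts, trains a CNN-LSTM regression
network to predict μ (mean log-fluorescence) from the one-hot encoded
5'UTR sequence, and calibrates a pre-trained network to a *new* context
— different flanking sequence, promoter, sorter or fluorescence units —
by fine-tuning on a small number of new measurements. It is aimed at
synthetic biologists who want model-guided ribosome-binding-site design
without re-measuring tens of thousands of variants per context.

Everything is exercisable offline: a built-in simulator generates
ground-truth sequence→expression mappings (an anti-Shine-Dalgarno-like
motif score with spacing and secondary-structure penalties, plus
per-context affine shifts and motif perturbations), draws log-normal
cell fluorescence, sorts cells into 6–12 bins (last edge 10⁵) and
samples multinomial sequencing reads.

## The model

For bin edges e₀ < e₁ < … < e_B, a sorted cell from LogNormal(μ, σ)
lands in bin j with probability (conditioned on the covered range)

    p_j(μ, σ) = [Φ((ln e_j − μ)/σ) − Φ((ln e_{j−1} − μ)/σ)]
                / [Φ((ln e_B − μ)/σ) − Φ((ln e_0 − μ)/σ)]

and the per-variant read counts c₁…c_B contribute the multinomial
log-likelihood Σ_j c_j ln p_j. The MLE runs quasi-Newton on (μ, ln σ)
with a 99.7% interval μ̂ ± 3·SE from the inverse observed information;
variants sorted into a single bin or with an ill-conditioned Hessian
are filtered out.

The regression network is one-hot input → stacked 1-D convolutions →
LSTM over the (steps × features) matrix → flatten → MLP → μ̂ (optionally
(μ̂, σ̂) trained with the KL divergence between log-normals). Training
uses Adam, mini-batches, a reduce-on-plateau schedule (factor 0.5,
patience 3, relative threshold 1%, min lr 10⁻⁵) and early stopping.
Fine-tuning continues training at learning rate 3×10⁻⁵ (batch 32, up to
600 epochs, patience 80), either updating all weights or only the MLP
("frozen backbone").

## Worked example

```python
from utrxfer.synthetic import (make_study_ground_truth, sample_library,
                               simulate_flowseq, LibrarySpec)
from utrxfer.flowseq import infer_lognormal_mle, quality_filter, dataset_precision

gt = make_study_ground_truth()
lib = sample_library(gt, LibrarySpec(n_variants=200), "A", seed=2)
counts = simulate_flowseq(gt, lib, n_cells_per_variant=1000,
                          n_reads_total=20_000, seed=3)
estimates = quality_filter([infer_lognormal_mle(c) for c in counts
                            if c.total_reads > 0])
print(f"{len(estimates)}/200 variants pass the quality filter")
print(f"median 99.7% CI width: {dataset_precision(estimates):.3f}")
```

prints

```
190/200 variants pass the quality filter
median 99.7% CI width: 0.341
```

i.e. 95% of the library is sorted into multiple bins with an
identifiable optimum, and the median μ̂ is pinned down to ±0.17 natural-log
units at this depth (doubling the reads shrinks the width by ≈1/√2).

The same objects feed the learning experiments: `utrxfer.studies.
pretrain_model` trains the study CNN-LSTM on a 5000-variant library
(test MAPE ≈ 7%, Spearman ρ ≈ 0.98 against the noise-free truth), and
`utrxfer.studies.transfer_study` fine-tunes it on a context with
rescaled units and perturbed motif weights — zero-shot MAPE ≈ 98%
drops to ≈ 10% after 90 calibration examples, while a same-architecture
network trained from scratch on those 90 examples stays at ≈ 22%.

A command-line interface mirrors the library:

```bash
utrxfer simulate --n-variants 500 --seed 1 --out runs/sim
utrxfer infer --counts runs/sim/counts.tsv --edges runs/sim/edges.json \
              --out runs/estimates.tsv
utrxfer run pipeline.yaml        # multi-stage config-driven run
```

## Layout

| module | contents |
| --- | --- |
| `utrxfer.synthetic` | ground-truth mappings, library designs, Flow-seq simulator |
| `utrxfer.flowseq` | binned log-normal MLE, quality filters, precision summaries |
| `utrxfer.data` | dataset container, splits, strength categories, activity cliffs |
| `utrxfer.model` | one-hot encoding, CNN/LSTM/CNN-LSTM architectures |
| `utrxfer.train` | losses, plateau schedule, training, search, scaling study |
| `utrxfer.transfer` | fine-tuning (full / frozen backbone), transfer benchmark |
| `utrxfer.evaluate` | metrics, bootstrap, paired permutation test, cliff report |
| `utrxfer.pipeline` / `utrxfer.cli` | config-driven orchestration, `utrxfer` CLI |

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
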