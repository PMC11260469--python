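# Methods

## Scope and data model

The package treats a sort-seq (Flow-seq) experiment as the primary
observable: per 5'UTR variant, read counts over B ordered fluorescence
bins with strictly increasing positive edges e₀ < … < e_B (default: 8
log-uniform bins on [10, 10⁵]; the last edge defaults to 10⁵,
matching the usual ceiling of FACS fluorescence channels). Cell
fluorescence per variant is modelled as log-normal; the mean μ of
log-fluorescence is the quantity the sequence models predict, and the
arbitrary-unit scale is carried as a units tag because different
experiments (sorters, reporters) report incompatible scales.

## Binned maximum-likelihood inference

Reads are modelled as a multinomial over bins with probabilities
proportional to the log-normal mass in each bin, *conditioned on the
covered range* [e₀, e_B]:

p_j = [Φ((ln e_j − μ)/σ) − Φ((ln e_{j−1} − μ)/σ)] / [Φ((ln e_B − μ)/σ) − Φ((ln e₀ − μ)/σ)].

Conditioning rather than modelling tail loss is deliberate: a FACS gate
observes sorted cells only, and it makes the single-bin case exactly
non-identifiable (p₁ ≡ 1 regardless of (μ, σ)), which is what the
"sorted into multiple bins" quality filter removes. Reads are weighted
directly; cells-per-bin weighting is not modelled because bin-level
sort counts are usually unavailable in deposited data. PCR jackpotting
(read overdispersion) is not modelled.

Optimisation is a deterministic Nelder-Mead simplex search over
(μ, ln σ) (the log-parameterisation enforcing σ > 0; derivative-free,
because finite-difference gradients are fragile on the flat
single-bin ridges of this likelihood) from a start given
by read-weighted moments of the log bin midpoints, so inference is a
pure function of the counts. The observed information is a
finite-difference Hessian of the negative log-likelihood at the
optimum; "invertible" means positive eigenvalues with condition number
below 10⁸ (no threshold is standard; 10⁸ separates the flat ridges of
one-bin and far-outside-range fits from informative fits in practice).
The 99.7% interval is μ̂ ± 3·SE — the ±3σ normal convention. Dataset
precision is summarised by the *median* CI width because a minority of
two-bin variants produce abnormally wide intervals; the same median
over 3·SE/|μ̂| (as a percentage) gives the measurement-noise floor on
the MAPE of any downstream predictor.

## Synthetic ground truth

The simulator's sequence→expression family is a caricature of
prokaryotic translation initiation, not a fitted model:

* a position-specific score matrix (default width 6, weights ~
  N(0, 4²)) rewards an anti-SD-like motif at its best placement;
* a quadratic penalty (0.4 per nt²) on the distance between the motif
  3' end and the start codon, optimum 5 nt, encodes spacing preference;
* a self-complementarity score (max Watson-Crick matches between the
  sequence and its reverse over all offsets, weight 0.3) is a cheap
  hairpin proxy — deliberately not a thermodynamic folding model;
* each context applies scale·μ + offset and optionally a perturbation
  of the motif weights, emulating flanking-sequence and unit changes.

Defaults were calibrated once so the default mapping's 1–99% μ range
(≈ 1.9–12.1 natural-log units) matches the span typical of a
well-resolved Flow-seq library, and σ = 0.4 per variant; at those
settings ≥ 95% of variants occupy ≥ 2 bins, so the downstream quality
filter keeps most of the library. `make_study_ground_truth()` freezes
the two-context study mapping: context "A" for pre-training, context
"B" compressed and shifted (scale 0.4, offset +1.2 — a narrow
2–6-unit target range, the signature of a different sorter/reporter)
with motif perturbation s.d. 0.5.

The simulator samples i.i.d. log-normal cells, clamps cells outside
the bin range into the first/last bin (a gate sorts every cell
somewhere; this keeps read conservation exact), and draws all reads in
one multinomial over (variant, bin) cells — equivalent to allocating
depth to bins proportional to sorted cells, with a `depth_skew` knob
for uneven per-bin sequencing. What it does *not* emulate: sorting
errors at bin boundaries, read overdispersion, growth/burden effects,
codon-level CDS interactions, real RNA thermodynamics. Passing tests
therefore demonstrate the pipeline's statistical machinery, not
biological realism.

## Sequence models

Sequences are one-hot encoded (channels A, C, G, T; ambiguity codes
rejected since the studied libraries are unambiguous) and
*right-aligned* to the 3' end with 5' zero padding: initiation
determinants are positioned relative to the start codon, and libraries
differ in 5' length. The architecture is conv blocks → LSTM over the
(steps × features) matrix → flatten → MLP. Two heads: μ̂ only (MSE
loss) or (μ̂, σ̂) trained with the KL divergence between log-normals
KL(N(μ,σ) ‖ N(μ̂,σ̂)) = ln(σ̂/σ) + (σ² + (μ−μ̂)²)/(2σ̂²) − ½; the
direction (truth ‖ prediction) is configurable because the defining
phrase is directionally ambiguous in common usage. σ̂ positivity uses
softplus + 10⁻³ floor.

The engine is pure NumPy (float64, manual backprop, Adam), which keeps
runs bit-reproducible on one CPU under a fixed seed; gradients are
verified against central finite differences in the test suite.

Two reference architectures are shipped. The full-scale pair renders
the canonical parameter budgets — CNN-LSTM: three conv
blocks of 128×7, LSTM 128, a single intermediate MLP layer of 192
(1.10×10⁶ parameters); CNN: three blocks of 256×7, MLP 1024
(8.79×10⁶) — an ≈8× efficiency gap in favour of the recurrent model.
These are reference reconstructions anchored to those parameter
totals and the single-intermediate-layer design fact, not the product
of a hyperparameter search at that scale. The *study* architecture used by all simulations is
CPU-sized: two conv blocks of 24×5, LSTM 24, MLP 48 (~33k parameters),
with learning rate 3×10⁻³; both were fixed by a small validation-loss
sweep on the default synthetic library, mirroring the role
hyperparameter search plays at full scale.

## Training protocols

Pre-training: Adam, batch 32, max 20 epochs, early stopping patience 5
on validation loss with best-epoch weight restoration (the returned
model should match the monitored criterion), reduce-on-plateau
schedule (mode min, factor 0.5, patience 3, threshold 1% *relative*,
min lr 10⁻⁵). Fine-tuning: the same schedule at learning rate 3×10⁻⁵,
batch 32, max 600 epochs, patience 80; `full` mode updates every
parameter, `frozen_backbone` only the MLP. Fine-tuning always operates
on a copy (copy-on-tune), so a pretrained model is never mutated.

Hyperparameter search is a seeded random sampler over typed parameter
ranges with intermediate-value pruning (a trial reporting a per-epoch
validation loss above the median of earlier trials at the same epoch
is abandoned). Random search is a strong baseline at desk-scale
budgets (default 25 trials) and keeps the search fully deterministic
under a seed.

## Packaged studies and problem sizes

`utrxfer.studies` freezes the simulation studies at CPU scale:

* **MLE recovery**: LogNormal(5, 1), 10⁵ cells, 10⁴ reads, 8 bins;
  μ recovered within 0.05 and σ within 0.1.
* **Learning curve**: 5000-variant library, fixed stratified 20% test
  set, training sizes {10, 38, 141, 532, 2000} (log-spaced from 10),
  each size split 80/20 train/validation, seeds {3, 7, 13, 15, 16},
  random vs μ-uniform composition. At n = 10 the network predicts a
  near-constant (prediction SD < 10% of target SD); the MAPE falls
  below half the constant-mean baseline by n ≈ 500 (uniform) and the
  uniform composition never transitions later than random — the
  balanced training set moves the phase transition earlier.
* **Transfer**: pre-train on context "A", evaluate on context "B".
  The scratch arm trains the same architecture from random weights
  with the *same* 600-epoch fine-tuning protocol, because that is the
  matched comparison for "fine-tuning vs random initialisation";
  re-running it with the 20-epoch pre-training protocol instead lets
  the scratch model jump to the target mean and blurs the comparison.
  A run is flagged `constant_prediction` when its test-prediction SD
  is below 1% of the target SD (the flag's threshold is this
  package's own convention).
* **Statistics calibration**: exhaustive 3-pair permutation case
  (p = 1/8), type-I error at α = 0.05 within (0.03, 0.07) over 1000
  null simulations, bootstrap SE of a mean within 20% of s/√n.

## Evaluation conventions

MAPE is reported on log-fluorescence and on exp(μ) ("raw"); exp(μ) is
the geometric-mean fluorescence — the log-normal mean exp(μ + σ²/2)
would need a σ estimate that deposited datasets often lack. Targets
with |μ| ≤ 10⁻⁶ are excluded from MAPE and counted. Spearman ρ uses
average ranks; constant inputs yield a flagged missing value.
Four-category strength accuracy divides the 1st–99th percentile μ
range into four equal classes (weak … strong); boundary values go to
the upper class, and values outside the range clamp to the extreme
classes. The alternative "within one margin of truth" reading of
category accuracy is available via the category width. Activity-cliff
pairs are equal-length sequences at Hamming distance exactly 1 with
one member below the weak threshold (default 3) and one above the
strong threshold (default 6); prediction ties count as incorrect
ordering.

The paired permutation test uses the mean paired difference of errors
as its statistic and independent sign flips as the null; all 2ⁿ
assignments are enumerated when 2ⁿ fits in the permutation budget
(exact p = #{≥ obs}/2ⁿ), otherwise Monte-Carlo flips use the add-one
rule (1 + #{≥ obs})/(n_perm + 1), so p can never be 0 and is bounded
below by 1/(n_perm + 1). The bootstrap reports the SD of B = 500
resampled metric values and a 2.5–97.5% percentile interval.

## Reproducibility

Every operation is a pure function of (inputs, seed); the pipeline
fans a single global seed out as seed + stage index so stages can be
re-run in isolation, and each stage writes a manifest with the config
hash and seed. Training is bit-reproducible on one CPU. The studies'
ground-truth mapping is a fixed, named object — the synthetic analogue
of "the dataset" — while the experiment seed drives library sampling,
simulation, splits, initialisation and resampling.

## Known limitations

* The ground-truth family is an explicit stand-in; nothing validates
  it against real translation-initiation biology, and conclusions
  about *data requirements* (transition sizes, calibration set sizes)
  scale with the ~33k-parameter study model, not with a
  million-parameter network. In particular, at this model scale the
  fixed 3×10⁻⁵ fine-tuning rate cannot repair a large pure additive
  offset within the 600-epoch budget (aggregate parameter movement
  scales with parameter count); the packaged transfer study therefore
  uses a rescaled-units context, where fine-tuning is highly
  effective.
* σ̂ prediction is exposed (KL head) but, as with real Flow-seq data,
  binned experiments carry little information about higher moments;
  the packaged studies predict μ only.
* No Bayesian posterior over (μ, σ); no per-bin sorting-error model;
  no external thermodynamic predictors.
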