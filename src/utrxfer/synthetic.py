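"""Synthetic ground truth, variant libraries and simulated Flow-seq data.

A synthetic sequence->expression function stands in for the unknown
biology a real sort-seq experiment probes, so every downstream stage
(MLE preprocessing, model training, transfer learning, evaluation) can
be exercised without any external download. The generative family is a
deliberately simple caricature of prokaryotic translation initiation:

* a position-specific score matrix rewards an anti-SD-like motif,
* a quadratic penalty on the distance between the motif 3' end and the
  start codon models spacing preference,
* a cheap self-complementarity score penalises hairpin-prone 5'UTRs,
* each genetic/experimental context applies an affine change
  (offset + scale) and optionally perturbs the motif weights, emulating
  context-dependent shifts in the mapping.

Per-variant cell fluorescence is log-normal; a simulated sorter assigns
cells to 6-12 fluorescence bins (last edge 1e5 by default) and
sequencing reads are drawn multinomially in proportion to each
variant's sorted-cell share of each bin.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .flowseq import BinnedReadCounts

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_BIN_EDGES = np.geomspace(10.0, 1e5, 9)  # 8 log-uniform bins


@dataclass(frozen=True)
class ContextEffect:
    offset: float = 0.0
    scale: float = 1.0
    motif_perturbation: np.ndarray | None = None

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("context_scale must be positive")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    motif_weights: np.ndarray            # (width, 4) energy-like scores
    optimal_spacing: int                 # nt between motif 3' end and start codon
    spacing_penalty: float               # per-nt^2 quadratic penalty
    structure_penalty: float             # weight on the self-complementarity score
    contexts: dict                       # context id -> ContextEffect
    noise_sigma: float                   # per-variant cell-to-cell sigma (ln scale)
    sigma_slope: float                   # optional linear mu-dependence of sigma
    rng_seed: int

    def __post_init__(self):
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if not np.all(np.isfinite(self.motif_weights)):
            raise ValueError("motif_weights must be finite")
        if not self.contexts:
            raise ValueError("at least one context is required")

    @property
    def motif_width(self) -> int:
        return self.motif_weights.shape[0]


@dataclass(frozen=True)
class LibrarySpec:
    fixed_prefix: str = "GGCT"
    variable_length: int = 9
    fixed_suffix: str = "TATCAC"    # ends at the start codon
    n_variants: int = 100
    design: str = "random"          # random | exhaustive | single-mutant-neighborhood

    def __post_init__(self):
        for part in (self.fixed_prefix, self.fixed_suffix):
            if any(b not in ALPHABET for b in part):
                raise ValueError("fixed regions must be over {A,C,G,T}")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.design not in ("random", "exhaustive", "single-mutant-neighborhood"):
            raise ValueError(f"unknown design: {self.design}")


def make_ground_truth(
    contexts,
    seed: int = 0,
    motif_width: int = 6,
    motif_scale: float = 4.0,
    optimal_spacing: int = 5,
    spacing_penalty: float = 0.4,
    structure_penalty: float = 0.3,
    noise_sigma: float = 0.4,
    sigma_slope: float = 0.0,
    context_offsets=None,
    context_scales=None,
    context_perturbations=None,
) -> SyntheticGroundTruth:
    """Draw a ground-truth mapping, deterministic in ``seed``.

    ``context_offsets`` / ``context_scales`` map context ids to the
    affine change each context applies; ``context_perturbations`` maps
    context ids either to an explicit (width, 4) array or to a scalar
    s.d. from which a perturbation matrix is drawn (seeded).
    """
    contexts = list(contexts)
    if not contexts:
        raise ValueError("at least one context is required")
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.0, motif_scale, size=(motif_width, 4))
    context_offsets = dict(context_offsets or {})
    context_scales = dict(context_scales or {})
    context_perturbations = dict(context_perturbations or {})
    effects = {}
    for ctx in contexts:
        pert = context_perturbations.get(ctx)
        if pert is None:
            pert_arr = None
        elif np.isscalar(pert):
            pert_arr = rng.normal(0.0, float(pert), size=(motif_width, 4))
        else:
            pert_arr = np.asarray(pert, dtype=float)
            if pert_arr.shape != (motif_width, 4):
                raise ValueError("perturbation shape must match motif_weights")
        effects[ctx] = ContextEffect(
            offset=float(context_offsets.get(ctx, 0.0)),
            scale=float(context_scales.get(ctx, 1.0)),
            motif_perturbation=pert_arr,
        )
    return SyntheticGroundTruth(
        motif_weights=weights,
        optimal_spacing=optimal_spacing,
        spacing_penalty=spacing_penalty,
        structure_penalty=structure_penalty,
        contexts=effects,
        noise_sigma=noise_sigma,
        sigma_slope=sigma_slope,
        rng_seed=seed,
    )


def make_study_ground_truth(seed: int = 1) -> SyntheticGroundTruth:
    """The two-context mapping used by the packaged simulation studies.

    Context "A" is the pre-training context (a well-resolved library
    whose mean log-fluorescence spans roughly 2-12). Context "B" emulates a new genetic
    and experimental context in the style of a 6-nt SD library measured
    on a different sorter: the mapping is compressed and shifted
    (scale 0.4, offset +1.2, giving a narrow target interval around
    2-6 in new arbitrary units) and the motif weights are perturbed
    (s.d. 0.5), so a model pre-trained on "A" ranks "B" variants well
    but is far off in absolute terms until calibrated.
    """
    return make_ground_truth(
        ["A", "B"], seed=seed,
        context_offsets={"B": 1.2},
        context_scales={"B": 0.4},
        context_perturbations={"B": 0.5},
    )


def selfcomp(sequence: str) -> int:
    """Cheap hairpin proxy: maximum number of Watson-Crick complementary
    position pairs between the sequence and its own reverse, over all
    alignment offsets."""
    n = len(sequence)
    rev = sequence[::-1]
    best = 0
    for shift in range(-(n - 1), n):
        count = 0
        for i in range(n):
            j = i + shift
            if 0 <= j < n and _COMPLEMENT[sequence[i]] == rev[j]:
                count += 1
        best = max(best, count)
    return best


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc.args[0]!r} in sequence") from None


def true_expression(gt: SyntheticGroundTruth, sequence: str, context) -> tuple[float, float]:
    """Noise-free (mu, sigma) of the log-normal fluorescence of a variant."""
    if context not in gt.contexts:
        raise KeyError(f"unknown context: {context!r}")
    eff = gt.contexts[context]
    idx = _encode(sequence)
    w = gt.motif_width
    L = len(sequence)
    if L < w:
        raise ValueError("sequence shorter than the motif")
    weights = gt.motif_weights
    if eff.motif_perturbation is not None:
        weights = weights + eff.motif_perturbation
    best = -np.inf
    for p in range(L - w + 1):
        score = float(weights[np.arange(w), idx[p:p + w]].sum())
        spacing = L - (p + w)
        score -= gt.spacing_penalty * (spacing - gt.optimal_spacing) ** 2
        best = max(best, score)
    mu_raw = best - gt.structure_penalty * selfcomp(sequence)
    mu = eff.scale * mu_raw + eff.offset
    sigma = gt.noise_sigma + gt.sigma_slope * abs(mu)
    return float(mu), float(max(sigma, 1e-3))


def _random_unique_kmers(rng: np.random.Generator, k: int, n: int) -> list[str]:
    if 4 ** k < n:
        raise ValueError(f"cannot draw {n} unique {k}-mers")
    seen: dict[str, None] = {}
    while len(seen) < n:
        draw = rng.integers(0, 4, size=(max(n - len(seen), 1), k))
        for row in draw:
            seen.setdefault("".join(ALPHABET[i] for i in row), None)
            if len(seen) == n:
                break
    return list(seen)


def _variable_regions(spec: LibrarySpec, rng: np.random.Generator) -> list[str]:
    k, n = spec.variable_length, spec.n_variants
    if spec.design == "exhaustive":
        if 4 ** k < n:
            raise ValueError(
                f"exhaustive design: 4^{k} = {4 ** k} < n_variants = {n}")
        return ["".join(t) for t in itertools.islice(
            itertools.product(ALPHABET, repeat=k), n)]
    if spec.design == "single-mutant-neighborhood":
        capacity = 1 + 3 * k
        if n > capacity:
            raise ValueError(
                f"single-mutant neighborhood of a {k}-mer holds {capacity} variants")
        center = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=k))
        out = [center]
        for pos in range(k):
            for base in ALPHABET:
                if base != center[pos]:
                    out.append(center[:pos] + base + center[pos + 1:])
        return out[:n]
    return _random_unique_kmers(rng, k, n)


def sample_library(gt: SyntheticGroundTruth, spec: LibrarySpec, context,
                   seed: int = 0) -> ExpressionDataset:
    """Emit ``n_variants`` unique variants with their true (mu, sigma)."""
    rng = np.random.default_rng(seed)
    regions = _variable_regions(spec, rng)
    rows = []
    for i, region in enumerate(regions):
        seq = spec.fixed_prefix + region + spec.fixed_suffix
        mu, sigma = true_expression(gt, seq, context)
        rows.append((f"v{i:06d}", seq, context, mu, sigma))
    frame = pd.DataFrame(rows, columns=["id", "sequence", "context", "mu", "sigma"])
    return ExpressionDataset(frame, metadata={
        "units": "arbitrary log-fluorescence",
        "design": spec.design,
        "seed": seed,
    })


def simulate_flowseq(
    gt: SyntheticGroundTruth,
    library: ExpressionDataset,
    n_cells_per_variant: int,
    n_reads_total: int,
    bin_edges=None,
    seed: int = 0,
    depth_skew=None,
) -> list[BinnedReadCounts]:
    """Simulate a sort-seq experiment for every variant in the library.

    Cells are drawn i.i.d. LogNormal(mu, sigma) per variant and sorted
    into the fluorescence bins; cells outside the covered range are
    clamped into the first/last bin (a FACS gate sorts every cell
    somewhere, which keeps read conservation exact). Sequencing depth is
    allocated to bins proportionally to the cells sorted into each bin
    (optionally skewed by ``depth_skew``), and reads within a bin are
    multinomial in the variants' cell shares; the total over all
    variants and bins equals ``n_reads_total`` exactly.
    """
    edges = np.asarray(DEFAULT_BIN_EDGES if bin_edges is None else bin_edges,
                       dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0) \
            or edges[0] <= 0:
        raise ValueError("bin_edges must be strictly increasing and positive")
    if n_cells_per_variant < 0 or n_reads_total < 0:
        raise ValueError("cell and read counts must be non-negative")
    n_bins = len(edges) - 1
    frame = library.frame
    rng = np.random.default_rng(seed)
    cells = np.zeros((len(frame), n_bins), dtype=np.int64)
    log_edges = np.log(edges)
    for vi, row in enumerate(frame.itertuples(index=False)):
        if n_cells_per_variant == 0:
            continue
        logf = rng.normal(row.mu, row.sigma, size=n_cells_per_variant)
        idx = np.searchsorted(log_edges[1:-1], logf, side="right")
        cells[vi] = np.bincount(idx, minlength=n_bins)
    weights = cells.astype(float)
    if depth_skew is not None:
        skew = np.asarray(depth_skew, dtype=float)
        if skew.shape != (n_bins,) or np.any(skew < 0):
            raise ValueError("depth_skew must be a non-negative vector of length B")
        weights = weights * skew
    total = weights.sum()
    if total > 0 and n_reads_total > 0:
        flat = rng.multinomial(n_reads_total, (weights / total).ravel())
        reads = flat.reshape(weights.shape)
    else:
        reads = np.zeros_like(cells)
    return [BinnedReadCounts(variant_id=vid, counts=reads[vi], bin_edges=edges)
            for vi, vid in enumerate(frame["id"])]


# -- I/O ----------------------------------------------------------------

def write_library(dataset: ExpressionDataset, tsv_path, fasta_path=None) -> None:
    dataset.to_tsv(tsv_path)
    if fasta_path is not None:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO
        records = [SeqRecord(Seq(row.sequence), id=row.id, description="")
                   for row in dataset.frame.itertuples(index=False)]
        SeqIO.write(records, str(fasta_path), "fasta")


def write_bin_counts(counts: list[BinnedReadCounts], tsv_path, sidecar_path=None,
                     depths=None) -> None:
    if not counts:
        raise ValueError("no bin counts to write")
    n_bins = len(counts[0].counts)
    rows = {c.variant_id: list(c.counts) for c in counts}
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"bin_{j + 1}" for j in range(n_bins)])
    frame.index.name = "id"
    frame.to_csv(tsv_path, sep="\t")
    if sidecar_path is not None:
        sidecar = {"bin_edges": list(map(float, counts[0].bin_edges))}
        if depths is not None:
            sidecar["depths"] = list(map(float, depths))
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1)


def read_bin_counts(tsv_path, sidecar_path) -> list[BinnedReadCounts]:
    frame = pd.read_csv(tsv_path, sep="\t", index_col="id")
    with open(sidecar_path) as fh:
        edges = np.asarray(json.load(fh)["bin_edges"], dtype=float)
    return [BinnedReadCounts(variant_id=str(vid),
                             counts=frame.loc[vid].to_numpy(dtype=np.int64),
                             bin_edges=edges)
            for vid in frame.index]
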