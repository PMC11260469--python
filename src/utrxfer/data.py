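"""Expression datasets, splitting schemes, strength categories,
activity-cliff mining and calibration-subset selection.

The in-memory container is a pandas DataFrame with columns
``id, sequence, context, mu[, sigma]``; I/O is plain TSV (optionally a
FASTA keyed by record id for the sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHABET = set("ACGT")

CATEGORY_LABELS = ("weak", "medium weak", "medium strong", "strong")

__all__ = [
    "ExpressionDataset",
    "DataSplit",
    "StrengthCategories",
    "ActivityCliffPair",
    "stratified_split",
    "per_context_split",
    "strength_categories",
    "categorize",
    "find_activity_cliffs",
    "select_training_subset",
]


class ExpressionDataset:
    """Sequence + expression records with context labels."""

    REQUIRED = ("id", "sequence", "context", "mu")

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None,
                 validate: bool = True):
        frame = frame.reset_index(drop=True)
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"missing required column {col!r}")
        if validate:
            if frame["id"].duplicated().any():
                raise ValueError("variant ids must be unique")
            if not np.all(np.isfinite(frame["mu"].to_numpy(dtype=float))):
                raise ValueError("mu must be finite")
            bad = [s for s in frame["sequence"] if set(s) - ALPHABET]
            if bad:
                raise ValueError(f"non-ACGT sequence: {bad[0]!r}")
        self.frame = frame
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list[str]:
        return list(self.frame["id"])

    @property
    def mu(self) -> np.ndarray:
        return self.frame["mu"].to_numpy(dtype=float)

    def subset(self, ids) -> "ExpressionDataset":
        ids = list(ids)
        sub = self.frame.set_index("id").loc[ids].reset_index()
        return ExpressionDataset(sub, metadata=self.metadata, validate=False)

    def by_context(self) -> dict:
        return {ctx: ExpressionDataset(g, metadata=self.metadata, validate=False)
                for ctx, g in self.frame.groupby("context", sort=True)}

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, fasta_path=None, metadata=None) -> "ExpressionDataset":
        frame = pd.read_csv(path, sep="\t", dtype={"id": str})
        if fasta_path is not None:
            from Bio import SeqIO
            seqs = {rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(str(fasta_path), "fasta")}
            frame["sequence"] = frame["id"].map(seqs)
            if frame["sequence"].isna().any():
                missing = frame.loc[frame["sequence"].isna(), "id"].iloc[0]
                raise ValueError(f"id {missing!r} not found in FASTA")
        if "context" not in frame.columns:
            frame["context"] = "default"
        return cls(frame, metadata=metadata)


@dataclass(frozen=True)
class DataSplit:
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "train_ids", tuple(self.train_ids))
        object.__setattr__(self, "val_ids", tuple(self.val_ids))
        object.__setattr__(self, "test_ids", tuple(self.test_ids))
        groups = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups must be pairwise disjoint")

    @property
    def all_ids(self) -> set:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)

    def save(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, ids in (("train", self.train_ids), ("val", self.val_ids),
                          ("test", self.test_ids)):
            (d / f"{name}_ids.txt").write_text("\n".join(ids) + "\n")

    @classmethod
    def load(cls, directory) -> "DataSplit":
        from pathlib import Path
        d = Path(directory)
        parts = [(d / f"{n}_ids.txt").read_text().split()
                 for n in ("train", "val", "test")]
        return cls(*parts)


@dataclass(frozen=True)
class StrengthCategories:
    """Four expression-strength classes of equal width on the 1st-99th
    percentile range of mu; ``width`` is the margin of tolerance
    (a quarter of that range)."""
    q1: float
    q99: float

    @property
    def width(self) -> float:
        return (self.q99 - self.q1) / 4.0

    @property
    def boundaries(self) -> tuple[float, float, float]:
        return tuple(self.q1 + k * self.width for k in (1, 2, 3))

    @property
    def labels(self) -> tuple:
        return CATEGORY_LABELS


def strength_categories(dataset: ExpressionDataset) -> StrengthCategories:
    mu = dataset.mu
    if len(np.unique(mu)) < 2:
        raise ValueError("mu range is degenerate; cannot form categories")
    # linear interpolation between order statistics (numpy default)
    q1, q99 = np.percentile(mu, [1, 99])
    if q99 <= q1:
        raise ValueError("mu range is degenerate; cannot form categories")
    return StrengthCategories(q1=float(q1), q99=float(q99))


def categorize(value: float, cats: StrengthCategories) -> str:
    """Which quarter of [q1, q99] contains the value; below-range values
    are weak, above-range strong, boundary ties go to the upper class."""
    b1, b2, b3 = cats.boundaries
    if value < b1:
        return CATEGORY_LABELS[0]
    if value < b2:
        return CATEGORY_LABELS[1]
    if value < b3:
        return CATEGORY_LABELS[2]
    return CATEGORY_LABELS[3]


def _allocate(size: int, ratios, rng: np.random.Generator) -> list[int]:
    """Largest-remainder apportionment of ``size`` slots to the ratios."""
    quotas = np.asarray(ratios, dtype=float) * size
    counts = np.floor(quotas).astype(int)
    remainder = size - counts.sum()
    if remainder > 0:
        frac = quotas - np.floor(quotas)
        order = np.argsort(-frac, kind="stable")
        for k in order[:remainder]:
            counts[k] += 1
    return list(counts)


def stratified_split(dataset: ExpressionDataset, ratios=(0.8, 0.1, 0.1),
                     n_strata: int = 10, seed: int = 0) -> DataSplit:
    """Equal-width mu strata; train/val/test allocated within each
    stratum at the given ratios so all three subsets share the dataset's
    fluorescence distribution."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    mu = dataset.mu
    ids = np.asarray(dataset.ids, dtype=object)
    lo, hi = mu.min(), mu.max()
    if hi > lo:
        strata = np.minimum(((mu - lo) / (hi - lo) * n_strata).astype(int),
                            n_strata - 1)
    else:
        strata = np.zeros(len(mu), dtype=int)
    parts: list[list] = [[], [], []]
    for s in range(n_strata):
        members = ids[strata == s]
        if len(members) == 0:
            continue
        members = members[rng.permutation(len(members))]
        counts = _allocate(len(members), ratios, rng)
        start = 0
        for k, c in enumerate(counts):
            parts[k].extend(members[start:start + c])
            start += c
    return DataSplit(train_ids=parts[0], val_ids=parts[1], test_ids=parts[2])


def _balanced_pick(mu: np.ndarray, ids: np.ndarray, n_pick: int) -> list:
    """Pick n_pick members with balanced mu: split the mu range into
    n_pick equal slices and take the member closest to each slice
    center, falling back to the globally closest remaining member when
    a slice is empty."""
    lo, hi = mu.min(), mu.max()
    centers = lo + (np.arange(n_pick) + 0.5) * (hi - lo) / n_pick
    remaining = np.ones(len(mu), dtype=bool)
    chosen = []
    for c in centers:
        if not remaining.any():
            break
        cand = np.where(remaining)[0]
        best = cand[np.argmin(np.abs(mu[cand] - c))]
        chosen.append(ids[best])
        remaining[best] = False
    return chosen


def per_context_split(dataset: ExpressionDataset, test_n: int = 30,
                      val_n: int = 20, min_context_size: int = 60,
                      seed: int = 0) -> dict:
    """Per-context splits in the style used for promoter sub-datasets:
    contexts below ``min_context_size`` records are dropped; each
    retained context gets a ``test_n``-sequence test set with balanced
    log-fluorescence means, then ``val_n`` random validation sequences,
    and the remainder for (fine-tuning) training."""
    rng = np.random.default_rng(seed)
    out = {}
    for ctx, sub in dataset.by_context().items():
        if len(sub) < min_context_size:
            continue
        ids = np.asarray(sub.ids, dtype=object)
        mu = sub.mu
        test_ids = _balanced_pick(mu, ids, test_n)
        rest = np.array([i for i in ids if i not in set(test_ids)], dtype=object)
        rest = rest[rng.permutation(len(rest))]
        val_ids = list(rest[:val_n])
        train_ids = list(rest[val_n:])
        out[ctx] = DataSplit(train_ids=train_ids, val_ids=val_ids,
                             test_ids=test_ids)
    return out


@dataclass(frozen=True)
class ActivityCliffPair:
    id_weak: str
    id_strong: str
    mu_weak: float
    mu_strong: float
    hamming_distance: int = 1


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def find_activity_cliffs(records, weak_threshold: float = 3.0,
                         strong_threshold: float = 6.0) -> list[ActivityCliffPair]:
    """All (weak, strong) pairs of equal-length sequences at Hamming
    distance exactly 1; ``records`` is an ExpressionDataset or an
    iterable of (id, sequence, mu)."""
    if isinstance(records, ExpressionDataset):
        items = [(r.id, r.sequence, float(r.mu))
                 for r in records.frame.itertuples(index=False)]
    else:
        items = [(str(i), s, float(m)) for i, s, m in records]
    weak = sorted([r for r in items if r[2] < weak_threshold])
    strong = sorted([r for r in items if r[2] > strong_threshold])
    pairs = []
    for wid, wseq, wmu in weak:
        for sid, sseq, smu in strong:
            if _hamming1(wseq, sseq):
                pairs.append(ActivityCliffPair(
                    id_weak=wid, id_strong=sid, mu_weak=wmu, mu_strong=smu))
    return pairs


def write_activity_cliffs(pairs, path) -> None:
    rows = [{"id_weak": p.id_weak, "id_strong": p.id_strong,
             "mu_weak": p.mu_weak, "mu_strong": p.mu_strong,
             "hamming_distance": p.hamming_distance} for p in pairs]
    pd.DataFrame(rows, columns=["id_weak", "id_strong", "mu_weak",
                                "mu_strong", "hamming_distance"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.6g")


def select_training_subset(dataset: ExpressionDataset, n: int,
                           strategy: str = "random", predictor=None,
                           seed: int = 0) -> list:
    """Choose ``n`` calibration examples.

    random: seeded uniform sampling without replacement.
    uniform_truth / uniform_predicted: split the (true or predicted) mu
    range into n equal slices, take one member per slice (round-robin,
    refilling empty slices from the nearest non-empty slice) so the
    selection covers the full log-fluorescence range.
    """
    if n > len(dataset):
        raise ValueError(f"n = {n} exceeds dataset size {len(dataset)}")
    if strategy not in ("random", "uniform_truth", "uniform_predicted"):
        raise ValueError(f"unknown strategy: {strategy}")
    rng = np.random.default_rng(seed)
    ids = np.asarray(dataset.ids, dtype=object)
    if n == len(dataset):
        return list(ids)
    if strategy == "random":
        return list(ids[rng.choice(len(ids), size=n, replace=False)])
    if strategy == "uniform_predicted":
        if predictor is None:
            raise ValueError("uniform_predicted requires a predictor")
        from .model import predict_mean
        values = np.array([p.mu_hat for p in
                           predict_mean(predictor, list(dataset.frame["sequence"]),
                                        ids=ids)])
    else:
        values = dataset.mu
    lo, hi = values.min(), values.max()
    if hi > lo:
        slice_idx = np.minimum(((values - lo) / (hi - lo) * n).astype(int), n - 1)
    else:
        slice_idx = np.zeros(len(values), dtype=int)
    pools = {s: list(np.where(slice_idx == s)[0]) for s in range(n)}
    for s in pools:
        rng.shuffle(pools[s])
    chosen: list[int] = []
    taken = np.zeros(len(values), dtype=bool)
    # one pass per slice; empty slices borrow from the nearest non-empty
    for s in range(n):
        pool = [i for i in pools[s] if not taken[i]]
        if not pool:
            for dist in range(1, n):
                for s2 in (s - dist, s + dist):
                    if 0 <= s2 < n:
                        pool = [i for i in pools[s2] if not taken[i]]
                        if pool:
                            break
                if pool:
                    break
        if not pool:
            break
        pick = pool[0]
        taken[pick] = True
        chosen.append(pick)
    return list(ids[chosen])
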