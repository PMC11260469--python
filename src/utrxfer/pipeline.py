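"""Configuration-driven orchestration: simulate -> infer -> split ->
train -> evaluate, with manifests for reproducibility.

A run config is a mapping (usually loaded from YAML) with a global
``seed``, an ``outdir`` and a ``stages`` list; each stage is a mapping
with a ``stage`` key naming the operation and stage-specific parameter
blocks. Every stage writes its outputs plus a manifest carrying the
config hash and the derived stage seed, so any report's lineage can be
reconstructed. The global seed fans out as seed + stage index, letting
stages be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import DataSplit, ExpressionDataset, stratified_split
from .flowseq import infer_lognormal_mle, quality_filter, write_estimates
from .model import ModelSpec, SequenceRegressor, build_model, encode_batch
from .synthetic import (LibrarySpec, make_ground_truth, sample_library,
                        simulate_flowseq, write_bin_counts, write_library,
                        read_bin_counts)
from .train import SchedulerConfig, TrainConfig, train
from .transfer import FinetuneConfig, finetune

KNOWN_STAGES = ("simulate", "infer", "split", "train", "finetune", "evaluate")

__all__ = ["RunConfig", "run"]


class ConfigError(ValueError):
    pass


class RunConfig:
    def __init__(self, mapping: dict):
        problems = []
        if "outdir" not in mapping:
            problems.append("missing key: outdir")
        if "stages" not in mapping or not isinstance(mapping.get("stages"), list):
            problems.append("missing or non-list key: stages")
        stages = mapping.get("stages", [])
        for i, st in enumerate(stages):
            name = st.get("stage")
            if name not in KNOWN_STAGES:
                problems.append(f"stages[{i}]: unknown stage {name!r}")
            elif name == "infer":
                upstream = any(s.get("stage") == "simulate" and s.get("flowseq")
                               for s in stages[:i])
                if not upstream and "edges_json" not in st:
                    problems.append(
                        f"stages[{i}] (infer): missing key bin_edges/"
                        "edges_json and no upstream simulated counts")
        if problems:
            raise ConfigError("invalid run config: " + "; ".join(problems))
        self.mapping = mapping
        self.seed = int(mapping.get("seed", 0))
        self.outdir = Path(mapping["outdir"])
        self.stages = mapping["stages"]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def hash(self) -> str:
        canon = json.dumps(self.mapping, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, index: int, config: RunConfig,
                    seed: int, outputs: list, status: str = "ok") -> None:
    manifest = {
        "stage": stage, "index": index, "config_hash": config.hash(),
        "seed": seed, "outputs": sorted(str(o) for o in outputs),
        "status": status,
    }
    with open(outdir / f"manifest_{index:02d}_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _model_spec(block: dict | None) -> ModelSpec:
    from .model import SMALL_CNN_LSTM_SPEC
    if not block:
        return SMALL_CNN_LSTM_SPEC
    return ModelSpec(**block)


def _train_config(block: dict | None, seed: int) -> TrainConfig:
    block = dict(block or {})
    sched = SchedulerConfig(**block.pop("scheduler", {}))
    block.setdefault("seed", seed)
    return TrainConfig(scheduler=sched, **block)


def run(config: RunConfig | dict | str) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(config)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for index, block in enumerate(config.stages):
        stage = block["stage"]
        seed = config.seed + index
        try:
            outputs = _STAGES[stage](block, state, outdir, seed)
        except Exception:
            # partial outputs stay on disk; record the failure point
            _write_manifest(outdir, stage, index, config, seed, [],
                            status="failed")
            raise
        _write_manifest(outdir, stage, index, config, seed, outputs)
    return outdir


def _stage_simulate(block, state, outdir, seed):
    contexts = block.get("contexts", ["A"])
    gt = make_ground_truth(
        contexts, seed=seed,
        **{k: block[k] for k in (
            "motif_width", "motif_scale", "optimal_spacing", "spacing_penalty",
            "structure_penalty", "noise_sigma", "context_offsets",
            "context_scales", "context_perturbations") if k in block})
    spec = LibrarySpec(**block.get("library", {}))
    frames = []
    for ci, ctx in enumerate(contexts):
        lib = sample_library(gt, spec, ctx, seed=seed + ci)
        frame = lib.frame.copy()
        frame["id"] = [f"{ctx}_{vid}" for vid in frame["id"]]
        frames.append(frame)
    dataset = ExpressionDataset(pd.concat(frames, ignore_index=True),
                                metadata={"units": "arbitrary log-fluorescence"})
    outputs = [outdir / "library.tsv"]
    write_library(dataset, outputs[0], outdir / "library.fasta")
    outputs.append(outdir / "library.fasta")
    state["dataset"] = dataset
    state["ground_truth"] = gt
    if block.get("flowseq"):
        fs = block["flowseq"]
        counts = simulate_flowseq(
            gt, dataset, n_cells_per_variant=int(fs.get("n_cells", 1000)),
            n_reads_total=int(fs.get("n_reads", 100_000)),
            bin_edges=fs.get("bin_edges"), seed=seed)
        write_bin_counts(counts, outdir / "counts.tsv", outdir / "edges.json")
        outputs += [outdir / "counts.tsv", outdir / "edges.json"]
        state["counts"] = counts
    return outputs


def _stage_infer(block, state, outdir, seed):
    counts = state.get("counts")
    if counts is None:
        counts = read_bin_counts(block["counts_tsv"], block["edges_json"])
    estimates = [infer_lognormal_mle(c) for c in counts if c.total_reads > 0]
    kept = quality_filter(estimates)
    write_estimates(kept, outdir / "estimates.tsv")
    state["estimates"] = kept
    # replace the dataset's true mu with the inferred mu for retained variants
    if "dataset" in state:
        frame = state["dataset"].frame
        mu_map = {e.variant_id: e.mu for e in kept}
        sg_map = {e.variant_id: e.sigma for e in kept}
        keep = frame["id"].isin(mu_map)
        frame = frame.loc[keep].copy()
        frame["mu"] = frame["id"].map(mu_map)
        frame["sigma"] = frame["id"].map(sg_map)
        state["dataset"] = ExpressionDataset(
            frame, metadata=state["dataset"].metadata)
    return [outdir / "estimates.tsv"]


def _require_dataset(block, state):
    if "dataset" in state:
        return state["dataset"]
    if "dataset_tsv" not in block:
        raise ConfigError("no dataset in state and no dataset_tsv given")
    return ExpressionDataset.from_tsv(block["dataset_tsv"])


def _stage_split(block, state, outdir, seed):
    dataset = _require_dataset(block, state)
    split = stratified_split(
        dataset, ratios=tuple(block.get("ratios", (0.8, 0.1, 0.1))),
        n_strata=int(block.get("n_strata", 10)), seed=seed)
    split.save(outdir / "split")
    state["split"] = split
    state["dataset"] = dataset
    return [outdir / "split" / f"{n}_ids.txt" for n in ("train", "val", "test")]


def _stage_train(block, state, outdir, seed):
    dataset = _require_dataset(block, state)
    split = state.get("split")
    if split is None:
        raise ConfigError("train stage requires a prior split stage")
    spec = _model_spec(block.get("model"))
    cfg = _train_config(block.get("config"), seed)
    model = build_model(spec, seed=cfg.seed)
    model, history = train(model, dataset, split, cfg)
    model.save(outdir / "model.npz")
    history.to_frame().to_csv(outdir / "history.tsv", sep="\t", index=False,
                              float_format="%.6g")
    state["model"] = model
    return [outdir / "model.npz", outdir / "history.tsv"]


def _stage_finetune(block, state, outdir, seed):
    dataset = _require_dataset(block, state)
    split = state.get("split")
    model = state.get("model")
    if model is None or split is None:
        raise ConfigError("finetune stage requires prior train and split stages")
    cfg_block = dict(block.get("config", {}))
    sched = SchedulerConfig(**cfg_block.pop("scheduler", {}))
    cfg_block.setdefault("seed", seed)
    cfg = FinetuneConfig(scheduler=sched, **cfg_block)
    tuned, history = finetune(model, dataset, split, cfg)
    tuned.save(outdir / "model_finetuned.npz")
    history.to_frame().to_csv(outdir / "history_finetune.tsv", sep="\t",
                              index=False, float_format="%.6g")
    state["model"] = tuned
    return [outdir / "model_finetuned.npz", outdir / "history_finetune.tsv"]


def _stage_evaluate(block, state, outdir, seed):
    from .data import strength_categories
    from .evaluate import metrics

    dataset = _require_dataset(block, state)
    split = state.get("split")
    model = state.get("model")
    if model is None:
        model = SequenceRegressor.load(block["model_npz"])
    test_ids = list(split.test_ids) if split is not None else dataset.ids
    test_set = dataset.subset(test_ids)
    X = encode_batch(list(test_set.frame["sequence"]), model.spec.max_len)
    preds = model.predict_mu(X)
    try:
        cats = strength_categories(dataset)
    except ValueError:
        cats = None
    rep = metrics(preds, test_set.mu, categories=cats)
    rep.to_json(outdir / "evaluation.json")
    table = pd.DataFrame([rep.to_dict()])
    table.to_csv(outdir / "evaluation.tsv", sep="\t", index=False,
                 float_format="%.6g")
    per_record = pd.DataFrame({
        "id": test_set.ids, "mu": test_set.mu, "mu_hat": preds,
    })
    per_record.to_csv(outdir / "predictions.tsv", sep="\t", index=False,
                      float_format="%.6g")
    state["report"] = rep
    return [outdir / "evaluation.json", outdir / "evaluation.tsv",
            outdir / "predictions.tsv"]


_STAGES = {
    "simulate": _stage_simulate,
    "infer": _stage_infer,
    "split": _stage_split,
    "train": _stage_train,
    "finetune": _stage_finetune,
    "evaluate": _stage_evaluate,
}
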