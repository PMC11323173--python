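"""Dataset splitting, mini-batch training, and checkpointing.

Default hyperparameters follow the reference protocol: 50 epochs, batch
size 32, Adam at learning rate 0.001, and an 85/15 stratified
train/test split.  Training is fully deterministic given the seed: data
order, parameter initialization, RBF center initialization, and dropout
masks are all derived from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._nn import Adam, weighted_cross_entropy
from .fusion_model import (
    FusionModel,
    ModelConfig,
    StateError,
    collate,
    init_rbf_centers,
    prepare_dataset,
)
from .sequence_io import ProteinSequence

CHECKPOINT_FORMAT = 1


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


class SplitError(ValueError):
    """Raised when a stratified split is impossible."""


@dataclass
class TrainConfig:
    """Optimization schedule (defaults mirror the reference protocol)."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0
    train_fraction: float = 0.85

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class SplitResult:
    """Disjoint, exhaustive stratified train/test id partition."""

    train_ids: list[str]
    test_ids: list[str]
    counts: dict

    def to_dict(self) -> dict:
        return {"train_ids": self.train_ids, "test_ids": self.test_ids,
                "counts": self.counts}


def stratified_split(records: Sequence[ProteinSequence], fraction: float,
                     seed: int) -> SplitResult:
    """Per-class shuffle (seeded) then split at round(fraction * n_class)."""
    if not (0.0 < fraction < 1.0):
        raise SplitError("fraction must lie in (0, 1)")
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for rec in records:
        if rec.label is None:
            raise SplitError(f"record {rec.id!r} has no label")
        by_class[rec.label].append(rec.id)
    for lab in (0, 1):
        if len(by_class[lab]) < 2:
            raise SplitError(
                f"class {lab} has {len(by_class[lab])} member(s); need >= 2")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    counts: dict = {}
    for lab in (0, 1):
        ids = list(by_class[lab])
        rng.shuffle(ids)
        n_train = int(round(fraction * len(ids)))
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
        counts[str(lab)] = {"train": n_train, "test": len(ids) - n_train}
    return SplitResult(train_ids=train_ids, test_ids=test_ids, counts=counts)


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Weights inversely proportional to class counts (mean weight 1)."""
    labels = np.asarray(labels)
    n = labels.size
    w = np.empty(2)
    for lab in (0, 1):
        n_lab = int((labels == lab).sum())
        if n_lab == 0:
            raise TrainingError(f"training set has no class-{lab} examples")
        w[lab] = n / (2.0 * n_lab)
    return w


def _init_rbf_from_features(model: FusionModel,
                            prepared, seed: int,
                            max_positions: int = 4000) -> None:
    """k-means over initial CNN per-position features -> RBF centers.

    The Gaussian width is then set by the median heuristic
    (gamma = 1 / median squared inter-center distance).
    """
    feats_list = []
    for start in range(0, len(prepared), 64):
        chunk = prepared[start:start + 64]
        ids, profiles, mask, lengths = collate(chunk)
        f = model._front_end(ids, profiles, mask, training=False, rng=None)
        feats_list.append(f[mask.astype(bool)])
    feats = np.concatenate(feats_list, axis=0)
    if feats.shape[0] > max_positions:
        sel = np.random.default_rng(seed).choice(
            feats.shape[0], size=max_positions, replace=False)
        feats = feats[sel]
    centers = init_rbf_centers(feats, model.config.rbf.num_centers, seed)
    model.rbf.set_centers(centers)
    model.centers_initialized = True


def train_model(
    model_or_kind,
    train_records: Sequence[ProteinSequence],
    config: Optional[TrainConfig] = None,
    model_config: Optional[ModelConfig] = None,
    pssms: Optional[dict] = None,
) -> tuple[FusionModel, pd.DataFrame]:
    """Train a model on labeled records; returns (model, per-epoch log).

    The log has columns ``epoch``, ``mean_loss``, ``train_accuracy``.
    Loss is class-weighted cross-entropy (weights inversely proportional
    to class counts).  For the hybrid model, RBF centers are initialized
    by k-means on the untrained CNN's per-position features and then
    trained jointly with everything else.
    """
    config = config or TrainConfig()
    if isinstance(model_or_kind, FusionModel):
        model = model_or_kind
    else:
        model = FusionModel(kind=model_or_kind, config=model_config,
                            seed=config.seed)
    train_records = list(train_records)
    if not train_records:
        raise TrainingError("empty training set")
    labels = np.array([r.label for r in train_records])
    if any(lab is None for lab in labels):
        raise TrainingError("all training records need labels")
    weights = class_weights(labels)

    prepared = prepare_dataset(train_records, model.config, pssms)
    order_by_len = np.argsort([p.length for p in prepared], kind="stable")

    if model.kind == "hybrid" and not model.centers_initialized:
        _init_rbf_from_features(model, prepared, seed=config.seed)

    opt = Adam(model.layers, lr=config.learning_rate)
    log_rows = []
    n = len(prepared)
    for epoch in range(config.epochs):
        rng_order = np.random.default_rng(config.seed + epoch)
        rng_drop = np.random.default_rng([config.seed, epoch, 7])
        perm = rng_order.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            batch = [prepared[i] for i in idx]
            ids, profiles, mask, lengths = collate(batch)
            y = labels[idx]
            logits = model.forward_batch(ids, profiles, mask, lengths,
                                         training=True, rng=rng_drop)
            loss, dlogits, probs = weighted_cross_entropy(logits, y, weights)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}")
            opt.zero_grads()
            model.backward_batch(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int(((probs[:, 1] >= 0.5).astype(int) == y).sum())
        log_rows.append({
            "epoch": epoch,
            "mean_loss": float(np.sum(losses) / n),
            "train_accuracy": correct / n,
        })
    log = pd.DataFrame(log_rows)
    return model, log


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: FusionModel, path, *,
                    train_config: Optional[TrainConfig] = None,
                    extra: Optional[dict] = None) -> Path:
    """Write a checkpoint directory: params.npz + manifest.json.

    The manifest (architecture kind, full model config, seed, residue
    ordering, normalization mode) plus the tensor archive fully determine
    the forward function.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "params.npz", **model.named_params())
    manifest = {
        "format": CHECKPOINT_FORMAT,
        "kind": model.kind,
        "seed": model.seed,
        "model_config": model.config.to_dict(),
        "residue_order": "ARNDCQEGHILKMFPSTWYV",
        "centers_initialized": model.centers_initialized,
    }
    if train_config is not None:
        manifest["train_config"] = {
            "epochs": train_config.epochs,
            "batch_size": train_config.batch_size,
            "learning_rate": train_config.learning_rate,
            "optimizer": train_config.optimizer,
            "seed": train_config.seed,
            "train_fraction": train_config.train_fraction,
        }
    if extra:
        manifest.update(extra)
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def load_checkpoint(path, expected_kind: Optional[str] = None) -> FusionModel:
    """Restore a model with bit-identical forward behaviour."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise StateError(f"no manifest.json in {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != CHECKPOINT_FORMAT:
        raise StateError("unsupported checkpoint format")
    if expected_kind is not None and manifest["kind"] != expected_kind:
        raise StateError(
            f"checkpoint kind {manifest['kind']!r} != expected "
            f"{expected_kind!r}")
    model = FusionModel(
        kind=manifest["kind"],
        config=ModelConfig.from_dict(manifest["model_config"]),
        seed=manifest["seed"],
    )
    with np.load(path / "params.npz") as npz:
        model.set_params({k: npz[k] for k in npz.files})
    model.centers_initialized = manifest.get("centers_initialized", True)
    return model
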