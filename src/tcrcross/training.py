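"""Training loop, evaluation metrics, cross-validation, and checkpoint
selection — including explanation-quality-based early stopping.

Two checkpoint-selection strategies are compared from a configurable start
epoch onward: loss-based (argmin of epoch-mean training loss) and
explanation-based (argmax of explanation quality, the mean BRHR over the four
epitope<->chain directions against structural ground truth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .brhr import DistanceStore, explanation_quality
from .explain import ExplainerSpec
from .models import MultiModalModel, collate
from .objectives import LossConfig, apply_mlm_mask, compute_losses, total_loss
from .nn import AdamW
from .repertoire import TCRSample, kfold_split


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    batch_size: int = 64
    seed: int = 0
    checkpoint_every: int = 10
    selection: str = "loss_based"  # or "explanation_based"
    selection_start_epoch: int = 300
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.selection_start_epoch > self.epochs:
            raise ValueError("selection_start_epoch exceeds epochs")


@dataclass
class QualityEvalSet:
    """Samples with structural (or synthetic) distances for scoring
    explanation quality during training."""

    samples: list[TCRSample]
    distances: DistanceStore
    sample_ids: Optional[list] = None
    explainer: ExplainerSpec = field(default_factory=ExplainerSpec)
    t: float = 0.25


@dataclass
class CheckpointRecord:
    epoch: int
    train_loss: float
    explanation_quality: float  # NaN when not evaluated
    params: dict  # parameter snapshot (name -> array)


def train(model: MultiModalModel, train_data: list[TCRSample], config: TrainConfig,
          quality_eval_set: QualityEvalSet | None = None,
          log: Optional[Callable[[dict], None]] = None) -> list[CheckpointRecord]:
    """AdamW training with per-epoch loss logging and checkpoint snapshots.

    Explanation quality is evaluated at each checkpoint from
    ``selection_start_epoch`` onward when a quality evaluation set is given.
    """
    rng = np.random.default_rng(config.seed)
    labels_all = np.array([s.label for s in train_data])
    batch_all = collate(train_data, model.modalities, model.config.vocab,
                        model.config.max_lens)
    opt = AdamW(model.parameters(), lr=config.learning_rate, betas=config.betas,
                weight_decay=config.weight_decay)
    mlm_active = config.loss.mlm_on_encoders or config.loss.mlm_on_decoders
    n = len(train_data)
    records: list[CheckpointRecord] = []
    model.train()
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch, mlm_targets = {}, {}
            for mod in model.modalities:
                ids = batch_all[mod]["ids"][idx]
                mask = batch_all[mod]["mask"][idx]
                if mlm_active:
                    corrupted, selected = apply_mlm_mask(
                        ids, mask, model.config.vocab, config.loss.mlm_mask_rate, rng)
                    mlm_targets[mod] = (ids, selected)
                    batch[mod] = {"ids": corrupted, "mask": mask}
                else:
                    batch[mod] = {"ids": ids, "mask": mask}
            chunk = [train_data[i] for i in idx]
            output = model.forward(batch, return_attentions=False)
            components = compute_losses(model, output, batch, chunk, labels_all[idx],
                                        mlm_targets, config.loss)
            loss = total_loss(components, config.loss)
            value = float(loss.data)
            if not math.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: "
                    + ", ".join(f"{k}={float(v.data):.4g}" for k, v in components.items()))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        mean_loss = float(np.mean(epoch_losses))
        if log is not None:
            log({"epoch": epoch, "loss": mean_loss,
                 **{f"loss_{k}": float(v.data) for k, v in components.items()}})
        if epoch % config.checkpoint_every == 0 or epoch == config.epochs:
            quality = float("nan")
            if quality_eval_set is not None and epoch >= config.selection_start_epoch:
                q = quality_eval_set
                quality = explanation_quality_on(model, q)
            records.append(CheckpointRecord(epoch=epoch, train_loss=mean_loss,
                                            explanation_quality=quality,
                                            params=model.state_dict()))
    return records


def explanation_quality_on(model: MultiModalModel, q: QualityEvalSet) -> float:
    from .brhr import dataset_brhr
    from .models import quality_directions

    report = dataset_brhr(model, q.samples, q.distances, q.explainer, q.t,
                          directions=quality_directions(model),
                          sample_ids=q.sample_ids)
    values = list(report.per_direction_mean.values())
    if any(np.isnan(v) for v in values):
        return float("nan")
    return float(np.mean(values))


def select_checkpoint(records: list[CheckpointRecord], strategy: str,
                      start_epoch: int = 300) -> CheckpointRecord:
    """Pick a checkpoint at epoch >= start_epoch: argmin training loss
    (loss_based) or argmax explanation quality (explanation_based); ties go to
    the earlier epoch."""
    eligible = [r for r in records if r.epoch >= start_epoch]
    if strategy == "explanation_based":
        eligible = [r for r in eligible if not math.isnan(r.explanation_quality)]
        if not eligible:
            raise ValueError("no eligible checkpoint with explanation quality")
        best = eligible[0]
        for r in eligible[1:]:
            if r.explanation_quality > best.explanation_quality:
                best = r
        return best
    if strategy == "loss_based":
        if not eligible:
            raise ValueError("no eligible checkpoint at or after start_epoch")
        best = eligible[0]
        for r in eligible[1:]:
            if r.train_loss < best.train_loss:
                best = r
        return best
    raise ValueError(f"unknown selection strategy {strategy!r}")


def roc_auc(scores, labels) -> float:
    """P(random positive outranks random negative), ties counted half
    (Mann-Whitney / rank formulation)."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_auc(model: MultiModalModel, samples: list[TCRSample]) -> float:
    labels = np.array([s.label for s in samples])
    return roc_auc(model.predict_proba(samples), labels)


def crossvalidate(samples: list[TCRSample],
                  build_fn: Callable[[int], MultiModalModel] | None,
                  train_config: TrainConfig | None = None, k: int = 5, seed: int = 0,
                  scorer: Callable[[list[TCRSample]], np.ndarray] | None = None
                  ) -> tuple[float, float, list[float]]:
    """k-fold cross-validation: mean, std and per-fold held-out ROC-AUC.

    ``build_fn(fold_seed)`` constructs a fresh model per fold. A ``scorer``
    (samples -> scores) bypasses training, e.g. for oracle baselines.
    """
    folds = kfold_split(samples, k=k, seed=seed)
    aucs = []
    for fi, test_idx in enumerate(folds):
        test = [samples[i] for i in test_idx]
        labels = np.array([s.label for s in test])
        if scorer is not None:
            scores = np.asarray(scorer(test))
        else:
            train_idx = np.setdiff1d(np.arange(len(samples)), test_idx)
            model = build_fn(seed + fi)
            cfg = replace(train_config, seed=train_config.seed + fi)
            train(model, [samples[i] for i in train_idx], cfg)
            scores = model.predict_proba(test)
        aucs.append(roc_auc(scores, labels))
    return float(np.mean(aucs)), float(np.std(aucs)), aucs
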