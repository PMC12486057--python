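"""Per-residue, per-direction importance scores from model attention.

A directed interaction ``a -> b`` scores the residues of the *target* ``b``:
the decoder in which ``a`` queries ``b`` yields an attention matrix whose
columns (keys) are ``b`` positions; reducing over query rows gives one score
per target residue. Directions without a native map are derived from the
reverse map by reducing over the opposite axis (note that with row-stochastic
attention the mean over keys is constant, so ``max`` is the informative
query-side reduction; both are exposed).

Following the evaluation protocol, unavailable (NA) values are treated as 0
and scores are smoothed with a length-3 boxcar kernel (1/3, 1/3, 1/3) to
tolerate a one-residue offset. Explanations for encoder-only models use the
binder classification loss; encoder-decoder models use the full training loss.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .models import CrossAttentionRecord, ModelOutput, MultiModalModel, collate
from .objectives import LossConfig, binder_loss, compute_losses, total_loss
from .repertoire import TCRSample

SMOOTHING_KERNEL = np.array([1 / 3, 1 / 3, 1 / 3])


@dataclass
class ImportanceVector:
    """Scores over the residues of ``direction``'s target sequence (specials
    excluded); may contain NaN before cleaning."""

    direction: tuple[str, str]
    scores: np.ndarray

    @property
    def length(self) -> int:
        return len(self.scores)


@dataclass
class ExplainerSpec:
    method: str = "attention"  # "attention" | "grad_x_attention" | a registered name
    layer_reduction: str = "last"  # "last" | "mean"
    query_reduction: str = "mean"  # "mean" | "max"
    smoothing: bool = True


EXPLAINER_REGISTRY: dict[str, Callable] = {}


def register_explainer(name: str, fn: Callable) -> None:
    """Register an external explanation backend (e.g. a relevance-propagation
    engine); ``fn(model, sample, spec) -> dict[direction, ImportanceVector]``."""
    EXPLAINER_REGISTRY[name] = fn


def clean_scores(v: ImportanceVector) -> ImportanceVector:
    """NA -> 0, per the evaluation convention."""
    return replace(v, scores=np.nan_to_num(v.scores, nan=0.0))


def smooth_scores(v: ImportanceVector) -> ImportanceVector:
    """Same-length convolution with kernel (1/3, 1/3, 1/3), zero padding."""
    if v.length == 0:
        raise ValueError("cannot smooth an empty importance vector")
    if np.isnan(v.scores).any():
        raise ValueError("clean NA values before smoothing (clean_scores)")
    return replace(v, scores=np.convolve(v.scores, SMOOTHING_KERNEL, mode="same"))


def _reduce_layers(layers: list[np.ndarray], how: str) -> np.ndarray:
    if how == "last":
        return layers[-1]
    if how == "mean":
        return np.mean(layers, axis=0)
    raise ValueError(f"unknown layer_reduction {how!r}")


def _reduce_axis(mat: np.ndarray, axis: int, how: str) -> np.ndarray:
    if how == "mean":
        return mat.mean(axis=axis)
    if how == "max":
        return mat.max(axis=axis)
    raise ValueError(f"unknown query_reduction {how!r}")


def _find_record(output: ModelOutput, direction: tuple[str, str]
                 ) -> Optional[tuple[CrossAttentionRecord, tuple[int, int], bool]]:
    """Locate the map for ``direction``; (record, key span, reversed?).

    Prefers a native map from the most downstream decoder; falls back to the
    reverse-direction map when the direction itself is not wired.
    """
    for reversed_ in (False, True):
        want = direction if not reversed_ else (direction[1], direction[0])
        found = None
        for rec in output.self_records + output.cross_records:
            for k_mod, span in rec.segments:
                if (rec.q_mod, k_mod) == want:
                    found = (rec, span, reversed_)
        if found is not None:
            return found
    return None


def attention_importance(output: ModelOutput, direction: tuple[str, str],
                         spec: ExplainerSpec, sample_index: int = 0,
                         weight_grads: dict | None = None) -> ImportanceVector:
    """Reduce an attention map to per-target-residue scores (NA treated as 0).

    ``weight_grads`` optionally maps id(probs tensor) -> gradient array for
    the gradient-times-attention method.
    """
    found = _find_record(output, direction)
    if found is None:
        available = sorted({(r.q_mod, k) for r in output.self_records + output.cross_records
                            for k, _ in r.segments})
        raise KeyError(f"direction {direction} unavailable; native maps: {available}")
    rec, (start, stop), reversed_ = found
    layers = []
    for p in rec.probs:
        arr = p.data
        if weight_grads is not None:
            g = weight_grads.get(id(p))
            arr = arr * (np.abs(g) if g is not None else 0.0)
        layers.append(arr[sample_index, :, :, start:stop].mean(axis=0))  # head mean
    mat = _reduce_layers(layers, spec.layer_reduction)

    q_mod = rec.q_mod
    k_mod = direction[1] if not reversed_ else direction[0]
    # strip special-token rows/columns (UNK counts as a residue position)
    special = output.vocab.special_ids - {output.vocab.unk_id}
    q_ids = output.batch[q_mod]["ids"][sample_index]
    k_ids = output.batch[k_mod]["ids"][sample_index]
    q_pos = np.nonzero(~np.isin(q_ids, list(special)))[0]
    k_pos = np.nonzero(~np.isin(k_ids, list(special)))[0]
    sub = np.nan_to_num(mat[np.ix_(q_pos, k_pos)], nan=0.0)
    if not reversed_:
        scores = _reduce_axis(sub, 0, spec.query_reduction)  # per key (target) residue
    else:
        scores = _reduce_axis(sub, 1, spec.query_reduction)  # per query residue
    return ImportanceVector(direction=direction, scores=scores)


def _available_directions(output: ModelOutput) -> list[tuple[str, str]]:
    native = []
    for rec in output.self_records + output.cross_records:
        for k_mod, _ in rec.segments:
            if (rec.q_mod, k_mod) not in native:
                native.append((rec.q_mod, k_mod))
    derived = [(b, a) for (a, b) in native if (b, a) not in native and a != b]
    return native + derived


def explain(model: MultiModalModel, sample: TCRSample, spec: ExplainerSpec,
            loss_choice: str | None = None, loss_config: LossConfig | None = None
            ) -> dict[tuple[str, str], ImportanceVector]:
    """Importance vectors for every available direction of one sample.

    ``loss_choice`` (for the gradient-weighted method) defaults to the binder
    classification loss for encoder-only models and to the full training loss
    for encoder-decoder models.
    """
    if spec.method in EXPLAINER_REGISTRY:
        return EXPLAINER_REGISTRY[spec.method](model, sample, spec)
    if spec.method not in ("attention", "grad_x_attention"):
        raise KeyError(f"explainer {spec.method!r} is not implemented or registered")
    was_training = model.training
    model.eval()
    try:
        batch = collate([sample], model.modalities, model.config.vocab, model.config.max_lens)
        output = model.forward(batch, return_attentions=True)
        weight_grads = None
        if spec.method == "grad_x_attention":
            if loss_choice is None:
                loss_choice = "binder" if not model.decoder_specs else "training"
            label = np.array([sample.label])
            if loss_choice == "binder":
                loss = binder_loss(output.binder_logit, label)
            elif loss_choice == "training":
                cfg = loss_config or LossConfig(use_mhc_loss=False, use_trvj_loss=False)
                components = compute_losses(model, output, batch, [sample], label,
                                            mlm_targets={}, config=cfg)
                loss = total_loss(components, cfg)
            else:
                raise ValueError(f"unknown loss_choice {loss_choice!r}")
            loss.backward()
            weight_grads = {}
            for rec in output.self_records + output.cross_records:
                for p in rec.probs:
                    weight_grads[id(p)] = p.grad
        result = {}
        for direction in _available_directions(output):
            v = attention_importance(output, direction, spec, 0, weight_grads)
            v = clean_scores(v)
            if spec.smoothing:
                v = smooth_scores(v)
            result[direction] = v
        return result
    finally:
        model.train(was_training)


def export_importances(importances: dict[int, dict[tuple[str, str], ImportanceVector]],
                       path) -> None:
    """Write per-sample, per-direction scores as CSV (0-based residue index)."""
    import pandas as pd

    rows = []
    for sid, per_dir in importances.items():
        for (a, b), v in per_dir.items():
            for i, s in enumerate(v.scores):
                rows.append({"sample": sid, "direction": f"{a}->{b}",
                             "residue": i, "score": float(s)})
    pd.DataFrame(rows).to_csv(path, index=False)
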