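"""Training objectives: binder classification, masked-language-modeling on
amino-acid tokens, and the MHC / V-J gene-segment auxiliary losses.

The binder head is trained with sigmoid binary cross-entropy. MLM follows the
BERT recipe: residue positions are corrupted independently at ``mlm_mask_rate``
(80% MASK token, 10% random residue, 10% unchanged) and recovery is scored by
cross-entropy at the corrupted positions only. MLM can be attached to the
per-modality encoders, to the decoders (reconstructing the decoder's
query-modality tokens), or both; disabling the decoder term leaves decoders
optimized purely by the classification signal. Auxiliary heads classify MHC
class (binary) and MHC/TRAV/TRAJ/TRBV/TRBJ alleles (categorical); samples with
a missing annotation are masked out of the corresponding head's loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, bce_with_logits, cross_entropy_with_logits
from .models import ModelOutput, MultiModalModel
from .repertoire import TCRSample, Vocabulary

TRVJ_FIELDS = ("trav", "traj", "trbv", "trbj")


@dataclass
class LossConfig:
    mlm_on_encoders: bool = True
    mlm_on_decoders: bool = True
    mlm_mask_rate: float = 0.15
    use_mhc_loss: bool = False
    use_trvj_loss: bool = False
    weights: dict = field(default_factory=dict)  # component -> nonnegative weight

    def weight(self, component: str) -> float:
        w = float(self.weights.get(component, 1.0))
        if w < 0 or not np.isfinite(w):
            raise ValueError(f"loss weight for {component!r} must be finite and >= 0")
        return w


def binder_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean sigmoid binary cross-entropy over the batch."""
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("binder labels must be 0 or 1")
    return bce_with_logits(logits, labels.astype(np.float32))


def apply_mlm_mask(ids: np.ndarray, mask: np.ndarray, vocab: Vocabulary,
                   rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """BERT-style corruption of residue tokens.

    Special tokens (PAD/BOS/EOS, and existing MASK/UNK) are never selected.
    Returns (corrupted ids, boolean array of selected target positions).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("mask rate must be in [0, 1)")
    ids = np.asarray(ids)
    maskable = np.asarray(mask, bool) & ~np.isin(ids, list(vocab.special_ids))
    if rate == 0.0:
        return ids.copy(), np.zeros_like(maskable)
    selected = maskable & (rng.random(ids.shape) < rate)
    corrupted = ids.copy()
    u = rng.random(ids.shape)
    n_res = len(vocab) - len(vocab.special_ids)  # residue ids are contiguous from 0
    random_res = rng.integers(0, n_res, size=ids.shape)
    corrupted[selected & (u < 0.8)] = vocab.mask_id
    swap = selected & (u >= 0.8) & (u < 0.9)
    corrupted[swap] = random_res[swap]
    # remaining 10%: kept unchanged but still predicted
    return corrupted, selected


def mlm_loss(mlm_logits: Tensor, targets: np.ndarray, positions: np.ndarray) -> Tensor:
    """Mean cross-entropy over selected positions; 0 when none are selected."""
    positions = np.asarray(positions, bool)
    targets = np.asarray(targets)
    if positions.shape != targets.shape or mlm_logits.shape[:-1] != targets.shape:
        raise ValueError("mlm_loss shape mismatch between logits, targets and positions")
    return cross_entropy_with_logits(mlm_logits, targets, positions)


def _categorical_labels(values: list, vocab: list[str], train: bool) -> tuple[np.ndarray, np.ndarray]:
    index = {v: i for i, v in enumerate(vocab)}
    ids = np.zeros(len(values), dtype=np.int64)
    present = np.zeros(len(values), dtype=bool)
    for i, v in enumerate(values):
        if v is None:
            continue
        if v not in index:
            if train:
                raise KeyError(f"label {v!r} not in the head's vocabulary")
            continue
        ids[i] = index[v]
        present[i] = True
    return ids, present


def _masked_ce(logits: Tensor, ids: np.ndarray, present: np.ndarray) -> Tensor:
    return cross_entropy_with_logits(logits, ids, present)


def mhc_loss(aux_logits: dict, samples: list[TCRSample], mhc_vocab: list[str],
             train: bool = True) -> Tensor:
    """Binary MHC-class loss plus categorical MHC-allele loss, summed.

    Samples with a missing annotation are excluded from that term.
    """
    class_vals = np.array([{"I": 1.0, "II": 0.0}.get(s.mhc_class, np.nan) for s in samples])
    class_mask = ~np.isnan(class_vals)
    loss = bce_with_logits(aux_logits["mhc_class"], np.nan_to_num(class_vals), class_mask)
    allele_ids, present = _categorical_labels([s.mhc_allele for s in samples], mhc_vocab, train)
    return loss + _masked_ce(aux_logits["mhc_allele"], allele_ids, present)


def trvj_loss(aux_logits: dict, samples: list[TCRSample], vocabs: dict[str, list[str]],
              train: bool = True) -> Tensor:
    """Sum of four categorical cross-entropies over TRAV/TRAJ/TRBV/TRBJ alleles."""
    total: Tensor | None = None
    for f in TRVJ_FIELDS:
        ids, present = _categorical_labels([getattr(s, f) for s in samples], vocabs[f], train)
        term = _masked_ce(aux_logits[f], ids, present)
        total = term if total is None else total + term
    return total


def total_loss(components: dict[str, Tensor], config: LossConfig) -> Tensor:
    """Weighted sum of the enabled loss components."""
    total: Tensor | None = None
    for name, value in components.items():
        w = config.weight(name)
        term = value * w
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no loss components enabled")
    return total


def compute_losses(model: MultiModalModel, output: ModelOutput, batch: dict,
                   samples: list[TCRSample], labels: np.ndarray,
                   mlm_targets: dict, config: LossConfig) -> dict[str, Tensor]:
    """All enabled loss components for one forward pass.

    ``mlm_targets`` maps modality -> (original ids, selected positions) as
    produced by :func:`apply_mlm_mask`; pass an empty dict to skip MLM.
    """
    components: dict[str, Tensor] = {"binder": binder_loss(output.binder_logit, labels)}
    if mlm_targets:
        enc_terms: Tensor | None = None
        dec_terms: Tensor | None = None
        for key, (logits, target_mod) in output.mlm_logits.items():
            if target_mod not in mlm_targets:
                continue
            targets, positions = mlm_targets[target_mod]
            kind = key[0]
            if kind == "enc" and config.mlm_on_encoders:
                term = mlm_loss(logits, targets, positions)
                enc_terms = term if enc_terms is None else enc_terms + term
            elif kind == "dec" and config.mlm_on_decoders:
                term = mlm_loss(logits, targets, positions)
                dec_terms = term if dec_terms is None else dec_terms + term
        if enc_terms is not None:
            components["mlm_encoders"] = enc_terms
        if dec_terms is not None:
            components["mlm_decoders"] = dec_terms
    if config.use_mhc_loss:
        components["mhc"] = mhc_loss(output.aux_logits, samples,
                                     model.config.aux_vocabs["mhc_allele"])
    if config.use_trvj_loss:
        components["trvj"] = trvj_loss(output.aux_logits, samples,
                                       {f: model.config.aux_vocabs[f] for f in TRVJ_FIELDS})
    return components


def aux_vocabs_from_samples(samples: list[TCRSample],
                            mhc: bool = True, trvj: bool = True) -> dict[str, list[str]]:
    """Label vocabularies for the auxiliary heads, fixed at build time."""
    vocabs: dict[str, list[str]] = {}
    if mhc:
        vocabs["mhc_class"] = ["II", "I"]
        vocabs["mhc_allele"] = sorted({s.mhc_allele for s in samples if s.mhc_allele})
    if trvj:
        for f in TRVJ_FIELDS:
            vocabs[f] = sorted({getattr(s, f) for s in samples if getattr(s, f)})
    return vocabs
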