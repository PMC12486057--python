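"""Multi-modal transformer models for TCR-pMHC binding prediction.

Three model families share one computational graph abstraction:

* encoder-only models: one independent transformer encoder per input modality,
  pooled features concatenated into a linear binder head;
* directional cross-attention probes: a decoder whose queries come from one
  modality and whose keys/values come from another (``a -> b``), optionally
  concatenating the raw encoder features of one modality into the classifier;
* encoder-decoder models (EGM-0/1/2) over chain A, chain B and the epitope:
  - EGM-0: each modality directly cross-attends to the concatenation of the
    other two;
  - EGM-1: inter-chain cross-attention first (A->B, B->A producing refined
    streams A', B'), then the epitope queries each refined chain and each
    refined chain queries the epitope through separate decoders;
  - EGM-2: EGM-1 with the chain-to-epitope decoders attending to the epitope
    concatenated with the complementary refined chain (A' -> E + B').

Memories fused from several modalities are concatenated along the sequence
axis with a learned per-source segment embedding, which keeps each source's
cross-attention columns separately addressable for explanation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .nn import (
    Parameter as nn_Parameter,
    Decoder,
    Linear,
    Module,
    SequenceEncoder,
    Tensor,
    concat,
    concat_memory,
    embedding,
    masked_mean_pool,
    trunc_normal,
)
from .repertoire import DEFAULT_VOCAB, TCRSample, Vocabulary, tokenize

EGM_VARIANTS = ("EGM0", "EGM1", "EGM2")

KNOWN_MODALITIES = ("tcra", "tcrb", "cdr1a", "cdr2a", "cdr3a",
                    "cdr1b", "cdr2b", "cdr3b", "epitope")


def default_max_lens() -> dict[str, int]:
    # CDR loops and epitopes are short; full chains need more room (+2 specials)
    lens = {m: 25 for m in KNOWN_MODALITIES}
    lens["tcra"] = lens["tcrb"] = 140
    return lens


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults follow the reference setup of
    two hidden layers, 128-dimensional states and a single attention head."""

    hidden_dim: int = 128
    n_layers: int = 2
    n_heads: int = 1
    ffn_dim: Optional[int] = None  # defaults to 4 * hidden_dim
    dropout: float = 0.1
    vocab: Vocabulary = field(default_factory=lambda: DEFAULT_VOCAB)
    max_lens: dict = field(default_factory=default_max_lens)
    chain_a: str = "tcra"
    chain_b: str = "tcrb"
    epitope: str = "epitope"
    aux_vocabs: dict = field(default_factory=dict)  # e.g. {"mhc_allele": [...], "trav": [...]}
    seed: int = 0

    @property
    def ffn(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.hidden_dim

    def __post_init__(self):
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")


@dataclass
class Probe:
    """Directional cross-attention probe variant: query -> memory (+ residual)."""

    query_mod: str
    memory_mod: str
    residual_mod: Optional[str] = None

    def __post_init__(self):
        if self.query_mod == self.memory_mod:
            raise ValueError("probe query and memory modalities must differ")
        if self.residual_mod not in (None, self.query_mod, self.memory_mod):
            raise ValueError("residual_mod must be the query, the memory, or None")


@dataclass
class DecoderSpec:
    """Wiring of one decoder: a query source and an ordered list of memory
    sources; sources are ('enc', modality) or ('dec', decoder-name)."""

    name: str
    query: tuple[str, str]
    memory: list[tuple[str, str]]


@dataclass
class CrossAttentionRecord:
    """One decoder's cross-attention, split into per-source-modality segments."""

    decoder: str
    q_mod: str
    segments: list[tuple[str, tuple[int, int]]]  # (key modality, (start, stop))
    probs: list[Tensor]  # per layer, (B, heads, Lq, Lk_total)


@dataclass
class ModelOutput:
    binder_logit: Tensor
    pooled: Tensor
    mlm_logits: dict  # key: ("enc", mod) or ("dec", decoder-name) -> (Tensor, target modality)
    aux_logits: dict  # head name -> Tensor
    cross_records: list[CrossAttentionRecord]
    self_records: list[CrossAttentionRecord]
    batch: dict
    vocab: Vocabulary = field(default_factory=lambda: DEFAULT_VOCAB)

    @property
    def binder_prob(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.binder_logit.data))

    @property
    def attentions(self) -> dict[tuple[str, str], list[np.ndarray]]:
        """Head-averaged attention arrays keyed by (query, key) modality.

        When several decoders expose the same direction, the last one in
        computation order (the most downstream stage) wins.
        """
        out: dict[tuple[str, str], list[np.ndarray]] = {}
        for rec in self.self_records + self.cross_records:
            for k_mod, (start, stop) in rec.segments:
                out[(rec.q_mod, k_mod)] = [p.data[:, :, :, start:stop].mean(axis=1)
                                           for p in rec.probs]
        return out

    @property
    def directions(self) -> list[tuple[str, str]]:
        return list(self.attentions.keys())


class MissingModalityError(KeyError):
    pass


def collate(samples: list[TCRSample], modalities: list[str],
            vocab: Vocabulary = DEFAULT_VOCAB,
            max_lens: dict | None = None) -> dict:
    """Tokenize samples into a batch: modality -> {ids (B, L), mask (B, L)}."""
    max_lens = max_lens or default_max_lens()
    batch: dict = {}
    for mod in modalities:
        ids, masks = [], []
        for i, s in enumerate(samples):
            seq = s.modality(mod)
            if seq is None:
                raise MissingModalityError(f"sample {i} lacks required modality {mod!r}")
            tok = tokenize(seq, vocab, max_lens[mod])
            ids.append(tok.ids)
            masks.append(tok.attention_mask)
        batch[mod] = {"ids": np.stack(ids), "mask": np.stack(masks)}
    return batch


class MultiModalModel(Module):
    """Generic encoder(+decoder) graph shared by all model families."""

    def __init__(self, modalities: list[str], decoder_specs: list[DecoderSpec],
                 pool_refs: list[tuple[str, str]], config: ModelConfig,
                 card: dict | None = None, expose_encoder_attn: bool = False):
        super().__init__()
        for m in modalities:
            if m not in config.max_lens:
                raise ValueError(f"unknown modality {m!r}; no max length configured")
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.modalities = list(modalities)
        self.decoder_specs = decoder_specs
        self.pool_refs = pool_refs
        self.card = card or {}
        self.expose_encoder_attn = expose_encoder_attn
        d, V = config.hidden_dim, len(config.vocab)
        self.encoders = {
            m: SequenceEncoder(V, config.max_lens[m], d, config.n_layers,
                               config.n_heads, config.ffn, config.dropout, rng)
            for m in modalities
        }
        self.decoders = {s.name: Decoder(d, config.n_layers, config.n_heads,
                                         config.ffn, config.dropout, rng)
                         for s in decoder_specs}
        # per-source segment embeddings for decoders with fused memories
        self.segment_embeds = {
            s.name: nn_Parameter(trunc_normal(rng, (len(s.memory), d)))
            for s in decoder_specs if len(s.memory) > 1
        }
        self.classifier = Linear(d * len(pool_refs), 1, rng)
        self.enc_mlm_heads = {m: Linear(d, V, rng) for m in modalities}
        self.dec_mlm_heads = {s.name: Linear(d, V, rng) for s in decoder_specs}
        self.aux_heads = {}
        for name, labels in config.aux_vocabs.items():
            width = 1 if name == "mhc_class" else len(labels)
            self.aux_heads[name] = Linear(d * len(pool_refs), width, rng)

    # -- wiring helpers -----------------------------------------------------

    def _query_modality(self, ref: tuple[str, str]) -> str:
        """A decoder output stays aligned with its query-side token positions,
        so its modality identity is the query's (transitively)."""
        kind, name = ref
        if kind == "enc":
            return name
        spec = next(s for s in self.decoder_specs if s.name == name)
        return self._query_modality(spec.query)

    @property
    def decoder_directions(self) -> list[tuple[str, str]]:
        out = []
        for s in self.decoder_specs:
            q = self._query_modality(s.query)
            for ref in s.memory:
                out.append((q, self._query_modality(ref)))
        return out

    # -- forward ------------------------------------------------------------

    def forward(self, batch: dict, return_attentions: bool = True) -> ModelOutput:
        for m in self.modalities:
            if m not in batch:
                raise MissingModalityError(f"batch is missing required modality {m!r}")
        feats: dict[tuple[str, str], tuple[Tensor, np.ndarray]] = {}
        for m in self.modalities:
            enc = self.encoders[m]
            feats[("enc", m)] = (enc(batch[m]["ids"], batch[m]["mask"]), batch[m]["mask"])

        self_records: list[CrossAttentionRecord] = []
        if return_attentions and self.expose_encoder_attn:
            for m in self.modalities:
                L = batch[m]["ids"].shape[1]
                self_records.append(CrossAttentionRecord(
                    decoder=f"enc:{m}", q_mod=m, segments=[(m, (0, L))],
                    probs=self.encoders[m].self_attention_probs()))

        cross_records: list[CrossAttentionRecord] = []
        for spec in self.decoder_specs:
            q_feat, q_mask = feats[spec.query]
            mems, mem_masks, k_mods = [], [], []
            for j, ref in enumerate(spec.memory):
                f, mmask = feats[ref]
                if spec.name in self.segment_embeds:
                    seg = embedding(self.segment_embeds[spec.name], np.array([j]))
                    f = f + seg.reshape(1, 1, self.config.hidden_dim)
                mems.append(f)
                mem_masks.append(mmask)
                k_mods.append(self._query_modality(ref))
            memory, mem_mask, spans = concat_memory(mems, mem_masks)
            dec = self.decoders[spec.name]
            out = dec(q_feat, q_mask, memory, mem_mask)
            feats[("dec", spec.name)] = (out, q_mask)
            if return_attentions:
                cross_records.append(CrossAttentionRecord(
                    decoder=spec.name, q_mod=self._query_modality(spec.query),
                    segments=list(zip(k_mods, spans)), probs=dec.cross_attention_probs()))

        pooled = concat([masked_mean_pool(*feats[ref]) for ref in self.pool_refs], axis=-1)
        binder_logit = self.classifier(pooled).reshape(-1)

        mlm_logits = {}
        for m, head in self.enc_mlm_heads.items():
            mlm_logits[("enc", m)] = (head(feats[("enc", m)][0]), m)
        for spec in self.decoder_specs:
            target_mod = self._query_modality(spec.query)
            mlm_logits[("dec", spec.name)] = (
                self.dec_mlm_heads[spec.name](feats[("dec", spec.name)][0]), target_mod)

        aux_logits = {name: head(pooled) for name, head in self.aux_heads.items()}
        if "mhc_class" in aux_logits:
            aux_logits["mhc_class"] = aux_logits["mhc_class"].reshape(-1)

        return ModelOutput(binder_logit=binder_logit, pooled=pooled,
                           mlm_logits=mlm_logits, aux_logits=aux_logits,
                           cross_records=cross_records, self_records=self_records,
                           batch=batch, vocab=self.config.vocab)

    __call__ = forward

    def predict_proba(self, samples: list[TCRSample], batch_size: int = 64) -> np.ndarray:
        """Binding probabilities in eval mode, batched."""
        was_training = self.training
        self.eval()
        probs = []
        for i in range(0, len(samples), batch_size):
            batch = collate(samples[i:i + batch_size], self.modalities,
                            self.config.vocab, self.config.max_lens)
            probs.append(self.forward(batch, return_attentions=False).binder_prob)
        self.train(was_training)
        return np.concatenate(probs)


# ---------------------------------------------------------------------------
# builders


def build_encoder_only(modalities, config: ModelConfig) -> MultiModalModel:
    """One independent, identically configured encoder per modality; pooled
    features concatenated into a linear binder head."""
    mods = list(modalities)
    if not mods:
        raise ValueError("at least one modality is required")
    for m in mods:
        if m not in KNOWN_MODALITIES:
            raise ValueError(f"unknown modality {m!r}; known: {KNOWN_MODALITIES}")
    return MultiModalModel(
        mods, decoder_specs=[], pool_refs=[("enc", m) for m in mods], config=config,
        card={"family": "encoder_only", "modalities": mods}, expose_encoder_attn=True)


def build_probe(query_mod: str, memory_mod: str, residual_mod: Optional[str],
                config: ModelConfig) -> MultiModalModel:
    """Directional probe: decoder self-attends on ``query_mod`` and
    cross-attends into ``memory_mod``; the classifier reads the pooled decoder
    output, plus the pooled encoder features of ``residual_mod`` if given."""
    variant = Probe(query_mod, memory_mod, residual_mod)  # validates
    name = f"{query_mod}->{memory_mod}"
    specs = [DecoderSpec(name, ("enc", query_mod), [("enc", memory_mod)])]
    pool: list[tuple[str, str]] = [("dec", name)]
    if residual_mod is not None:
        pool.append(("enc", residual_mod))
    return MultiModalModel(
        [query_mod, memory_mod], specs, pool, config,
        card={"family": "probe", "query": query_mod, "memory": memory_mod,
              "residual": residual_mod})


def build_egm(variant: str, config: ModelConfig) -> MultiModalModel:
    """Build an EGM-0/1/2 encoder-decoder model over (chain A, chain B, epitope).

    The chain modalities default to the full TCR chains and are configurable
    (e.g. CDR3 loops for small-scale experiments) via ``ModelConfig``.
    """
    if variant not in EGM_VARIANTS:
        raise ValueError(f"unknown EGM variant {variant!r}; expected one of {EGM_VARIANTS}")
    A, B, E = config.chain_a, config.chain_b, config.epitope
    ea, eb, ee = ("enc", A), ("enc", B), ("enc", E)
    if variant == "EGM0":
        specs = [
            DecoderSpec(f"{A}->({B}+{E})", ea, [eb, ee]),
            DecoderSpec(f"{B}->({A}+{E})", eb, [ea, ee]),
            DecoderSpec(f"{E}->({A}+{B})", ee, [ea, eb]),
        ]
        pool = [("dec", s.name) for s in specs]
    else:
        s1a = DecoderSpec(f"s1:{A}->{B}", ea, [eb])   # refined chain A (A')
        s1b = DecoderSpec(f"s1:{B}->{A}", eb, [ea])   # refined chain B (B')
        da, db = ("dec", s1a.name), ("dec", s1b.name)
        e2a = DecoderSpec(f"{E}->{A}'", ee, [da])
        e2b = DecoderSpec(f"{E}->{B}'", ee, [db])
        if variant == "EGM1":
            a2e = DecoderSpec(f"{A}'->{E}", da, [ee])
            b2e = DecoderSpec(f"{B}'->{E}", db, [ee])
        else:  # EGM2: chain-to-epitope decoders also see the complementary chain
            a2e = DecoderSpec(f"{A}'->({E}+{B}')", da, [ee, db])
            b2e = DecoderSpec(f"{B}'->({E}+{A}')", db, [ee, da])
        specs = [s1a, s1b, e2a, e2b, a2e, b2e]
        pool = [("dec", s.name) for s in (e2a, e2b, a2e, b2e)]  # final stage only
    return MultiModalModel([A, B, E], specs, pool, config,
                           card={"family": "egm", "variant": variant,
                                 "chains": (A, B), "epitope": E})


def quality_directions(model: MultiModalModel) -> list[tuple[str, str]]:
    """The four epitope<->chain directions used for explanation quality."""
    c = model.config
    return [(c.epitope, c.chain_a), (c.epitope, c.chain_b),
            (c.chain_a, c.epitope), (c.chain_b, c.epitope)]


# ---------------------------------------------------------------------------
# checkpoint files


def save_checkpoint(model: MultiModalModel, path) -> None:
    """Write parameters (.npz) plus a model-card JSON (family, wiring,
    configuration and vocabulary) next to it."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    cfg = asdict(model.config)
    cfg["vocab"] = list(model.config.vocab.tokens)
    card = {"card": model.card, "config": cfg}
    path.with_suffix(".json").write_text(json.dumps(card))


def load_checkpoint(path) -> MultiModalModel:
    """Rebuild a model from :func:`save_checkpoint` output and load weights."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(meta["config"])
    cfg_dict["vocab"] = Vocabulary(tokens=tuple(cfg_dict["vocab"]))
    config = ModelConfig(**cfg_dict)
    card = meta["card"]
    if card["family"] == "encoder_only":
        model = build_encoder_only(card["modalities"], config)
    elif card["family"] == "probe":
        model = build_probe(card["query"], card["memory"], card["residual"], config)
    elif card["family"] == "egm":
        model = build_egm(card["variant"], config)
    else:
        raise ValueError(f"unknown model family {card['family']!r}")
    with np.load(path.with_suffix(".npz")) as arrays:
        model.load_state_dict(dict(arrays))
    return model
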