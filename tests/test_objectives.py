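"""Loss components: closed forms, masking rules, and gradient isolation."""

import numpy as np
import pytest

from tcrcross import (
    DEFAULT_VOCAB,
    LossConfig,
    ModelConfig,
    SyntheticSpec,
    apply_mlm_mask,
    aux_vocabs_from_samples,
    binder_loss,
    build_egm,
    collate,
    compute_losses,
    mhc_loss,
    mlm_loss,
    simulate_repertoire,
    tokenize,
    total_loss,
    trvj_loss,
)
from tcrcross.nn import Tensor
from tcrcross.objectives import TRVJ_FIELDS

MAX_LENS = {"cdr3a": 14, "cdr3b": 14, "epitope": 11}


class TestBinderLoss:
    def test_logit_zero_label_one_is_ln2(self):
        loss = binder_loss(Tensor(np.array([0.0])), np.array([1]))
        assert np.isclose(float(loss.data), np.log(2), atol=1e-6)

    def test_saturated_logit_near_zero_loss(self):
        loss = binder_loss(Tensor(np.array([20.0])), np.array([1]))
        assert float(loss.data) < 1e-8

    def test_sign_symmetry(self):
        x = np.array([1.7, -0.3])
        a = binder_loss(Tensor(x), np.array([1, 1]))
        b = binder_loss(Tensor(-x), np.array([0, 0]))
        assert np.isclose(float(a.data), float(b.data), rtol=1e-6)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            binder_loss(Tensor(np.array([0.0])), np.array([2]))


class TestApplyMlmMask:
    def test_rate_zero_selects_nothing(self):
        tok = tokenize("CASSLGF", DEFAULT_VOCAB, 12)
        rng = np.random.default_rng(0)
        corrupted, sel = apply_mlm_mask(tok.ids, tok.attention_mask, DEFAULT_VOCAB, 0.0, rng)
        assert sel.sum() == 0 and np.array_equal(corrupted, tok.ids)

    def test_selection_rate_matches_binomial_expectation(self):
        # 100-residue span at rate 0.15, averaged over many draws
        tok = tokenize("A" * 100, DEFAULT_VOCAB, 102)
        rng = np.random.default_rng(1)
        counts = [apply_mlm_mask(tok.ids, tok.attention_mask, DEFAULT_VOCAB, 0.15, rng)[1].sum()
                  for _ in range(2000)]
        se = np.sqrt(100 * 0.15 * 0.85 / 2000)
        assert abs(np.mean(counts) - 15.0) < 4 * se

    def test_specials_never_selected(self):
        tok = tokenize("CASSLGF", DEFAULT_VOCAB, 12)
        rng = np.random.default_rng(2)
        special_pos = np.isin(tok.ids, list(DEFAULT_VOCAB.special_ids))
        for _ in range(500):
            corrupted, sel = apply_mlm_mask(tok.ids, tok.attention_mask,
                                            DEFAULT_VOCAB, 0.9, rng)
            assert not sel[special_pos].any()
            assert np.array_equal(corrupted[special_pos], tok.ids[special_pos])

    def test_corruption_split_80_10_10(self):
        tok = tokenize("A" * 200, DEFAULT_VOCAB, 202)
        rng = np.random.default_rng(3)
        masked = swapped = kept = total = 0
        for _ in range(300):
            corrupted, sel = apply_mlm_mask(tok.ids, tok.attention_mask,
                                            DEFAULT_VOCAB, 0.5, rng)
            total += sel.sum()
            masked += (corrupted[sel] == DEFAULT_VOCAB.mask_id).sum()
            same = corrupted[sel] == tok.ids[sel]
            kept += same.sum()
            swapped += (~same & (corrupted[sel] != DEFAULT_VOCAB.mask_id)).sum()
        assert abs(masked / total - 0.8) < 0.02
        # "random residue" draws may coincide with the original, so kept > 0.10
        assert abs(swapped / total - 0.10 * 19 / 20) < 0.02
        assert abs(kept / total - (0.10 + 0.10 / 20)) < 0.02


class TestMlmLoss:
    def test_uniform_logits_give_log_vocab(self):
        V = len(DEFAULT_VOCAB)
        logits = Tensor(np.zeros((1, 4, V)))
        targets = np.array([[1, 2, 3, 4]])
        positions = np.ones((1, 4), bool)
        assert np.isclose(float(mlm_loss(logits, targets, positions).data), np.log(V))

    def test_peaked_logits_near_zero(self):
        V = len(DEFAULT_VOCAB)
        targets = np.array([[1, 2]])
        logits = np.full((1, 2, V), -50.0)
        logits[0, 0, 1] = logits[0, 1, 2] = 50.0
        assert float(mlm_loss(Tensor(logits), targets, np.ones((1, 2), bool)).data) < 1e-6

    def test_no_positions_gives_zero(self):
        logits = Tensor(np.zeros((1, 3, 25)))
        assert float(mlm_loss(logits, np.zeros((1, 3), int), np.zeros((1, 3), bool)).data) == 0.0


@pytest.fixture(scope="module")
def annotated_samples():
    samples, _ = simulate_repertoire(SyntheticSpec(n_samples=16, label_noise=0.0, seed=2))
    return samples


class TestAuxLosses:
    def test_uniform_logits_closed_form(self, annotated_samples):
        samples = annotated_samples[:4]
        vocab = aux_vocabs_from_samples(samples)
        n_alleles = len(vocab["mhc_allele"])
        aux = {"mhc_class": Tensor(np.zeros(4)),
               "mhc_allele": Tensor(np.zeros((4, n_alleles)))}
        v = float(mhc_loss(aux, samples, vocab["mhc_allele"]).data)
        assert np.isclose(v, np.log(2) + np.log(n_alleles), rtol=1e-5)

    def test_perfect_heads_give_zero(self, annotated_samples):
        samples = annotated_samples[:4]
        vocab = aux_vocabs_from_samples(samples)
        cls = np.array([50.0 if s.mhc_class == "I" else -50.0 for s in samples])
        allele = np.full((4, len(vocab["mhc_allele"])), -50.0)
        for i, s in enumerate(samples):
            allele[i, vocab["mhc_allele"].index(s.mhc_allele)] = 50.0
        aux = {"mhc_class": Tensor(cls), "mhc_allele": Tensor(allele)}
        assert float(mhc_loss(aux, samples, vocab["mhc_allele"]).data) < 1e-5

    def test_loss_monotone_in_correct_logit(self, annotated_samples):
        # allele vocabulary from the full set so the softmax is non-degenerate
        vocab = aux_vocabs_from_samples(annotated_samples)
        samples = annotated_samples[:1]
        idx = vocab["mhc_allele"].index(samples[0].mhc_allele)
        prev = np.inf
        for boost in (0.0, 1.0, 2.0, 4.0):
            allele = np.zeros((1, len(vocab["mhc_allele"])))
            allele[0, idx] = boost
            aux = {"mhc_class": Tensor(np.zeros(1)),
                   "mhc_allele": Tensor(allele)}
            v = float(mhc_loss(aux, samples, vocab["mhc_allele"]).data)
            assert v < prev
            prev = v

    def test_trvj_uniform_closed_form(self, annotated_samples):
        samples = annotated_samples[:4]
        vocabs = aux_vocabs_from_samples(samples)
        aux = {f: Tensor(np.zeros((4, len(vocabs[f])))) for f in TRVJ_FIELDS}
        expected = sum(np.log(len(vocabs[f])) for f in TRVJ_FIELDS)
        assert np.isclose(float(trvj_loss(aux, samples, vocabs).data), expected, rtol=1e-5)

    def test_missing_annotation_is_skipped(self, annotated_samples):
        samples = [annotated_samples[0], annotated_samples[1]]
        samples[1] = type(samples[1])(**{**vars(samples[1]), "trav": None})
        vocabs = aux_vocabs_from_samples(samples)
        aux = {f: Tensor(np.zeros((2, max(1, len(vocabs[f]))))) for f in TRVJ_FIELDS}
        v = float(trvj_loss(aux, samples, vocabs).data)
        assert np.isfinite(v)

    def test_unseen_allele_at_train_time_errors(self, annotated_samples):
        samples = annotated_samples[:2]
        with pytest.raises(KeyError):
            mhc_loss({"mhc_class": Tensor(np.zeros(2)),
                      "mhc_allele": Tensor(np.zeros((2, 1)))},
                     samples, ["NOT-AN-ALLELE"])


class TestTotalLoss:
    def test_unit_weights_sum(self):
        comps = {"a": Tensor(np.asarray(1.5)), "b": Tensor(np.asarray(2.0))}
        assert float(total_loss(comps, LossConfig()).data) == pytest.approx(3.5)

    def test_weighted_sum(self):
        comps = {"a": Tensor(np.asarray(1.0)), "b": Tensor(np.asarray(4.0))}
        cfg = LossConfig(weights={"b": 0.25})
        assert float(total_loss(comps, cfg).data) == pytest.approx(2.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss({"a": Tensor(np.asarray(1.0))}, LossConfig(weights={"a": -1}))


class TestGradientIsolation:
    """With decoder MLM off, no MLM term may reach decoder parameters."""

    def _setup(self, mlm_on_decoders):
        samples, _ = simulate_repertoire(SyntheticSpec(n_samples=8, label_noise=0.0, seed=4))
        cfg = ModelConfig(hidden_dim=16, n_layers=1, n_heads=1, ffn_dim=32, dropout=0.0,
                          chain_a="cdr3a", chain_b="cdr3b", max_lens=dict(MAX_LENS), seed=0)
        model = build_egm("EGM1", cfg)
        batch = collate(samples, model.modalities, max_lens=MAX_LENS)
        rng = np.random.default_rng(0)
        mlm_targets = {}
        corrupted_batch = {}
        for mod in model.modalities:
            ids, mask = batch[mod]["ids"], batch[mod]["mask"]
            corrupted, sel = apply_mlm_mask(ids, mask, DEFAULT_VOCAB, 0.3, rng)
            mlm_targets[mod] = (ids, sel)
            corrupted_batch[mod] = {"ids": corrupted, "mask": mask}
        lc = LossConfig(mlm_on_decoders=mlm_on_decoders)
        out = model.forward(corrupted_batch)
        comps = compute_losses(model, out, corrupted_batch, samples,
                               np.array([s.label for s in samples]), mlm_targets, lc)
        return model, comps

    def _decoder_params(self, model):
        return [p for name, p in model.named_parameters() if name.startswith("decoders.")]

    def test_decoders_get_no_mlm_gradient_when_disabled(self):
        model, comps = self._setup(mlm_on_decoders=False)
        assert "mlm_decoders" not in comps
        comps["mlm_encoders"].backward()
        for p in self._decoder_params(model):
            assert p.grad is None or not np.any(p.grad)

    def test_decoders_do_get_gradient_when_enabled(self):
        model, comps = self._setup(mlm_on_decoders=True)
        comps["mlm_decoders"].backward()
        assert any(p.grad is not None and np.any(p.grad)
                   for p in self._decoder_params(model))
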