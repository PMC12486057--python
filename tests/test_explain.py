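"""Importance extraction, NA handling, smoothing, and explainer dispatch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrcross import (
    ExplainerSpec,
    ImportanceVector,
    ModelConfig,
    SyntheticSpec,
    attention_importance,
    build_egm,
    build_probe,
    clean_scores,
    explain,
    register_explainer,
    simulate_repertoire,
    smooth_scores,
)
from tcrcross.explain import EXPLAINER_REGISTRY

MAX_LENS = {"cdr3a": 14, "cdr3b": 14, "epitope": 11}


def small_config(seed=0):
    return ModelConfig(hidden_dim=16, n_layers=1, n_heads=1, ffn_dim=32, dropout=0.0,
                       chain_a="cdr3a", chain_b="cdr3b", max_lens=dict(MAX_LENS), seed=seed)


@pytest.fixture(scope="module")
def sample():
    samples, truth = simulate_repertoire(SyntheticSpec(n_samples=10, label_noise=0.0, seed=0))
    return next(s for s in samples if s.label == 1)


class TestSmoothing:
    def test_impulse_response(self):
        v = ImportanceVector(("a", "b"), np.array([0.0, 0, 3, 0, 0]))
        np.testing.assert_allclose(smooth_scores(v).scores, [0, 1, 1, 1, 0])

    def test_na_then_smooth(self):
        v = ImportanceVector(("a", "b"), np.array([np.nan, 3.0, np.nan]))
        out = smooth_scores(clean_scores(v))
        np.testing.assert_allclose(out.scores, [1, 1, 1])

    def test_all_zero_stays_zero(self):
        v = ImportanceVector(("a", "b"), np.zeros(7))
        assert not smooth_scores(v).scores.any()

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            smooth_scores(ImportanceVector(("a", "b"), np.array([])))

    def test_nan_input_rejected(self):
        with pytest.raises(ValueError):
            smooth_scores(ImportanceVector(("a", "b"), np.array([1.0, np.nan])))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=30),
           st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, xs, a, b):
        x = np.array(xs)
        y = np.roll(x, 1)
        lhs = smooth_scores(ImportanceVector(("q", "k"), a * x + b * y)).scores
        rhs = (a * smooth_scores(ImportanceVector(("q", "k"), x)).scores
               + b * smooth_scores(ImportanceVector(("q", "k"), y)).scores)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-8, atol=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=30))
    def test_bounds_for_nonnegative_input(self, xs):
        x = np.array(xs)
        out = smooth_scores(ImportanceVector(("q", "k"), x)).scores
        assert out.max() <= x.max() + 1e-9
        assert out.min() >= -1e-12


class TestAttentionImportance:
    def _output_with_map(self, rows):
        """Fabricate a ModelOutput-like object carrying one cross map."""
        from tcrcross.models import CrossAttentionRecord, ModelOutput
        from tcrcross.nn import Tensor
        from tcrcross.repertoire import DEFAULT_VOCAB, tokenize

        rows = np.asarray(rows, dtype=float)
        Lq, Lk = rows.shape
        # wrap residue-level map with BOS/EOS rows/cols so stripping is exercised
        full = np.zeros((1, 1, Lq + 2, Lk + 2))
        full[0, 0, 1:1 + Lq, 1:1 + Lk] = rows
        rec = CrossAttentionRecord("d", "epitope", [("cdr3b", (0, Lk + 2))],
                                   [Tensor(full)])
        batch = {
            "epitope": {"ids": tokenize("A" * Lq, DEFAULT_VOCAB, Lq + 2).ids[None],
                        "mask": np.ones((1, Lq + 2), np.int8)},
            "cdr3b": {"ids": tokenize("A" * Lk, DEFAULT_VOCAB, Lk + 2).ids[None],
                      "mask": np.ones((1, Lk + 2), np.int8)},
        }
        return ModelOutput(binder_logit=Tensor(np.zeros(1)), pooled=Tensor(np.zeros((1, 1))),
                           mlm_logits={}, aux_logits={}, cross_records=[rec],
                           self_records=[], batch=batch)

    def test_single_query_row_passthrough(self):
        out = self._output_with_map([[0.2, 0.5, 0.3]])
        v = attention_importance(out, ("epitope", "cdr3b"),
                                 ExplainerSpec(smoothing=False))
        np.testing.assert_allclose(v.scores, [0.2, 0.5, 0.3])

    def test_mean_over_query_rows(self):
        out = self._output_with_map([[1, 0, 0], [0, 0, 1]])
        v = attention_importance(out, ("epitope", "cdr3b"), ExplainerSpec())
        np.testing.assert_allclose(v.scores, [0.5, 0, 0.5])

    def test_na_becomes_zero(self):
        out = self._output_with_map([[np.nan, 0.5, 0.5]])
        v = attention_importance(out, ("epitope", "cdr3b"), ExplainerSpec())
        np.testing.assert_allclose(v.scores, [0, 0.5, 0.5])

    def test_reverse_direction_derived_from_native_map(self):
        out = self._output_with_map([[1, 0, 0], [0, 0, 1]])
        v = attention_importance(out, ("cdr3b", "epitope"),
                                 ExplainerSpec(query_reduction="max"))
        # scores over epitope residues (the native query side)
        np.testing.assert_allclose(v.scores, [1, 1])

    def test_unavailable_direction_lists_alternatives(self):
        out = self._output_with_map([[1.0]])
        with pytest.raises(KeyError, match="epitope"):
            attention_importance(out, ("cdr3a", "cdr3b"), ExplainerSpec())


class TestExplain:
    def test_vectors_cover_all_directions_and_lengths(self, sample):
        model = build_egm("EGM1", small_config())
        vecs = explain(model, sample, ExplainerSpec())
        assert ("epitope", "cdr3a") in vecs and ("cdr3a", "epitope") in vecs
        assert vecs[("epitope", "cdr3b")].length == len(sample.cdr3b)
        assert vecs[("cdr3b", "epitope")].length == len(sample.epitope)
        for v in vecs.values():
            assert np.isfinite(v.scores).all()

    def test_attention_method_deterministic(self, sample):
        model = build_egm("EGM2", small_config())
        a = explain(model, sample, ExplainerSpec())
        b = explain(model, sample, ExplainerSpec())
        for d in a:
            np.testing.assert_array_equal(a[d].scores, b[d].scores)

    def test_grad_x_attention_differs_from_attention(self, sample):
        model = build_probe("epitope", "cdr3b", "epitope", small_config())
        plain = explain(model, sample, ExplainerSpec(smoothing=False))
        grad = explain(model, sample, ExplainerSpec(method="grad_x_attention",
                                                    smoothing=False))
        d = ("epitope", "cdr3b")
        assert grad[d].scores.shape == plain[d].scores.shape
        assert not np.allclose(grad[d].scores, plain[d].scores)

    def test_grad_method_nonzero_on_stage1_decoders(self, sample):
        model = build_egm("EGM1", small_config())
        grad = explain(model, sample, ExplainerSpec(method="grad_x_attention",
                                                    smoothing=False))
        assert np.any(grad[("cdr3a", "cdr3b")].scores != 0)

    def test_external_explainer_registry(self, sample):
        model = build_probe("epitope", "cdr3b", None, small_config())
        with pytest.raises(KeyError):
            explain(model, sample, ExplainerSpec(method="my_lrp"))
        marker = {}

        def fake(model, sample, spec):
            marker["called"] = True
            return {}

        register_explainer("my_lrp", fake)
        try:
            explain(model, sample, ExplainerSpec(method="my_lrp"))
            assert marker["called"]
        finally:
            EXPLAINER_REGISTRY.pop("my_lrp")
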