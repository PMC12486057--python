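"""Binding Region Hit Rate: oracle equivalence, calibration, invariances,
structural distance extraction, and dataset-level aggregation."""

import math

import numpy as np
import pytest

from tcrcross import (
    DistanceStore,
    ExplainerSpec,
    ModelConfig,
    SyntheticSpec,
    binding_region_hit_rate,
    build_distance_store,
    build_egm,
    dataset_brhr,
    explanation_quality,
    interaction_distances,
    quality_directions,
    simulate_repertoire,
)

MAX_LENS = {"cdr3a": 14, "cdr3b": 14, "epitope": 11}


def brute_force_hit_rate(scores, dists, t):
    """Independent oracle: enumerate both top-k sets explicitly."""
    n = len(scores)
    k = math.ceil(t * n)
    by_score = sorted(range(n), key=lambda i: (-scores[i], i))[:k]
    by_dist = sorted(range(n), key=lambda i: (dists[i], i))[:k]
    return len(set(by_score) & set(by_dist)) / k


class TestBindingRegionHitRate:
    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 13))
            scores = rng.normal(size=n)
            dists = rng.uniform(1, 30, size=n)
            if rng.random() < 0.3:  # exercise tie-breaking
                scores = np.round(scores)
                dists = np.round(dists)
            for t in (0.25, 0.5, 1.0):
                assert binding_region_hit_rate(scores, dists, t) == \
                    brute_force_hit_rate(scores, dists, t)

    def test_negated_distances_give_one_for_all_t(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(2, 30, size=17)
        for t in (0.1, 0.25, 0.5, 0.75, 1.0):
            assert binding_region_hit_rate(-d, d, t) == 1.0

    def test_single_slot_miss_is_zero(self):
        scores = np.array([0.0, 9.0, 1.0, 1.0])
        dists = np.array([1.0, 20.0, 20.0, 20.0])  # argmin 0 != argmax 1
        assert binding_region_hit_rate(scores, dists, 0.25) == 0.0

    def test_worked_example_partial_overlap(self):
        scores = [9, 1, 8, 1, 1, 1, 1, 1]
        dists = [3.0, 4.0, 20, 20, 20, 20, 20, 20]
        assert binding_region_hit_rate(scores, dists, 0.25) == 0.5

    def test_random_scores_mean_is_hypergeometric(self):
        # independent rankings: E[rate] = k/n
        rng = np.random.default_rng(7)
        n, t = 20, 0.25
        k = math.ceil(t * n)
        dists = rng.uniform(1, 30, size=n)
        rates = [binding_region_hit_rate(rng.normal(size=n), dists, t)
                 for _ in range(10_000)]
        var = (k / n) * (1 - k / n) * (n - k) / (n - 1) / k
        se = np.sqrt(var / len(rates))
        assert abs(np.mean(rates) - k / n) < 3 * se

    def test_t_one_always_full_overlap(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(1, 15))
            assert binding_region_hit_rate(rng.normal(size=n),
                                           rng.uniform(1, 9, n), 1.0) == 1.0

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=12)
        dists = rng.uniform(1, 30, size=12)
        base = binding_region_hit_rate(scores, dists, 0.25)
        assert binding_region_hit_rate(np.exp(scores), dists, 0.25) == base
        assert binding_region_hit_rate(scores, np.log(dists), 0.25) == base

    def test_errors(self):
        with pytest.raises(ValueError):
            binding_region_hit_rate([1.0], [1.0, 2.0], 0.25)
        with pytest.raises(ValueError):
            binding_region_hit_rate([], [], 0.25)
        with pytest.raises(ValueError):
            binding_region_hit_rate([1.0], [1.0], 0.0)


# a tiny two-chain complex: chain E residues approach chain B increasingly
SYNTHETIC_PDB = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  ALA E   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA E   1       0.000   1.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY E   2       4.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER E   3       9.000   0.000   0.000  1.00  0.00           C
ATOM      5  H   SER E   3      20.000   0.000   0.000  1.00  0.00           H
ATOM      6  CA  LEU B   1       0.000   4.000   0.000  1.00  0.00           C
ATOM      7  CA  VAL B   2       4.000   4.000   0.000  1.00  0.00           C
TER
END
"""


class TestInteractionDistances:
    @pytest.fixture
    def pdb(self, tmp_path):
        p = tmp_path / "synthetic_complex.pdb"
        p.write_text(SYNTHETIC_PDB)
        return p

    def test_min_heavy_atom_distances(self, pdb):
        rd = interaction_distances(pdb, {"epitope": "E", "cdr3b": "B"},
                                   ("cdr3b", "epitope"))
        # E1 is 3 A from B1 (via its CB atom), E2 is 4 A from B2,
        # E3's nearest heavy atom sits sqrt(5^2 + 4^2) from B2
        np.testing.assert_allclose(rd.distances, [3.0, 4.0, np.sqrt(41.0)])
        assert rd.index_map.tolist() == [0, 1, 2]

    def test_hydrogens_ignored(self, pdb):
        rd = interaction_distances(pdb, {"epitope": "E", "cdr3b": "B"},
                                   ("cdr3b", "epitope"))
        # the H atom of SER E3 at x=20 is over 16 A from chain B; if hydrogens
        # counted, min would still be the CA, but the CA itself must be used
        assert rd.distances[2] == pytest.approx(np.sqrt(41.0))

    def test_two_residue_chain_both_sides(self, pdb):
        rd = interaction_distances(pdb, {"epitope": "E", "cdr3b": "B"},
                                   ("epitope", "cdr3b"))
        np.testing.assert_allclose(rd.distances, [3.0, 4.0])

    def test_missing_chain_errors(self, pdb):
        with pytest.raises(KeyError):
            interaction_distances(pdb, {"epitope": "E", "cdr3b": "Z"},
                                  ("epitope", "cdr3b"))


@pytest.fixture(scope="module")
def model_and_data():
    samples, truth = simulate_repertoire(
        SyntheticSpec(n_samples=40, label_noise=0.0, seed=6))
    cfg = ModelConfig(hidden_dim=16, n_layers=1, n_heads=1, ffn_dim=32,
                      dropout=0.0, chain_a="cdr3a", chain_b="cdr3b",
                      max_lens=dict(MAX_LENS), seed=0)
    model = build_egm("EGM1", cfg)
    store = build_distance_store(samples, truth, quality_directions(model), seed=0)
    return model, samples, truth, store


class TestDatasetBRHR:

    def test_no_predicted_binders_gives_empty_report(self, model_and_data):
        model, samples, _, store = model_and_data
        report = dataset_brhr(model, samples, store, ExplainerSpec(),
                              binder_threshold=1.1)  # nothing exceeds 1.1
        assert report.n_samples_used == 0
        assert all(np.isnan(v) for v in report.per_direction_mean.values())

    def test_perfect_standin_scores_give_rate_one(self, model_and_data):
        """Scores equal to negated distances must yield mean 1.0 everywhere."""
        from tcrcross import register_explainer
        from tcrcross.explain import EXPLAINER_REGISTRY, ImportanceVector
        model, samples, truth, store = model_and_data

        ids = {id(s): i for i, s in enumerate(samples)}

        def perfect(model, sample, spec):
            i = ids[id(sample)]
            out = {}
            for d in quality_directions(model):
                dist = store.get(i, d)
                if dist is not None:
                    out[d] = ImportanceVector(d, -np.asarray(dist))
            return out

        register_explainer("perfect", perfect)
        try:
            report = dataset_brhr(model, samples, store,
                                  ExplainerSpec(method="perfect"),
                                  binder_threshold=0.0)
            used = {d: v for d, v in report.per_direction_mean.items()
                    if report.per_sample[d]}
            assert used and all(v == 1.0 for v in used.values())
        finally:
            EXPLAINER_REGISTRY.pop("perfect")

    def test_mean_of_per_sample_rates(self):
        from tcrcross.brhr import BRHRReport
        report = BRHRReport(t=0.25, n_samples_used=2,
                            per_direction_mean={("a", "b"): 0.75},
                            per_sample={("a", "b"): [1.0, 0.5]})
        assert np.mean(report.per_sample[("a", "b")]) == report.per_direction_mean[("a", "b")]

    def test_explanation_quality_nan_when_direction_empty(self, model_and_data):
        model, samples, _, store = model_and_data
        empty = DistanceStore()  # no distances at all -> every direction empty
        with pytest.warns(UserWarning):
            q = explanation_quality(model, samples[:4], empty)
        assert np.isnan(q)

    def test_report_csv_round_trip(self, model_and_data, tmp_path):
        import pandas as pd
        model, samples, _, store = model_and_data
        report = dataset_brhr(model, samples[:10], store, ExplainerSpec(),
                              binder_threshold=0.0)
        p = tmp_path / "report.csv"
        report.to_csv(p)
        df = pd.read_csv(p)
        assert set(df.columns) == {"direction", "mean_brhr", "n"}
        assert len(df) == 4
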