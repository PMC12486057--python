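"""Binding Region Hit Rate (BRHR): structure-grounded explanation quality.

For a directed interaction, per-residue importance scores are compared with
per-residue structural interaction distances (minimum heavy-atom distance from
each target-chain residue to the partner chain). With a percentile threshold
``t``, the top ``k = ceil(t * n)`` residues by importance are intersected with
the top ``k`` residues by closeness; the hit rate is the intersection size
over ``k``. Rates are computed per (sample, direction) for samples the model
predicts as binders, then averaged. The default ``t = 0.25`` is the strictest
threshold that still guarantees at least one selected residue per sequence.

Explanation quality for checkpoint selection is the mean BRHR over the four
epitope<->chain directions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .explain import (
    ExplainerSpec,
    ImportanceVector,
    attention_importance,
    clean_scores,
    explain,
    smooth_scores,
)
from .models import MultiModalModel, collate, quality_directions
from .repertoire import TCRSample


@dataclass
class ResidueDistances:
    """Minimum inter-chain heavy-atom distance (Angstrom) per target residue."""

    direction: tuple[str, str]
    distances: np.ndarray
    structure_id: str = ""
    index_map: np.ndarray | None = None  # original residue index per entry

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)


def _direction_key(direction: tuple[str, str]) -> str:
    return f"{direction[0]}->{direction[1]}"


class DistanceStore:
    """Per-sample, per-direction distance vectors with a JSON round trip."""

    def __init__(self):
        self._data: dict[str, dict[str, list[float]]] = {}

    def put(self, sample_id, direction: tuple[str, str], distances) -> None:
        self._data.setdefault(str(sample_id), {})[_direction_key(direction)] = \
            [float(x) for x in np.asarray(distances)]

    def get(self, sample_id, direction: tuple[str, str]) -> np.ndarray | None:
        entry = self._data.get(str(sample_id), {}).get(_direction_key(direction))
        return None if entry is None else np.asarray(entry)

    def sample_ids(self) -> list[str]:
        return list(self._data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._data))

    @classmethod
    def from_json(cls, path: str | Path) -> "DistanceStore":
        store = cls()
        store._data = json.loads(Path(path).read_text())
        return store


def interaction_distances(structure_path: str | Path,
                          chain_assignment: dict[str, str],
                          direction: tuple[str, str]) -> ResidueDistances:
    """Per-residue minimum heavy-atom distances from a PDB/mmCIF structure.

    For each residue of the target chain (``direction[1]``), the distance is
    the minimum over its heavy atoms to any heavy atom of the source chain.
    Residues with no resolved heavy atoms are excluded; ``index_map`` records
    the surviving residue indices.
    """
    import gemmi

    source_mod, target_mod = direction
    for mod in (source_mod, target_mod):
        if mod not in chain_assignment:
            raise KeyError(f"chain assignment lacks modality {mod!r}")
    st = gemmi.read_structure(str(structure_path))
    st.setup_entities()
    model = st[0]
    chains = {c.name: c for c in model}
    for mod in (source_mod, target_mod):
        if chain_assignment[mod] not in chains:
            raise KeyError(f"chain {chain_assignment[mod]!r} not present in structure")

    def heavy_coords(residue):
        return np.array([[a.pos.x, a.pos.y, a.pos.z] for a in residue
                         if a.element.name != "H"])

    source_atoms = [heavy_coords(r) for r in chains[chain_assignment[source_mod]]]
    source_atoms = [a for a in source_atoms if len(a)]
    if not source_atoms:
        raise ValueError("source chain has no resolved heavy atoms")
    source_xyz = np.concatenate(source_atoms)

    dists, index_map = [], []
    for i, residue in enumerate(chains[chain_assignment[target_mod]]):
        xyz = heavy_coords(residue)
        if len(xyz) == 0:
            continue
        diff = xyz[:, None, :] - source_xyz[None, :, :]
        dists.append(float(np.sqrt((diff**2).sum(-1)).min()))
        index_map.append(i)
    if not dists:
        raise ValueError("target chain has no resolvable residues")
    return ResidueDistances(direction=direction, distances=np.array(dists),
                            structure_id=st.name or str(structure_path),
                            index_map=np.array(index_map))


def _top_k(values: np.ndarray, k: int, largest: bool) -> set[int]:
    order = np.argsort(-values if largest else values, kind="stable")
    return set(order[:k].tolist())


def binding_region_hit_rate(scores, dists, t: float = 0.25) -> float:
    """|top-k by importance  ∩  top-k by closeness| / k, with k = ceil(t * n).

    Ties are broken toward the lower residue index in both rankings.
    """
    s = scores.scores if isinstance(scores, ImportanceVector) else np.asarray(scores, float)
    d = dists.distances if isinstance(dists, ResidueDistances) else np.asarray(dists, float)
    if len(s) != len(d):
        raise ValueError(f"scores ({len(s)}) and distances ({len(d)}) differ in length")
    n = len(s)
    if n == 0:
        raise ValueError("empty inputs")
    if not (0.0 < t <= 1.0):
        raise ValueError("t must be in (0, 1]")
    k = math.ceil(t * n)
    hits = _top_k(s, k, largest=True) & _top_k(d, k, largest=False)
    return len(hits) / k


@dataclass
class BRHRReport:
    t: float
    n_samples_used: int
    per_direction_mean: dict[tuple[str, str], float] = field(default_factory=dict)
    per_sample: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [{"direction": _direction_key(d), "mean_brhr": m,
                 "n": len(self.per_sample.get(d, []))}
                for d, m in self.per_direction_mean.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


def dataset_brhr(model: MultiModalModel, samples: list[TCRSample],
                 distance_store: DistanceStore, spec: ExplainerSpec | None = None,
                 t: float = 0.25, directions: list[tuple[str, str]] | None = None,
                 sample_ids: list | None = None, batch_size: int = 64,
                 binder_threshold: float = 0.5) -> BRHRReport:
    """Mean per-(sample, direction) hit rates over predicted binders.

    ``sample_ids`` aligns samples with the distance store (defaults to their
    positions). Samples with ``p_bind <= binder_threshold`` are skipped; if no
    sample is predicted as a binder the report is empty with NaN means.
    """
    spec = spec or ExplainerSpec()
    ids = [str(i) for i in (sample_ids if sample_ids is not None else range(len(samples)))]
    if directions is None:
        directions = quality_directions(model)

    was_training = model.training
    model.eval()
    per_sample: dict[tuple[str, str], list[float]] = {d: [] for d in directions}
    used: set[int] = set()
    try:
        for lo in range(0, len(samples), batch_size):
            chunk = samples[lo:lo + batch_size]
            if spec.method == "attention":
                batch = collate(chunk, model.modalities, model.config.vocab,
                                model.config.max_lens)
                output = model.forward(batch, return_attentions=True)
                probs = output.binder_prob
                for j, p in enumerate(probs):
                    if p <= binder_threshold:
                        continue
                    i = lo + j
                    for d in directions:
                        dist = distance_store.get(ids[i], d)
                        if dist is None:
                            continue
                        v = clean_scores(attention_importance(output, d, spec, j))
                        if spec.smoothing:
                            v = smooth_scores(v)
                        per_sample[d].append(binding_region_hit_rate(v, dist, t))
                        used.add(i)
            else:
                for j, sample in enumerate(chunk):
                    i = lo + j
                    prob = model.predict_proba([sample])[0]
                    if prob <= binder_threshold:
                        continue
                    vectors = explain(model, sample, spec)
                    for d in directions:
                        dist = distance_store.get(ids[i], d)
                        if dist is None or d not in vectors:
                            continue
                        per_sample[d].append(binding_region_hit_rate(vectors[d], dist, t))
                        used.add(i)
    finally:
        model.train(was_training)

    means = {d: (float(np.mean(v)) if v else float("nan")) for d, v in per_sample.items()}
    return BRHRReport(t=t, n_samples_used=len(used),
                      per_direction_mean=means, per_sample=per_sample)


def explanation_quality(model: MultiModalModel, samples: list[TCRSample],
                        distance_store: DistanceStore,
                        spec: ExplainerSpec | None = None, t: float = 0.25) -> float:
    """Mean BRHR over the four epitope<->chain directions; NaN when any
    direction has no predicted binder with distances."""
    report = dataset_brhr(model, samples, distance_store, spec, t,
                          directions=quality_directions(model))
    values = list(report.per_direction_mean.values())
    if any(np.isnan(v) for v in values):
        warnings.warn("explanation quality undefined: a direction has no scored binder")
        return float("nan")
    return float(np.mean(values))
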