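"""Assay-table I/O, sequence canonicalization, tokenization, negative
sampling and cross-validation folds for TCR-pMHC binding data.

A sample couples a T cell receptor (alpha/beta chains and their CDR loops),
an epitope peptide, MHC metadata and V/J gene-segment labels with a binary
binder label. Tables follow the column style of public assay exports
(VDJdb / McPAS-TCR / IEDB); column-name aliases are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_RESIDUE = "X"  # canonical placeholder for any non-standard residue

SEQUENCE_FIELDS = ("tcra_seq", "tcrb_seq", "cdr1a", "cdr2a", "cdr3a",
                   "cdr1b", "cdr2b", "cdr3b", "epitope")
CATEGORY_FIELDS = ("mhc_class", "mhc_allele", "trav", "traj", "trbv", "trbj", "species")

#: canonical field -> accepted header aliases (lower-cased, punctuation stripped)
DEFAULT_ALIASES = {
    "tcra_seq": ["tcra_seq", "tcra", "tcr_alpha", "alpha_seq", "va_seq"],
    "tcrb_seq": ["tcrb_seq", "tcrb", "tcr_beta", "beta_seq", "vb_seq"],
    "cdr1a": ["cdr1a", "cdr1_alpha", "cdr1a_seq"],
    "cdr2a": ["cdr2a", "cdr2_alpha", "cdr2a_seq"],
    "cdr3a": ["cdr3a", "cdr3_alpha", "cdr3a_seq", "cdr3alpha"],
    "cdr1b": ["cdr1b", "cdr1_beta", "cdr1b_seq"],
    "cdr2b": ["cdr2b", "cdr2_beta", "cdr2b_seq"],
    "cdr3b": ["cdr3b", "cdr3_beta", "cdr3b_seq", "cdr3beta", "cdr3"],
    "epitope": ["epitope", "peptide", "antigen_epitope", "epitope_seq"],
    "mhc_class": ["mhc_class", "mhcclass", "mhc_category"],
    "mhc_allele": ["mhc_allele", "mhc", "mhca", "hla"],
    "trav": ["trav", "v_alpha", "va_gene"],
    "traj": ["traj", "j_alpha", "ja_gene"],
    "trbv": ["trbv", "v_beta", "vb_gene"],
    "trbj": ["trbj", "j_beta", "jb_gene"],
    "species": ["species", "organism"],
    "label": ["label", "binder", "binds", "class", "sign"],
}

_POSITIVE_LABELS = {"binder", "1", "true", "positive", "pos", "yes"}
_NEGATIVE_LABELS = {"nonbinder", "non-binder", "0", "false", "negative", "neg", "no"}


class FormatError(ValueError):
    """Malformed input table (missing column, bad label value, ...)."""


class EmptyInputError(ValueError):
    """Input table contains no data rows."""


class InfeasibleSamplingError(ValueError):
    """Negative sampling cannot satisfy its constraints on this input."""


@dataclass
class TCRSample:
    """One TCR-pMHC assay record. Optional fields are ``None`` when absent."""

    epitope: str
    cdr3b: str | None = None
    cdr3a: str | None = None
    tcra_seq: str | None = None
    tcrb_seq: str | None = None
    cdr1a: str | None = None
    cdr2a: str | None = None
    cdr1b: str | None = None
    cdr2b: str | None = None
    mhc_class: str | None = None
    mhc_allele: str | None = None
    trav: str | None = None
    traj: str | None = None
    trbv: str | None = None
    trbj: str | None = None
    species: str | None = None
    label: int = 1  # 1 = binder, 0 = nonbinder

    def modality(self, name: str) -> str | None:
        """Sequence for a modality name ('epitope', 'cdr3b', 'tcra', ...)."""
        key = {"tcra": "tcra_seq", "tcrb": "tcrb_seq"}.get(name, name)
        return getattr(self, key)

    def tcr_identity(self) -> tuple:
        """Identity used for duplicate checks; absent fields are ignored."""
        return tuple((f, getattr(self, f)) for f in ("tcra_seq", "tcrb_seq", "cdr3a", "cdr3b")
                     if getattr(self, f) is not None)


def canonicalize(seq: str | None, warn_context: str = "") -> str | None:
    """Upper-case and map residues outside the 20-letter alphabet to 'X'.

    Gap characters and the ambiguity codes B/J/O/U/X/Z are all treated as an
    unknown residue; the tokenizer maps 'X' to the UNK token.
    """
    if seq is None:
        return None
    if isinstance(seq, float) and np.isnan(seq):
        return None
    s = str(seq).strip().upper()
    if not s:
        return None
    if any(c not in AMINO_ACIDS for c in s):
        logger.warning("non-standard residues in %r%s mapped to %s",
                       s, f" ({warn_context})" if warn_context else "", UNKNOWN_RESIDUE)
        s = "".join(c if c in AMINO_ACIDS else UNKNOWN_RESIDUE for c in s)
    return s


def parse_label(value) -> int:
    s = str(value).strip().lower()
    if s in _POSITIVE_LABELS:
        return 1
    if s in _NEGATIVE_LABELS:
        return 0
    raise FormatError(f"unrecognized binder label {value!r}")


# ---------------------------------------------------------------------------
# vocabulary / tokenization


@dataclass(frozen=True)
class Vocabulary:
    """20 amino acids followed by PAD/BOS/EOS/MASK/UNK, indices from 0."""

    tokens: tuple = tuple(AMINO_ACIDS) + ("<pad>", "<bos>", "<eos>", "<mask>", "<unk>")

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index["<pad>"]

    @property
    def bos_id(self) -> int:
        return self.index["<bos>"]

    @property
    def eos_id(self) -> int:
        return self.index["<eos>"]

    @property
    def mask_id(self) -> int:
        return self.index["<mask>"]

    @property
    def unk_id(self) -> int:
        return self.index["<unk>"]

    @property
    def special_ids(self) -> frozenset:
        return frozenset({self.pad_id, self.bos_id, self.eos_id, self.mask_id, self.unk_id})

    def residue_id(self, c: str) -> int:
        return self.index.get(c, self.unk_id)


DEFAULT_VOCAB = Vocabulary()


@dataclass
class TokenSequence:
    ids: np.ndarray
    attention_mask: np.ndarray

    @property
    def length(self) -> int:
        return int(self.attention_mask.sum())


def tokenize(seq: str, vocab: Vocabulary = DEFAULT_VOCAB, max_len: int = 25) -> TokenSequence:
    """[BOS] + residues + [EOS], right-padded to ``max_len``.

    Truncation keeps the leftmost ``max_len - 2`` residues plus both specials.
    """
    if max_len < 3:
        raise ValueError("max_len must be at least 3 (BOS + one slot + EOS)")
    residues = [vocab.residue_id(c) for c in (seq or "")][: max_len - 2]
    ids = [vocab.bos_id] + residues + [vocab.eos_id]
    mask = [1] * len(ids)
    pad = max_len - len(ids)
    ids += [vocab.pad_id] * pad
    mask += [0] * pad
    return TokenSequence(np.array(ids, dtype=np.int64), np.array(mask, dtype=np.int8))


def detokenize(tok: TokenSequence, vocab: Vocabulary = DEFAULT_VOCAB) -> str:
    out = []
    for i in tok.ids[: tok.length]:
        i = int(i)
        if i == vocab.unk_id:
            out.append(UNKNOWN_RESIDUE)
        elif i not in vocab.special_ids:
            out.append(vocab.tokens[i])
    return "".join(out)


# ---------------------------------------------------------------------------
# table I/O


def _normalize_header(name: str) -> str:
    return "".join(c for c in name.lower() if c.isalnum() or c == "_")


def read_samples(path: str | Path, dialect: str = "csv",
                 column_map: dict[str, str] | None = None) -> list[TCRSample]:
    """Read an assay table into ``TCRSample`` records, preserving row order.

    ``column_map`` maps file headers to canonical field names and takes
    precedence over the built-in aliases. The epitope, cdr3b and label
    columns are mandatory.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")
    rename: dict[str, str] = {}
    explicit = {k: v for k, v in (column_map or {}).items()}
    for col in df.columns:
        if col in explicit:
            rename[col] = explicit[col]
            continue
        norm = _normalize_header(col)
        for canon, aliases in DEFAULT_ALIASES.items():
            if norm in aliases:
                rename[col] = canon
                break
    df = df.rename(columns=rename)
    for mandatory in ("epitope", "cdr3b", "label"):
        if mandatory not in df.columns:
            raise FormatError(f"missing mandatory column: {mandatory}")
    samples = []
    for idx, row in df.iterrows():
        kwargs = {}
        for f in SEQUENCE_FIELDS:
            if f in df.columns:
                kwargs[f] = canonicalize(row[f], warn_context=f"row {idx}, column {f}")
        for f in CATEGORY_FIELDS:
            if f in df.columns and pd.notna(row[f]):
                kwargs[f] = str(row[f]).strip()
        kwargs["label"] = parse_label(row["label"])
        if not kwargs.get("epitope"):
            raise FormatError(f"row {idx}: empty epitope")
        samples.append(TCRSample(**kwargs))
    return samples


def write_samples(samples: list[TCRSample], path: str | Path,
                  provenance: list[str] | None = None) -> None:
    """Write a canonical CSV; ``provenance`` tags rows as observed vs sampled."""
    rows = []
    for i, s in enumerate(samples):
        row = {f.name: getattr(s, f.name) for f in dc_fields(s)}
        row["label"] = "binder" if s.label == 1 else "nonbinder"
        if provenance is not None:
            row["provenance"] = provenance[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# negative sampling


def generate_negatives(positives: list[TCRSample], seed: int) -> list[TCRSample]:
    """Pair observed TCRs with pMHCs they are not recorded as binding.

    For every epitope the number of sampled negatives equals the number of
    positives for that epitope (per-epitope 1:1, hence global 1:1 class
    balance). TCR donors are drawn uniformly without replacement from the
    positives of *other* epitopes; any (TCR identity, epitope) pair already
    observed as a positive is rejected. When an epitope needs more negatives
    than it has distinct candidate TCRs, donors are reused (the 1:1 contract
    takes precedence); only an empty candidate pool is infeasible.
    """
    by_epitope: dict[str, list[TCRSample]] = {}
    for s in positives:
        by_epitope.setdefault(s.epitope, []).append(s)
    if len(by_epitope) < 2:
        raise InfeasibleSamplingError(
            "need at least two distinct epitopes to cross-pair negatives")
    known = {(s.tcr_identity(), s.epitope) for s in positives}
    rng = np.random.default_rng(seed)
    negatives: list[TCRSample] = []
    for epitope in sorted(by_epitope):
        templates = by_epitope[epitope]
        donors = [s for e in sorted(by_epitope) if e != epitope for s in by_epitope[e]
                  if (s.tcr_identity(), epitope) not in known]
        need = len(templates)
        if not donors:
            raise InfeasibleSamplingError(
                f"epitope {epitope}: no candidate TCR can be paired as a negative")
        picks = rng.choice(len(donors), size=need, replace=len(donors) < need)
        for template, j in zip(templates, picks):
            donor = donors[int(j)]
            neg = TCRSample(
                epitope=epitope,
                mhc_class=template.mhc_class,
                mhc_allele=template.mhc_allele,
                species=donor.species,
                label=0,
                **{f: getattr(donor, f) for f in
                   ("tcra_seq", "tcrb_seq", "cdr1a", "cdr2a", "cdr3a",
                    "cdr1b", "cdr2b", "cdr3b", "trav", "traj", "trbv", "trbj")},
            )
            negatives.append(neg)
    return negatives


def assemble_dataset(positives: list[TCRSample], seed: int) -> tuple[list[TCRSample], list[str]]:
    """Positives plus 1:1 sampled negatives, with provenance tags."""
    negatives = generate_negatives(positives, seed)
    samples = list(positives) + negatives
    provenance = ["observed"] * len(positives) + ["sampled_negative"] * len(negatives)
    return samples, provenance


# ---------------------------------------------------------------------------
# cross-validation folds


def kfold_split(samples: list[TCRSample], k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Disjoint, label-stratified folds (index arrays) covering all samples."""
    n = len(samples)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    labels = np.array([s.label for s in samples])
    counts = np.bincount(labels, minlength=2)
    if counts.min() >= k and counts[0] > 0 and counts[1] > 0:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), labels)]
    logger.warning("label counts %s too small for stratification with k=%d; plain k-fold", counts, k)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]
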