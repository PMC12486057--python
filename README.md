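# tcrcross

Multi-modal cross-attention transformers for TCR–pMHC binding prediction,
with per-residue attention explanations, structure-grounded explanation
scoring, and explanation-quality-based checkpoint selection.

## The problem

T cell receptors (TCRs) recognize peptides presented by MHC molecules
(pMHC); predicting which TCR binds which epitope is a binary classification
problem over several sequence modalities — the α/β chains, their CDR loops
(CDR3β above all), the epitope — plus categorical MHC and V/J gene-segment
labels. The model estimates

```
p_bind = P(binding | α, β, e, m)
```

and a pair is called a binder when `p_bind > t` (default `t = 0.5`); ranking
quality is reported as ROC-AUC. Beyond raw accuracy, this package treats
*explainability as a first-class design signal*: cross-attention maps are
reduced to per-residue importance scores `S` for each directed interaction
(e.g. epitope → CDR3β), and scored against structural ground truth with the
**Binding Region Hit Rate**

```
BRHR(t) = | top-k residues by S  ∩  top-k residues by smallest contact distance | / k,
k = ceil(t * n),  t = 0.25 by default
```

where the contact distance of a residue is its minimum heavy-atom distance to
the partner chain. BRHR over the four epitope↔chain directions ("explanation
quality") is also usable as a checkpoint-selection rule: pick the training
snapshot whose explanations best match binding geometry, rather than the one
with the lowest training loss.

The package implements three model families on a shared core (independent
per-modality BERT-style encoders; masked-language-modeling, binder, MHC and
V/J auxiliary losses): encoder-only modality-combination baselines,
directional cross-attention probes (`a -> b` = `a` queries `b`, optionally
with residual features of either modality in the classifier), and the
encoder–decoder architectures EGM-0/1/2 over (chain A, chain B, epitope) —
EGM-1 refines the chains against each other before epitope↔chain
cross-attention, EGM-2 additionally lets each chain read the epitope together
with the complementary chain. A synthetic-repertoire generator with planted,
recoverable binding motifs and matching synthetic contact distances makes the
whole pipeline testable end-to-end on one CPU; real assay tables
(VDJdb / McPAS-TCR / IEDB-style CSV/TSV) and PDB/mmCIF complexes are read
through the same interfaces.

All model math runs on a compact numpy automatic-differentiation engine
(`tcrcross.nn`) verified against numerical gradients — there is no
deep-learning framework dependency.

## Worked example

`examples/01_simulate_repertoire.py` generates a repertoire whose binding
rule is planted motif compatibility:

```
200 samples (103 binders), 4 motif pairs, label noise 0.05

sample 0 (binder): epitope=LENLQKLMY cdr3b=QTVRTDWWYTSV
  epitope motif at [5, 6, 7]: KLM
  cdr3b motif at [8, 9, 10]: YTS

motif-compatibility oracle AUC vs noisy labels: 0.955
(below 1.0 only because a fraction label_noise of labels is flipped)
```

A binder's epitope and CDR3 loops carry motifs from the same pair; the
rule-based oracle's AUC of 0.955 against the noisy labels is exactly the
ceiling any classifier can reach at 5% label noise.

`examples/02_train_and_explain.py` trains a small EGM-2 on 1,000 such samples
(a few minutes on one CPU) and reads its explanations:

```
EGM-2, 114,210 parameters
decoders: ['s1:cdr3a->cdr3b', 's1:cdr3b->cdr3a', "epitope->cdr3a'", "epitope->cdr3b'", "cdr3a'->(epitope+cdr3b')", "cdr3b'->(epitope+cdr3a')"]
held-out ROC-AUC: 0.939  (chance 0.5, noise-free ceiling 1.0)
mean BRHR over the four epitope<->chain directions: 0.504 (chance at t=0.25 is 0.25)

one predicted binder, direction epitope->cdr3b (scores over CDR3b):
  smoothed importances: [0.001 0.003 0.002 0.007 0.069 0.071 0.101 0.039 0.049 0.016 0.222 0.209]
  top-3 residues by importance: [6, 10, 11]; planted motif: [6, 7, 8]
```

The model recovers the planted binding rule from sequence data alone
(held-out AUC 0.939 against the noise-limited ceiling) and its attention
importance concentrates near the planted contact residues — a mean BRHR of
0.504 where independent rankings would give 0.25. The other examples compute
BRHR from a (synthetic) PDB structure and compare loss-based against
explanation-based checkpoint selection in an overfitting regime.

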