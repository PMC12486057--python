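# Methods

`tcrcross` models the TCR–pMHC binding prediction problem as binary
classification: given a T cell receptor (its α/β chains or their CDR loops),
an epitope peptide and MHC metadata, predict `p_bind = P(binding | α, β, e, m)`
and call a pair a binder when `p_bind` exceeds a threshold (0.5 by default;
ROC-AUC, the headline metric, is threshold-free). This note documents the
model, the synthetic data the package is validated on, the explanation and
evaluation machinery, and the numerical choices that were genuinely open.

## Model families

All models are built from per-modality transformer encoders (token + learned
absolute positional embeddings, post-LayerNorm self-attention blocks, GELU
feed-forward) over a 25-token vocabulary (20 amino acids plus
PAD/BOS/EOS/MASK/UNK). The default configuration is two layers, 128-dimensional
hidden states and a single attention head, trained with AdamW at learning rate
1e-4; every architecture keeps one independent, identically configured encoder
per input modality.

* **Encoder-only models** mean-pool each encoder's non-PAD positions,
  concatenate, and classify with a linear layer. They serve as
  modality-selection baselines (e.g. CDR3β-only, CDR3β+epitope, …).
* **Directional probes** add a decoder whose self-attention runs on a query
  modality and whose cross-attention reads a memory modality (`a -> b` = `a`
  queries `b`). The classifier consumes the pooled decoder output, optionally
  concatenated with the raw encoder features of the query or the memory
  modality. These isolate what information cross-attention propagates.
* **EGM-0/1/2** are encoder–decoder architectures over chain A, chain B and
  the epitope. EGM-0 lets each modality cross-attend directly into the
  concatenation of the other two. EGM-1 first refines the chains against each
  other (`A -> B`, `B -> A`, outputs A′/B′ staying aligned with their query
  positions), then runs four independent stage-2 decoders: the epitope queries
  each refined chain, and each refined chain queries the epitope; the
  classifier pools the four stage-2 outputs. EGM-2 additionally gives each
  chain→epitope decoder the complementary refined chain as extra memory
  (`A′ -> E ⊕ B′`).

Memory fusion is concatenation **along the sequence axis**, so each source
modality keeps its own attention columns and per-direction maps remain
readable; a learned per-source segment embedding is added to fused memories to
mark their origin (this is also why EGM-2 has strictly more parameters than
EGM-1). Pooling is a mean over non-PAD positions — with one head and shallow
stacks there is no reason to privilege the BOS position. Self-attention is
bidirectional everywhere (classification, not generation), stage-1 and stage-2
decoders never share parameters, and initialization is truncated normal
(σ = 0.02).

## Objectives

Training minimizes an unweighted-by-default sum of: sigmoid binary
cross-entropy on the binder head; masked-language-modeling (MLM) losses on
each encoder and on each decoder (a decoder head reconstructs its query
modality's masked tokens), using the BERT corruption recipe (rate 0.15,
80% MASK / 10% random residue / 10% unchanged, specials never selected);
and optional auxiliary heads read from the same pooled features — a binary
MHC-class head, one softmax over MHC alleles, and four softmaxes over the
TRAV/TRAJ/TRBV/TRBJ gene-segment labels. Samples missing a categorical
annotation are masked out of that head's loss rather than erroring, because
real exports are incomplete. Turning decoder MLM off leaves decoders trained
purely by the classification signal, which the tests verify at the gradient
level.

## Synthetic data: what it emulates and what it does not

The generator plants compatible motif triples — one short motif in the
epitope, one in CDR3α, one in CDR3β, all belonging to the same "motif pair" —
into otherwise i.i.d. uniform random sequences; full chains embed their CDR3
at a recorded offset. A sample binds iff the epitope motif and the TCR-side
motifs come from the same pair, labels are flipped with probability
`label_noise`, classes are exactly balanced, and MHC/V/J categorical labels
are drawn correlated with the motif pair (fidelity 0.8) so auxiliary
objectives are learnable. Nonbinders carry *mismatched* motifs (epitope motif
from one pair, both TCR motifs from another), mirroring the hard-negative
character of cross-paired assay negatives and removing single-modality
shortcuts: no marginal feature of one sequence predicts the label. Defaults:
9-mer epitopes, 12-residue CDR3 loops, 3-residue motifs, 4 motif pairs,
label noise 0.05.

Matching synthetic "structures" assign motif residues distances in the
3–5 Å contact band and all other residues 8–30 Å, so the planted residues are
exactly the closest contacts under any ranking — only the induced ranking
matters to BRHR.

What passing tests on this generator show: the architectures can be trained
end-to-end, the attention pathways can discover and expose a real cross-modal
interaction, and the evaluation stack (explanations → BRHR → checkpoint
selection) behaves as designed. What they do not show: performance on real
repertoires, where binding rules are not short exact motifs, sequence
backgrounds are far from i.i.d., V(D)J recombination shapes length and gene
usage, and structural contacts are continuous rather than two disjoint bands.

## Explanations

For a directed interaction `a -> b`, the cross-attention map of the decoder
in which `a` queries `b` is reduced to one score per *target* (`b`) residue:
special-token rows/columns are stripped, unavailable values are treated as 0,
layers are reduced (last layer by default; mean exposed), query rows are
reduced (mean by default; max exposed), and the result is smoothed with the
length-3 boxcar kernel (1/3, 1/3, 1/3) with zero padding, tolerating a
one-residue offset. Directions without a native map are derived from the
reverse map by reducing the opposite axis; note that with row-stochastic
attention the mean over keys is constant, so `max` is the informative
query-side reduction. A gradient-weighted variant multiplies each map by the
absolute gradient of the relevant loss — the binder loss for encoder-only
models, the full training loss for encoder–decoder models — before reduction.
External relevance-propagation engines can be plugged in through a registry;
they are integration points, not reimplementations.

## BRHR and explanation quality

Structural ground truth is the per-residue minimum heavy-atom distance from
each target-chain residue to any residue of the partner chain (unresolved
residues are excluded, with an index map). The Binding Region Hit Rate at
threshold `t` intersects the top `k = ceil(t·n)` residues by importance with
the top `k` by closeness and divides by `k`; ties break toward the lower
residue index, making the statistic deterministic. `ceil` guarantees `k ≥ 1`,
and `t = 0.25` is the default, the strictest threshold that always selects at
least one residue. Per-(sample, direction) rates are computed for samples the
model predicts as binders and averaged; a model that predicts no binders
yields an empty report rather than an error. Explanation quality for
checkpoint selection is the mean BRHR over the four epitope↔chain directions.
Under score–distance independence the expected rate is `k/n`, which the tests
verify against the hypergeometric mean; a perfect explainer scores 1.0 at any
`t`.

## Training and checkpoint selection

Negatives are sampled once, before any fold splitting, by pairing observed
TCRs with pMHCs they are not recorded as binding (per-epitope 1:1 with the
positives); regenerating them per fold is possible by calling the sampler
inside a fold loop, but the fixed-once default keeps folds comparable. The
MHC allele is treated as metadata and as an auxiliary prediction target — no
model consumes it as a sequence input — and the allele head is a single
softmax over all alleles rather than one per MHC class.

The training loop logs per-epoch mean loss, snapshots parameters on a
checkpoint cadence (default every 10 epochs), and, when a quality evaluation
set (samples + distances) is supplied, scores explanation quality at each
checkpoint from the selection start epoch onward (default 300 of 500, i.e.
60% of training — near convergence). Two selection rules are implemented:
lowest training loss, and highest explanation quality; ties go to the earlier
epoch. Cross-validation uses label-stratified k-folds (k = 5 by default) and
reports mean ± std of per-fold ROC-AUC, computed with the tie-aware
Mann–Whitney formulation.

## Desk-scale study conditions

The reference experiments (`tcrcross.experiments`) run the whole pipeline on
one CPU in minutes by scaling the problem down: CDR3 loops stand in for full
chains, models use hidden size 32, one layer, one head and feed-forward width
64, and training runs 20–100 epochs at learning rate 3e-3 with the MLM terms
down-weighted to 0.1. The down-weighting matters at this scale: an EGM has
nine MLM heads whose summed cross-entropy (~29 nats at initialization) swamps
the single binder term, and at unit weights the classification task does not
train within the epoch budget. Problem sizes per experiment: parameter
recovery trains EGM-2 on 1,000 samples (label noise 0.05) for 25 epochs and
evaluates on 300 noise-free samples; the directionality study uses 2,000
training samples, 8 motif pairs and 20 epochs; the selection study trains
EGM-1 on 600 samples at label noise 0.15 for 100 epochs with a
length-shifted, noise-free test set. These sizes are the package's own
choices for a reproducible CPU workflow.

## Known limitations

* The numerical core is a compact numpy autodiff engine written for this
  package; it is single-threaded, eager, and tuned for small models — it is
  not a general deep-learning runtime, and large configurations will be slow.
* The directionality phenomenon — that a probe keeping the *attended*
  modality's residual features stays at chance — is reproduced here only as a
  transient, early-training effect. A probe's decoder is itself a joint
  nonlinear function of both modalities, so on planted-motif data that is
  learnable at all, both residual configurations converge to the same AUC
  with enough training; the near-chance behavior reported on large real
  corpora reflects that data regime rather than a structural property of the
  architecture. The directionality experiment therefore measures the gap
  early in training, and its second clause may fail on some seed sets.
* Mapping CDR-level importance vectors onto full-chain coordinates assumes
  exact substring placement (the synthetic generator records it; real
  structures would need alignment/renumbering, which is out of scope).
* Checkpoint snapshots are held in memory as parameter dictionaries; very
  long runs with dense cadences should raise `checkpoint_every`.
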