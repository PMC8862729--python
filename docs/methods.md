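# Methods

## Model

The encoder maps an RNA sequence r₁…r_n (alphabet A/C/G/U after T→U
normalisation; positions are 1-based throughout) to an embedding matrix
Z ∈ ℝ^{n×D}. The input is the element-wise sum of a learned token
embedding (vocabulary A, C, G, U, MASK, PAD) and a learned position
embedding, followed by a stack of transformer layers. Each layer applies
multi-head self-attention

    head_i = softmax(Q_i K_iᵀ / √D) V_i,   C = Concat(head_1…head_H) W^O

with per-head projections W_iᴽ, W_iᴷ, W_iⱽ of size **D×D** (concat width
H·D) and attention logits scaled by **√D** — deliberately not the
conventional D/H split or √(D/H) scale; a `head_split` switch restores
the conventional layout. A position-wise feed-forward network (GELU,
hidden width 4·D) follows. Both sub-blocks are wrapped in post-norm
residual connections; an attention-plus-FFN stack without them is
untrainable at depth, and both can be disabled for unit testing. Padding
keys are excluded from every softmax. Reference width is D = 120 with 6
layers; tests and the scaled-down study use D = 24 with 2 layers and 4
heads.

No deep-learning framework is used: the encoder, both losses and Adam
run on a compact reverse-mode autodiff engine over numpy arrays
(`rnaembed.autodiff`), whose gradients are verified against central
finite differences in the test suite.

## Pre-training tasks

**Masked language modelling.** Per instance, max(1, ⌊0.15·n + 0.5⌋)
positions are selected uniformly without replacement; 80% become MASK,
10% are substituted with one of the *other three* bases, 10% are kept.
The loss is mean softmax cross-entropy of the 4-way classification head
at the selected positions only. The pre-training set takes 10
independently masked copies of each sequence, drawn once and reused
every epoch.

**Structural alignment learning.** For a reference-aligned pair, the
structured hinge f(x,x′,ŷ) + Δ(y,ŷ) − f(x,x′,y) + λ‖w‖₂² is minimised,
with f the sum of cosine scores ω_ij at matched columns plus affine gap
scores, and Δ counting matched-position differences (δ_FN = 0.05 per
missed reference pair, δ_FP = 0.1 per spurious pair; Δ is restricted to
matched pairs — not gap columns — so it decomposes over DP cells, which
is what makes exact loss-augmented decoding possible). ŷ maximises
f + Δ via the same affine-gap DP on shifted scores (ω_ij + δ_FP off the
reference, ω_ij − δ_FN on it, plus the constant δ_FN·|matched(y)|).
Because the decoder is exact and y is feasible, the hinge is never
negative. During a gradient step ŷ is held fixed (structured-SVM
subgradient); the hinge is linear in Ω, so its gradient is ±1 on the
disagreement cells. λ = 10⁻⁴ by default, applied once per batch so its
meaning is batch-size independent; ‖w‖₂² is the squared L2 norm of all
encoder parameters. Gap scores are fixed constants, not learned.

**Alternation.** One MLM epoch then one SAL epoch per cycle, a single
Adam optimiser over all weights (lr 3·10⁻³ for the tiny model). SAL
pairs are re-sampled per epoch: `pairs_per_family` random ordered member
pairs (default 8), with optional exclusion of held-out pairs.

## Alignment and its metrics

Decoding is the three-state Gotoh DP (match / gap-in-second / gap-in-
first) under the affine convention *open + extend·(L−1)* for a run of L
gap columns; terminal gaps are penalised like internal ones. Traceback
ties break deterministically: match over gap-in-second (i,−) over
gap-in-first (−,j), so results are bit-reproducible. Sensitivity is
TP/|reference matches|, PPV is TP/|predicted matches|, F1 their harmonic
mean; gap columns are never counted.

## Clustering and its metrics

ŝ is computed exactly as the SSA formula prescribes (α row-softmax,
β column-softmax of Ω, a = α + β − αβ, ŝ = Σaω/Σa); it is symmetric by
construction. Rows of the N×N similarity matrix are feature vectors; a
Gaussian kernel on their Euclidean distances (bandwidth = median nonzero
pairwise distance) gives the nonnegative affinity for normalised
spectral clustering — ŝ itself can be negative, so it cannot serve as an
affinity directly. k is a required input. RI, the expected index E and
ARI are computed from unordered-pair counts
(E = ((TP+FP)(TP+FN) + (TN+FP)(TN+FN))/total,
ARI = ((TP+TN) − E)/(total − E)); the tests verify this against an
independent contingency-table implementation. Homogeneity and
completeness use the standard conditional-entropy definitions.

## Motif calling

The attention map M sums each key position's softmax mass over all
heads and query positions of one layer (final layer by default), so
ΣM = n·H. Positions above mean(M) + 1·sd(M) are salient; maximal
salient runs of ≥ 3 bases are reported. Both thresholds are declared
defaults — attention salience has no canonical cutoff.

## Synthetic families

A family is sampled from a random consensus consistent with a consensus
secondary structure: paired columns always hold Watson–Crick pairs (no
G·U wobble, so stem assertions are unambiguous). Members apply
per-position substitutions — at paired columns the pair is resampled
from the other Watson–Crick pairs, compensatorily by default — and
indels restricted to loop columns (deletion or a 1–2 nt insertion, each
with probability indel_rate/2), so the consensus structure remains
well defined for every member and the true homology columns are known.
Insertions of different members are deliberately left unaligned to each
other. Pair identity = matched-column agreement / matched-column count
of the truth alignment. Defaults emulate small curated families:
2–3 hairpins, ~40–90 nt consensus, 6 members, substitution rate 0.18,
indel rate 0.12; an optional identity band is enforced by rejection
sampling. What this generator does **not** emulate: thermodynamically
realistic folding, G·U wobble, covariance-model indel profiles, or
conserved sequence motifs beyond the consensus itself — so passing
tests demonstrate correctness of the machinery and learnability of the
synthetic conditions, not benchmark-level accuracy on real ncRNA.

## Scaled-down study

`rnaembed.workflow.scaled_down_experiment` fixes the protocol: 5
families at the defaults above; a tiny encoder (2 layers, D = 24, 4
heads); 5 alternating cycles; 5 member pairs per family held out of SAL
sampling for alignment evaluation; clustering on the first 4 members of
the first 3 families (12 sequences, k = 3). Both the trained model and
an identically initialised untrained model are evaluated, isolating the
effect of training. Training lifts held-out alignment F1 by ~0.5 over
the untrained baseline (e.g. 0.24 → 0.75 at seed 1).

## Known limitations

* **Clustering at small scale.** The structured hinge perturbs Ω only
  at cells where the decode and the reference disagree: it sharpens the
  score matrix *relatively* (large alignment gains) but moves absolute
  within-family ŝ by only ~0.01–0.05. The MLM task at this scale (a few
  hundred optimizer steps, random-consensus sequences) cannot learn
  family signatures, while the untrained baseline is genuinely strong —
  identical residues at equal positions share identical token+position
  embeddings (cosine 1), so raw identity and length already cluster a
  12-sequence set. Consequently the trained model's ARI does not
  reliably exceed the untrained baseline in the scaled-down study; that
  separation emerges only with far larger pre-training corpora and
  model capacity. The weaker property that *is* robust at this scale —
  mean within-family ŝ exceeding the between-family mean after
  training — is asserted in the test suite.
* The evaluation-pipeline oracle uses +1 on reference matches and −3
  elsewhere; −3 sits below every affine-gap alternative, making the
  reference matched set uniquely optimal (an off-score of −1 would lose
  to matches across adjacent opposite-gap columns).
* Exhaustive alignment enumeration (the DP test oracle) is exponential
  and used only for n, m ≤ 4.
* Degenerate inputs: zero-norm embedding rows make the cosine undefined
  and raise an error naming the row; empty sequences and empty
  selections are rejected; a gap-only family member is repaired by
  retaining one consensus base.
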