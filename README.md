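# rnaembed

Context- and structure-aware **per-base embeddings for non-coding RNA**,
and the three analyses they power: fast structural pairwise alignment,
RNA family clustering, and sequence-motif detection.

Classical RNA structural alignment couples folding and alignment
(Sankoff-style dynamic programs, O(n⁴)–O(n⁶)). This package instead
learns an embedding z_i ∈ ℝᴰ for every base of a sequence with a small
transformer encoder pre-trained by two alternating tasks:

* **MLM** (masked language modelling) — 15% of bases are selected per
  instance (80% → `[mask]`, 10% → a random other base, 10% kept) and the
  encoder is trained to restore them, with softmax cross-entropy over
  the selected positions; the training set takes 10 mask patterns of
  each sequence.
* **SAL** (structural alignment learning) — a structured max-margin
  task on reference family alignments. For a pair (x, x′) with reference
  alignment y, the score matrix is ω_ij = (z_i·z′_j)/(‖z_i‖‖z′_j‖) and
  the per-instance loss is the structured hinge

  f(x,x′,ŷ) + Δ(y,ŷ) − f(x,x′,y) + λ‖w‖₂²,

  where f sums ω over matched columns plus affine gap scores, ŷ is the
  loss-augmented prediction (exact affine-gap Needleman–Wunsch on
  margin-shifted scores), and Δ = δ_FN·(missed reference pairs) +
  δ_FP·(spurious predicted pairs) with defaults δ_FN = 0.05, δ_FP = 0.1.

The embedding then drives:

* **Alignment** — Needleman–Wunsch over Ω with gap open −1 / extend
  −0.1 (three-state Gotoh DP, O(nm)); accuracy as sensitivity / PPV / F1
  over matched columns.
* **Clustering** — soft symmetric alignment similarity
  ŝ = (1/A) Σ a_ij ω_ij with a_ij = α_ij + β_ij − α_ij β_ij (α row-,
  β column-softmax of Ω); spectral clustering of the N×N similarity
  matrix rows; pair-count RI/ARI plus homogeneity/completeness.
* **Motifs** — the attention map M (per-position attention mass of the
  final layer, summed over heads and queries); maximal runs above
  mean + 1 sd are motif calls.

A synthetic-family generator (consensus structures with Watson–Crick
stems, compensatory substitutions, loop-only indels, known truth
alignments) makes everything trainable and testable without downloads.

## Worked example

`examples/03_structural_alignment.py` trains a tiny encoder (2 layers,
D = 24, 4 heads) for three alternating MLM/SAL cycles on three synthetic
families, then aligns two members of one family:

```
cycle 3 SAL: loss 8.8001

fam1/1  UCAAGACCUGAUGAG-GGCCUUCAUCAGUGAGUUACAG-GGCCUGUAAUGCGCCAGGG-UC-UUAC-CUGGCACUUA-
fam1/2  U--AGACUGGAUGAGAAGUGUUCAUCCAUGUGUGACAGCGGUCUGUCAUGCGCCAGGGCUCCCUACGCUGGCUUGCAU
score 47.148
vs reference: sensitivity 0.942 PPV 0.929 F1 0.935
```

The two gapped rows are the predicted structural alignment, `score` is
the summed cosine-plus-gap objective, and the metrics compare predicted
matched columns with the known reference alignment (94% of reference
columns recovered, 93% of predicted columns correct). The other
examples cover family generation, MLM pre-training, clustering and
motif calling.

A thin CLI wraps the same functions
(`rnaembed synth|pretrain|train|align|cluster|eval-cluster|motif`).

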