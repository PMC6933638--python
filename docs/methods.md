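# Methods

## Base-pairing probabilities

The structure encodings consume only the equilibrium probability
`p(i,j)` that bases i and j pair. `mircnn.structure` computes these
under a deliberately simple **pair-additive model**: a secondary
structure is any nested set of canonical pairs (AU/UA, CG/GC, GU/UG)
whose hairpin loops contain at least `min_loop` unpaired bases, and its
Boltzmann weight is the product over its pairs of
`exp(-E(pair)/temperature_scale)`. Defaults: `E(CG) = -3`, `E(AU) = -2`,
`E(GU) = -1` (arbitrary units), `temperature_scale = 1`, `min_loop = 3`
(the standard RNA steric minimum). N residues never pair.

Probabilities are exact for this model: an inside recursion computes
segment partition functions `Z(i,j)` and pair-closed functions
`Zb(i,j)`, and an outside pass processes pairs in order of decreasing
span, summing over each pair's innermost enclosing pair. The outside sum
is vectorized per stored pair (O(n²) flops per pair), entirely adequate
for the 200 nt cap. Products of Boltzmann factors overflow doubles for
long, strongly pairing sequences, so the recursions carry an adaptive
per-base rescaling factor (doubled until the total partition function is
finite); probability ratios are scale-invariant.

Correctness is established against an independent brute-force oracle
(`enumerate_bppm_oracle`) that explicitly enumerates every nested
structure for n ≤ 22 and tabulates weighted pair frequencies; the two
routes agree to 1e-9 over hundreds of random sequences.

This is not a nearest-neighbor (Turner) energy model: there are no
stacking, bulge, or multiloop terms, so absolute probabilities differ
from those of a thermodynamic folding engine. The downstream encodings
are agnostic to the source, and externally computed probabilities can be
substituted bit-for-bit through `read_bpp_file` (a 1-based
`i <tab> j <tab> p` triplet dialect, the dot-plot convention).

## Encodings

All grids are padded with zeros at the end to a fixed side length
(default L = 200, matching the sequence-length cap; 96-plus percent of
known pre-miRNAs fit). The probability/pair/mixed matrices are filled
symmetrically; an **ordered** pair matrix reads cell (i,j) in the base
order (s_i, s_j) and cell (j,i) as (s_j, s_i), so its support is
symmetric but its values are not (an AU pair contributes 1/6 above the
diagonal and 2/6 below). Collapsing ordered codes {1/6,2/6}→1/3,
{3/6,4/6}→2/3, {5/6,6/6}→1 recovers the unordered matrix exactly, a
tested invariant. The diagonal is forced to zero (no self-pairing), and
the one-hot column order is A, C, G, U.

The threshold T defaults to 0.0001. Because pairing probabilities are
far from uniform on [0,1], threshold sweeps use data-driven values:
`percentile_thresholds` pools all probabilities above a floor (0.0001)
and reads off nearest-rank percentiles (0/10/20/30/40 by default usage).
Raising T can only shrink the set of nonzero cells (tested).

## Architectures and parameter accounting

Structure-matrix CNN: conv 2×2 (valid, ReLU, bias) ×64 → max pool 2
(stride 2, floor) → conv 2×2 ×128 → pool → flatten → dense 256 → dense
128 → softmax over C classes, dropout 0.5 after each hidden dense layer;
Adam, learning rate 0.001, batch 32. The valid-convolution/floor-pool
combination gives the shape trace 200→199→99→98→49 and a total of
78,748,399 trainable parameters at C=47 — the closed-form count in
`count_parameters` and the built network's array sizes must and do agree
exactly.

One-hot CNN: for each filter width w ∈ {2,4,…,16}, a valid w×4
convolution with 512 biased filters followed by global max pooling; the
8×512 pooled features are concatenated, passed through dropout 0.7,
dense 1024, dropout, and a softmax head; Adam, learning rate 0.001,
batch 64. Total 4,485,255 parameters at C=135.

ReLU activations and Glorot-uniform initialization (explicitly seeded)
are used throughout; dropout is inverted (identity at evaluation).
The engine is plain numpy with reverse-mode gradients, verified by
central-difference numeric gradient checks on every layer type.

## Training and evaluation

Training minimizes softmax cross-entropy with Adam on shuffled
mini-batches. The epoch count is a configuration knob (default 50) with
early stopping on a training-loss plateau (patience 5, min delta 1e-4);
note the default patience is aggressive when dropout is high — the
per-epoch loss is noisy and can plateau mid-run before converging, so
longer patience is advisable for small models. On very small datasets
the batch size should be reduced below the 32/64 defaults so Adam gets
more than a handful of updates per epoch. Training is deterministic
under a seed on a fixed platform (single-threaded CPU).

Evaluation is closed-set argmax (ties to the lowest class id).
Precision, recall, and F-score are computed per family with zero
denominators mapped to 0, keeping the macro F-score well defined.
`kfold_cv` delegates stratified splitting to scikit-learn's
StratifiedKFold (shuffled, seeded); folds partition the data and
preserve class proportions within one sequence.

## Open-set rejection

Scores are the maximum softmax probability; accept means score ≥
threshold (the shipped default 0.977 rejects anything below it).
The ROC of the accept decision — positives are in-distribution members —
is swept over all distinct scores plus sentinels, with trapezoid AUC;
this equals the pairwise Mann-Whitney statistic with half-credit for
ties (tested to 1e-9, and cross-checked against
scikit-learn's `roc_auc_score`). Two selection criteria are implemented
and neither is privileged: the smallest threshold with FPR at most a
target (default 0.05), and the F-score-maximizing threshold (ties toward
the larger threshold). Degenerate targets that only the reject-all
sentinel satisfies return that sentinel with a warning.

## Synthetic benchmark

`make_benchmark` is the package's study-condition generator. Defaults:
10 families × 60 members; each family consensus is a 66 nt hairpin
(28 bp stem, 10 nt loop) whose 3' arm is the reverse complement of the
5' arm with 10% of eligible stem positions relaxed to G·U wobbles; a
16-mer "mature" motif is planted in the 5' arm, pairwise Hamming ≥ 8
across families; members are drawn by per-base substitution at rate
μ = 0.05 (no indels, so motif offsets stay fixed), with the motif region
mutating at a quarter of that rate to emulate mature-arm conservation.
Decoy sets: per-sequence shuffles (composition preserved), i.i.d.
random sequences (length-matched), cloverleaf-shaped sequences (an
acceptor stem enclosing three stem-loops, the tRNA silhouette), and
held-out unseen hairpin families. Flank augmentation adds k ∈
{5,10,15,20} random bases split uniformly between the two ends.

What the generator does *not* emulate: real phylogenetic correlation
structure within families, indels and alignment ambiguity, genuine
tRNA/snoRNA sequence statistics, or Turner-model thermodynamics. Passing
tests on this benchmark demonstrate that the pipeline's machinery is
correct and that its separability and rejection logic behave as designed
— not that real-data accuracies are reproduced, which require the real
family databases.

## Desk-scale experiment sizes

The test suite trains scaled-down instances of both architectures — the
one-hot model with 64 filters per width and a 256-unit dense layer, and
the structure model at L = 80 with 16/32 convolution filters and
64/32-unit dense layers — sizes chosen so the full suite runs in minutes
on one CPU while exercising identical code paths to the full
hyperparameters (which are what the parameter-count checks build).

The motif-recovery experiment uses its own conditions: 4 families at
background μ = 0.25 (~75% arm identity, typical of real family
divergence) with the default motif protection (motif μ ≈ 6%), model
trained to convergence. At the benchmark's μ = 0.05 the background is so
conserved that filters lock onto arbitrary consensus windows and no
preferential recovery of the mature region can be expected — with a
divergent background the top-activated filters recover the planted motif
exactly.

## Known limitations

- The pair-additive folding model ranks plausible stems correctly but
  is not thermodynamically calibrated; import external probabilities
  when absolute ensembles matter.
- The published parameter totals imply different class counts for the
  two architectures (135 one-hot, 47 structure); both are reproduced as
  printed, and the package treats the class count as a free spec field.
- Struct-CNN training at the full L = 200 / 64-128 filter scale is slow
  on one CPU in this numpy engine; the scaled configurations above are
  recommended for experimentation.
- No GPU support, no LSTM variants, no hyperparameter search harness.
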