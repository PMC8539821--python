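# Methods

## Problem and model

A protein may reside in several subcellular compartments at once, so
predicting localization from sequence is a multi-label problem: for a
protein p and an ordered vocabulary of L locations the model outputs a
score vector ŷ ∈ (0,1)^L of independent per-location probabilities (no
softmax coupling — the scores of one protein deliberately do not sum to 1).

Two fixed-size inputs represent each protein:

* **One-hot matrix P** (l_max × 23).  Row i carries a single 1 at the
  alphabet index of residue a_i, so Σ_j P_{i,j} = 1 for every real row.
  The 23-symbol alphabet is the 20 standard residues in the order
  `ACDEFGHIKLMNPQRSTVWY` followed by the ambiguity codes B, Z, X.
  Selenocysteine (U) maps to C, pyrrolysine (O) to K, and any other letter
  (including J) to the X column.
* **PSSM matrix S** (l_max × 43).  The 42 numeric columns of PSI-BLAST
  `-out_ascii_pssm` output (20 log-odds, 20 weighted observed percentages,
  information content, relative gapless-match weight) plus one trailing
  constant-zero column.  The 43rd column exists so the model consumes
  43-wide matrices; whether it "should" be a position index or bias column
  is not derivable from the architecture, and an inert zero column is the
  one choice that cannot inject signal.  Users with precomputed 43-column
  matrices can load them verbatim.

Sequences longer than l_max (default 1000) are truncated at the
C-terminus; shorter ones are zero-padded.  Padding rows are fed to the
network unmasked by default (`mask_padding` zeroes the encoder output at
padded positions instead; with zero-initialized biases a padded suffix
contributes only the LSTM's decaying carry-over state either way).

The network has four ablation variants built from three blocks:

* **BLSTM encoder** — a stack (default 2) of bidirectional LSTM layers
  with 128 hidden units per direction, giving a per-position 256-wide state
  matrix.  The recurrence is the standard LSTM: input/forget/output gates
  are logistic functions of [h_{t−1}, x_t], the cell candidate is a tanh of
  the same, C_t = f_t·C_{t−1} + i_t·C̃_t, and h_t = o_t·tanh(C_t), so every
  emitted value lies strictly in (−1, 1).
* **ConvNet1 / ConvNet2** — two identically shaped 7-layer stacks
  (4 convolutions + 3 interleaved max-pools): kernel counts 256/128/64/32,
  kernel sizes 4×3 then 3×3 three times, each convolution followed by ReLU
  and (after the first three) a 2×2 max-pool.  Convolution is valid
  cross-correlation, C_{i,j} = Σ_{m,n} ω_{m,n} X_{i+m,j+n}, with no kernel
  flip.  ConvNet1 reads the BLSTM state matrix as a one-channel image;
  ConvNet2 reads the PSSM directly.
* **Dense sigmoid head** — the flattened convolutional features (both
  stacks concatenated in the joint model) through a single fully connected
  layer to L logits and an elementwise sigmoid.  An optional hidden dense
  layer (`dense_hidden`) is off by default.

The variants: `blstm` (encoder only; the two directions' final hidden
states feed the head), `blstm_conv1` (encoder + ConvNet1), `conv2`
(ConvNet2 on the PSSM only), and `full` (both branches concatenated).

## Loss and training

Binary cross-entropy averaged over label terms, plus an L2 penalty on the
convolution kernels only (not LSTM or dense weights):

    L = −(1/n) Σ_i [ y_i log ŷ_i + (1−y_i) log(1−ŷ_i) ] + λ‖ω‖²

Predictions are clipped to [1e-7, 1−1e-7] before the logarithms.  Defaults
(none of which follow from the architecture itself): Adam with learning
rate 1e-3, 60 epochs, batch size 32, λ = 1e-4, binarization threshold 0.5
for F1/MCC.  Training is deterministic for a fixed seed on a single
thread.  The output-layer biases are initialized to the training-set
base-rate logits (`init_output_bias`, on by default): with positive rates
around 5–10 % per location, a zero-initialized head spends a long initial
phase just learning the class priors, and Adam's per-coordinate steps make
that phase proportional to |logit| / learning-rate.

Degenerate folds: a label with no positive (or no negative) example in a
held-out fold has undefined AUC/F1/MCC.  Those entries are reported as
explicit `None` markers and excluded from macro-averages — imputing 0
would bias every macro-average downward by an amount that depends on the
fold split, not on the model.

## Evaluation metrics

Let y be the n × L binary truth and s the score matrix.

* **Ranking loss**: per protein, the fraction of (true, false) label pairs
  with s_true ≤ s_false among k(L−k) pairs (k = number of true labels),
  averaged over proteins.  Ties count against the classifier, exactly as
  the ≤ in the definition reads.  The per-protein denominator uses the
  number of labels L, the only reading under which the quantity is a
  pairwise fraction in [0, 1].
* **Coverage**: per protein, max over true labels j of |{k : s_k ≥ s_j}| —
  the 1-based depth one must descend the ranked label list to cover every
  true label; ties counted inclusively.  `zero_based=True` converts to the
  rank−1 convention some libraries report.
* **Label-ranking average precision**: per protein, the mean over true
  labels j of (number of true labels ranked at or above j) / (rank of j),
  ties inclusive.
* **F1, MCC, AUC** per label column, with scores binarized at the
  threshold for F1/MCC and AUC computed rank-based (ties contribute ½),
  which equals the trapezoidal ROC area.

Every metric is validated in the test suite against a brute-force
enumeration of the definitions on random small instances including tied
scores, and against scikit-learn on tie-free instances.

## Synthetic benchmark

Real localization benchmarks are unavailable offline, so the package ships
a generator whose outputs exercise every pipeline stage with a known
ground truth.  Each of L locations (default 14, named after common
compartments) owns a distinct motif of 6 residues (pairwise Hamming
distance ≥ 2).  Each protein draws its number of locations from
(0.83, 0.15, 0.017, 0.003) for 1–4 — mirroring the composition of curated
human benchmarks, where a modest minority of proteins is multi-located —
and a length from N(300, 60²) clipped at 50.  For every positive location,
2 copies of its motif are planted at non-overlapping uniform positions in
an otherwise uniform-random sequence.  The pseudo-PSSM emulates profile
shape, not evolution: log-odds columns are Normal(−1, 1) noise with the
residue's own column raised by a conservation bonus of 5; percentage
columns are the row softmax rescaled to sum to 100; matrices are
deterministic in (seed, sequence).

What passing on this benchmark shows: the encoders, network, training loop
and metrics interoperate and the architecture can extract planted
sequence/profile signals.  What it does not show: performance on real
proteins, whose signals (targeting peptides, compositional bias, homology
structure, correlated labels) are nothing like uniform-background motifs.

## Desk-scale protocol

The standard CPU benchmark (`sublocnet.benchmark`) trains desk-scale
variants on 2000 generated proteins (data seed 17) and evaluates on 500
held-out proteins at l_max = 400.  The desk architecture keeps the wiring
and kernel shapes of the full model but narrows it to what a single CPU
trains in minutes: 1 BLSTM layer of 32 units per direction, 8 kernels per
convolution layer, and 4×2 pooling — the aggressive height pooling makes
the flattened features nearly position-invariant, which suits signals
planted at unknown positions, and the 64-wide state matrix gives the first
convolution enough reservoir dimensions to separate motif signatures
(narrower encoders train markedly slower).  PSSMs are sigmoid-squashed
(`pssm_scaling="sigmoid"`) so the percentage block (0–100) and the
log-odds block share a (0, 1) scale; unscaled, the first convolution sees
inputs two orders of magnitude apart and ReLU units die early.

Training: Adam, learning rate 1.25e-3, batch 32, λ = 1e-4.  (At 2e-3 and
above this architecture is bistable: a sizeable fraction of runs collapse
to the dead-ReLU constant predictor within the first epochs.)  The
learning-capability check trains the sequence-branch variant for up to 24
epochs, monitoring held-out macro-AUC after each epoch and stopping once
the target is demonstrated (the crossing epoch varies by training seed;
the acceptance script prints the epoch count actually used).  The
ablation-ordering comparison (joint model vs PSSM-only model) uses a fixed
12-epoch budget for both variants — the ordering is decided early because
the PSSM-only branch learns far more slowly, and a shared fixed budget
keeps the comparison symmetric.

## Numerical choices

* Compute precision is float32 (`ModelConfig.dtype`); the gradient-check
  tests build float64 models and verify analytic backpropagation against
  central finite differences for every layer type.
* Convolution layers use He-uniform initialization (they are all followed
  by ReLU; Glorot shrinks activation variance by ~2× per layer and the
  four-layer stack then starts nearly silent).  Dense and LSTM weights use
  Glorot-uniform; all biases start at zero except the calibrated output
  bias.
* Max-pooling ties: the first maximum in row-major window order receives
  the gradient.
* The strictly sequential or gather/scatter-shaped inner loops (the LSTM
  recurrence, im2col/col2im, pooling) are compiled with numba; input
  projections and all weight gradients remain single BLAS contractions
  over the whole sequence.  Large per-layer scratch arrays are cached and
  reused across mini-batches.
* Adam uses the standard (β₁, β₂, ε) = (0.9, 0.999, 1e-8).

## Full-scale recipe (optional, not run by the test suite)

To train at published scale: obtain the D3106 / D4802 benchmark deposits
(figshare DOI 10.6084/m9.figshare.14378630.v1) as FASTA plus per-protein
PSSM matrices, convert labels to the `id<TAB>Loc1,Loc2` table this package
reads, and run

    sublocnet crossval --fasta d3106.fasta --labels d3106.tsv \
        --pssm-dir pssms/ --variant full --l-max 1000 -k 5 \
        --epochs 60 --seed 1 --out-dir runs/d3106-full

with the default (paper-scale) architecture.  This is a GPU-scale
computation; on CPUs expect days, and published-level scores additionally
depend on training hyperparameters the architecture does not determine.
The package therefore treats published benchmark scores as out of its
verification scope; its claims are the exact dataset statistics, the exact
metric definitions, and the behavior of the architecture on the synthetic
benchmark above.

## Known limitations

* No attention mechanism, no GO-term features, no homology reduction.
* The BLSTM processes padding rows; masking is available but off by
  default, and sequences beyond l_max lose their C-terminal residues —
  including any targeting signals that live there.
* The desk-scale benchmark is a capability check of the implementation,
  not a claim about biological performance.
* Running PSI-BLAST is out of scope; the package consumes its output.
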