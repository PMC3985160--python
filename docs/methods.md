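# Methods

## Feature extraction

A protein sequence of length l over the 20-letter alphabet is summarised by
56 numbers: the normalized 2-gram frequencies of its 6-letter exchange-group
recoding (36 slots) followed by the normalized residue 1-gram frequencies
(20 slots). A gram counted x times is normalized to x/(l − n + 1), the
count divided by the number of gram positions, so each block sums to one.
The exchange-group map is a partition (every residue belongs to exactly one
group), so the recoded string has the raw sequence's length and the two
normalization denominators coincide.

Design choices the representation itself leaves open:

- **Slot ordering.** e2 slots are lexicographic over group labels (AA … FF)
  and a1 slots alphabetic over residues, e2 block first. Any fixed
  convention works; this one is reproducible and is frozen in
  `features.FEATURE_NAMES` so the same gram always occupies the same column
  across calls and processes.
- **Non-standard residues.** Default policy is `strict` (fail loudly,
  naming residue and position); `drop-unknown` is available for data with
  ambiguity codes. Strictness surfaces data problems rather than silently
  changing composition.
- **Short sequences.** Sequences of fewer than 2 residues have no 2-gram
  representation and are rejected rather than zero-padded.
- **Scaling.** Classifier inputs are min-max scaled to [−1, 1] per
  dimension with statistics from the training split only; test values may
  leave the interval. Constant dimensions map to 0. Fitting the scaler on
  pooled data would leak test statistics into training.

## ELM

Targets are one-against-all ±1 vectors (C outputs for C classes). Hidden
weights and biases are i.i.d. uniform on [−1, 1] (gaussian widths uniform
on (0, 1], keeping them positive); this matches the [−1, 1] feature range
and the usual practice for random-feature networks. Activations: sigmoid
1/(1 + e^(−a·x−b)), gaussian e^(−b‖x−a‖²), and a linear node a·x + b (which
makes the model a random affine projection plus least squares). Output
weights are the minimum-norm least-squares solution computed by SVD with
singular values below machine-eps × max(N, J) (relative) treated as zero;
no ridge term. Predicted class is the row argmax of O = HW, ties to the
smallest class index — deterministic and testable.

With J = N hidden nodes and a smooth activation the random design is
almost surely full rank and the network interpolates the training set
exactly; the test suite verifies a ≥ 95% perfect-fit rate over 100 random
draws, tolerating the occasional ill-conditioned draw.

## OP-ELM

Neuron ranking uses a multiresponse forward selection: starting from an
empty active set, repeatedly admit the hidden-layer column maximizing
Σ_c |h_jᵀ R|, where R is the residual of a full least-squares refit on the
current active set (maintained by growing an orthonormal basis one column
at a time). This reproduces the ranking role of multiresponse sparse
regression without the exact LARS-style step-length path, which the
downstream selection never consumes. Zero-variance columns are ranked last
with a warning — note this includes constant non-zero columns, which could
in principle serve as an intercept; the contract favors predictability.

The neuron count is chosen by the PRESS leave-one-out error
ε_i = (t_i − h_i β)/(1 − h_i P h_iᵀ), P = (HᵀH)⁻¹, averaged as the mean
squared residual over samples **and** output columns (the multi-output
aggregation is a package choice). Ties in the curve resolve to the
smallest k (parsimony). The keystone correctness test checks the closed
form against explicitly retraining N times with one sample held out.

Numerical details:

- P is stabilized with a ridge λ = 1e−8 · trace(HᵀH)/k only when the
  squared condition number of H exceeds 1e12; λ = 0 otherwise, so the
  statistic is the exact leave-one-out error on well-posed problems.
- Leverages within 1e−10 of 1 have their denominator floored at 1e−10 with
  a warning (such samples are fit exactly and carry an unbounded LOO
  residual).
- The full curve over prefix sizes k = 1..J_max is computed from a single
  thin QR of the ranked matrix: the QR of a prefix is the prefix of the QR,
  so prefix leverages are cumulative row sums of Q² and prefix fits grow by
  one rank-1 update per step (O(N·J·C) after the factorization). If the
  R diagonal signals near rank deficiency the per-prefix SVD/ridge routine
  is used instead; a unit test pins the fast path to the per-prefix values.

The pruned model keeps the selected top-ranked neurons and refits its
output weights on them; its training residual can only be ≥ the full
model's, while its leave-one-out error is ≤ by construction of the argmin.

## Voting ensembles

V-ELM (K basic-ELM members, default K = 7) and VOP-ELM (K OP-ELM members,
default K = 3; ensemble sizes beyond ~15 buy little accuracy for linearly
growing cost) train every member on the full training set — diversity comes
solely from the random hidden parameters, not from resampling. Member seeds
are spawned from the master seed through numpy's `SeedSequence`, making
members independent, reproducible, and prefix-stable (the first k members
of a K-ensemble are the K′ = k ensemble), which the sweep utilities exploit
to pair accuracies across K. Vote ties default to the smallest class index;
a seeded random tie-break is available but off by default.

`simulate_proposition1` is a Monte-Carlo illustration of why voting helps:
with per-vote class probabilities fixed and the true class strictly the
most probable single vote, the majority is correct with probability → 1 as
K grows. It simulates vote tallies directly and never estimates the vote
distribution from trained models.

## Synthetic data generator

Each superfamily is a composition profile over the 20 residues:
(1 − s)·uniform + s·Dirichlet(0.5) with a single separation knob
s ∈ (0, 1]. At s → 0 all classes collapse to the uniform composition; at
s = 1 they are independent peaked draws. Sequences are sampled i.i.d. from
the profile (a first-order Markov transition bias is optional but off by
default — the 1-/2-gram features are composition-driven, so composition
signal exercises the whole stack) with lengths uniform on [50, 400].

The `pir1`/`pir2` presets reproduce the class-size structure of the two
PIR-derived superfamily collections: 10 classes, 949 and 534 sequences,
with per-class sizes as documented (Globin 548/205, Cytochrome b6-f complex
8/6, etc.). The documented pir2 per-class counts sum to 533 against a
stated total of 534; the extra member is assigned to the largest class
(Globin 204 → 205) so the preset totals match the documented collection
sizes. What the generator deliberately does **not** emulate: real motifs,
homology structure, length distributions, or within-class phylogenetic
correlation. Passing tests on this data show the pipeline and the
classifiers behave as specified under compositional class signal; they do
not certify accuracy figures on real PIR sequences.

## Study conditions

The benchmark configuration used by the test suite and the acceptance
script is: 10 classes, separation 0.35, fixed split (pir1-sized training
set, pir2-sized test set), sigmoid activation, J = 600 hidden nodes
(J_max = 600 for OP-ELM), V-ELM K = 7, VOP-ELM K = 3. Separation 0.35 was
calibrated once so that a single sigmoid ELM scores in the high 0.80s —
hard enough that the methods separate, easy enough to be realistic. J = 600
was chosen because with 949 training samples an un-pruned 600-node ELM
visibly overfits, which is exactly the regime neuron pruning and ensemble
averaging address; the library-level `train_opelm` default stays at a
conservative J_max = 100. The acceptance script runs 15 trials per
algorithm; the trend tests use 50 seeds. Under these conditions the
qualitative ordering VOP-ELM > OP-ELM > ELM and V-ELM > ELM holds, and
V-ELM accuracy is non-decreasing over K ∈ {5, 7, 15}. Absolute rates on
real PIR data are outside what synthetic composition data can reproduce.

One further documented inconsistency: the randomized-split protocol is
described both with 949 and with 939 training samples in its source
material; the runner takes `n_train` as a parameter and defaults to 949.

## Known limitations

- MRSR ranking is the greedy refit variant, not the exact step-length path;
  rankings can differ on strongly correlated columns (the selected model is
  still LOO-optimal over the produced ranking).
- PRESS with the ridge fallback engaged is an approximation to LOO; it is
  exact only at λ = 0.
- The linear activation often underperforms — expected, since it reduces
  the network to one global affine least-squares fit.
- Class imbalance is handled only implicitly (the least-squares fit weights
  all samples equally); the imbalanced fixed split scores below the
  balanced random split, as the generator's trend test documents.
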