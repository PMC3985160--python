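# protelm

Classifying a protein sequence into its superfamily by alignment — comparing
it against every identified sequence in a database — is accurate but slow.
`protelm` implements the alternative: represent each sequence by a fixed-size
composition vector and classify it with single-hidden-layer feedforward
networks (SLFNs) trained by the extreme learning machine family of
algorithms, which solve for the network weights in closed form instead of
iterating gradients. It is aimed at bioinformaticians who want a fast,
reproducible sequence classifier and at method developers who need clean
reference implementations of ELM, OP-ELM and their voting ensembles.

## The representation and the classifiers

**Features.** A sequence over the amino-acid alphabet
Σ = {A,C,…,W,Y} is recoded through the six exchange groups
A={H,R,K}, B={D,E,N,Q}, C={C}, D={S,T,P,A,G}, E={M,I,L,V}, F={F,Y,W}.
The feature vector concatenates the 36 exchange-group 2-gram frequencies
with the 20 residue 1-gram frequencies — 56 dimensions, each count x
normalized as x̄ = x/(l − n + 1) for a length-l sequence. Columns are then
min-max scaled to [−1, 1] using training-split statistics.

**ELM.** An SLFN with J hidden nodes computes o(x) = Σⱼ wⱼ g(aⱼ, bⱼ, x).
ELM draws (aⱼ, bⱼ) at random (linear, sigmoid or gaussian activation) and
solves the output weights against one-against-all ±1 targets T by
least squares, W = H⁺T, where H is the hidden-layer output matrix and H⁺
its Moore–Penrose pseudoinverse.

**OP-ELM.** Random nodes are partly redundant. OP-ELM ranks the J_max hidden
neurons by multiresponse sparse regression (forward selection for the
multi-output target), then keeps the prefix of k neurons minimizing the
PRESS leave-one-out error
ε_i = (t_i − h_i β)/(1 − h_i P h_iᵀ) with P = (HᵀH)⁻¹ — the exact
leave-one-out residual computed from a single fit — and refits W on the
kept neurons.

**V-ELM / VOP-ELM.** K networks with the same architecture but independent
random hidden parameters are trained on the same data; a test sample takes
the class with the most member votes (ties to the smallest class index).
If a single network is right more often than it is wrong in any particular
way, the majority vote is correct with probability approaching one as K
grows.

Because the original PIR superfamily collections are not redistributable,
the package ships a synthetic generator that reproduces their shape: 10
superfamilies with the documented class sizes (949 sequences in the
`pir1` preset, 534 in `pir2`, Globin-dominated imbalance) and
class-specific residue compositions whose overlap is set by a single
`separation` knob.

## Worked example

Generate a pir1-shaped dataset, extract features, and run the repeated-trial
protocol (fixed pir1-sized training set, pir2-sized test set):

```bash
protelm simulate --preset pir1 --seed 0 \
    --fasta-out pir1.fasta --labels-out pir1.tsv
# wrote 949 sequences to pir1.fasta
protelm extract pir1.fasta -o pir1_features.csv
# wrote 949 x 56 feature matrix to pir1_features.csv

protelm experiment --algorithm elm --trials 5 --seed 0
# elm (sigmoid, 5 trials): rate 86.59% +- 1.60%
protelm experiment --algorithm vopelm --trials 5 --seed 0
# vopelm (sigmoid, 5 trials): rate 93.90% +- 1.07%
# mean selected neurons: 175.3
```

The first rate is the mean test classification accuracy of a single
600-node sigmoid ELM over 5 independent random initializations (±
standard deviation). The voting OP-ELM ensemble (K = 3 pruned members)
gains about 7 points on the same data, and its members keep on average 175
of the 600 candidate neurons — the rest were hurting leave-one-out
generalization. In Python the same pieces are available directly:

```python
from protelm import ProteinRecord, build_feature_vector, count_ngrams, to_exchange_string

rec = ProteinRecord("ex", "VAAGTVAGT")
count_ngrams(rec.residues, 2).counts   # {'VA': 2, 'AA': 1, 'AG': 2, 'GT': 2, 'TV': 1}
to_exchange_string(rec).groups         # 'EDDDDEDDD'
build_feature_vector(rec).combined     # 56-vector; e2_DD = 0.625, a1_A = 1/3, ...
```

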