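# snarefuse

Hybrid feature-fusion classifier for SNARE vs. non-SNARE protein
sequences, with a self-contained synthetic benchmark generator.

SNARE proteins (soluble N-ethylmaleimide-sensitive factor attachment
protein receptors) drive membrane fusion and are key players in plant
abiotic-stress responses. Deciding whether a protein sequence belongs
to the SNARE family is therefore a useful proxy signal when screening
plant proteomes for stress-related machinery. `snarefuse` implements a
hybrid deep architecture for this binary decision, built from scratch
in NumPy:

```
F(seq) = Bi-LSTM( CNN+RBF( Embedding( Encoding(seq) ) ) )
```

* **Encoding** — residues are mapped to integer codes over the
  PSI-BLAST column alphabet `ARNDCQEGHILKMFPSTWYV` (+ mask `X`); each
  sequence gets an M×20 position-specific scoring matrix **A** =
  {P<sub>a,b</sub>} (parsed from PSI-BLAST ASCII output, or a BLOSUM62
  pseudo-profile when none is supplied), squashed to [0,1] and
  augmented to the M×40 matrix **P<sub>com</sub>** = [A | A′] (A′ =
  row-reversed A). A 400-D composition vector (profile columns pooled
  by observed residue, length-normalized) is also available for
  exploratory analysis.
* **Embedding** — hashed character n-grams (orders 1–3, bag-of-subwords
  style) feed a jointly trained embedding table; per-position vectors
  are concatenated with the profile rows.
* **CNN branch** — parallel same-padded 1-D convolutions with ReLU
  (f(x) = max(0, x)) and dropout extract per-position features
  f<sub>ij</sub>.
* **RBF layer** — kernel activations of the distance to k learnable
  centers μ (initialized by k-means over CNN features): Gaussian
  φ(s) = exp(−γs²) or linear-quadratic p(r) = 1 − r²/σ.
* **Feature fusion** — per-position concatenation
  F<sub>com</sub> = [f ; rbf].
* **Bi-LSTM + softmax** — bidirectional LSTM over the fused sequence;
  pooled states pass through a softmax head
  σ(z)<sub>i</sub> = e<sup>z_i</sup>/Σ<sub>k</sub>e<sup>z_k</sup>.

Ablation baselines sharing the same front-end — plain CNN, LSTM,
CNN+RNN, CNN+Bi-LSTM — support architecture comparisons. Evaluation
reports accuracy, sensitivity, specificity, F1, ROC/AUC, and the
Matthews correlation coefficient

MCC = (TN·TP − FN·FP) / √((FP+TP)(FN+TP)(FP+TN)(FN+TN)).

Because the curated SNARE/non-SNARE corpus behind the original study is
not redistributable, the package ships a planted-motif generator: the
positive class carries a degenerate 16-residue coiled-coil-like motif
with a central Q anchor (mimicking the Q-SNARE zero layer) inside i.i.d.
background sequence, with configurable mutation rate, lengths, class
sizes, and background composition. Every stage of the pipeline is
testable offline against it.

## Worked example

```bash
# 1. simulate a benchmark: 300 SNARE-like + 300 background sequences
cat > sim.yaml <<EOF
n_positive: 300
n_negative: 300
length_range: [80, 120]
mutation_rate: 0.05
seed: 1
EOF
snarefuse simulate --config sim.yaml --out data/

# 2. train the hybrid model (85/15 stratified split, 10 epochs)
cat > train.yaml <<EOF
epochs: 10
batch_size: 32
learning_rate: 0.001
seed: 1
model_profile: desk
EOF
snarefuse train --data data/data.fasta --labels data/truth.tsv \
    --config train.yaml --model hybrid --out run/

# 3. evaluate on the held-out 15% (train/ writes it as test_split.fasta)
snarefuse evaluate --checkpoint run/ --data run/test_split.fasta \
    --labels data/truth.tsv --out eval/
```

This prints

```
INFO snarefuse: wrote 600 records to data/data.fasta
INFO snarefuse: trained hybrid for 10 epochs; final loss 0.0697
INFO snarefuse: accuracy 1.0000, MCC 1.0000
```

and `eval/metrics.json` contains

```json
{"tp": 45, "tn": 45, "fp": 0, "fn": 0,
 "accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0,
 "f1": 1.0, "mcc": 1.0, "auc": 1.0}
```

i.e. the hybrid recovers the planted motif class perfectly on the 90
held-out sequences at a 5% per-position mutation rate: sensitivity 1.0
means every held-out SNARE-like sequence was found, and MCC 1.0 means
the confusion matrix is exactly diagonal. The task gets genuinely hard
as `mutation_rate` grows (at 0.35 held-out accuracy drops to roughly
0.9). A Python-level walkthrough of the same pipeline lives in
`scripts/acceptance.py`.

`snarefuse compare --data ... --labels ... --out ...` trains all five
architecture variants on one split and writes a comparison table
(classifier, accuracy, sensitivity, specificity, MCC).

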