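# acpcnn

A multi-headed convolutional neural network for identifying anticancer
peptides (ACPs) from sequence alone, with the full evaluation and
representation-ablation machinery around it.

ACPs are short peptides (roughly 10–50 residues) with cytotoxic activity
against cancer cells. Identifying them experimentally is slow and costly, so
sequence-based classifiers are used to triage candidates. This package is
for computational biologists who want a small, fully reproducible
CNN pipeline for that problem: encode peptides, train, cross-validate,
ablate the input representations — all runnable offline on synthetic data
with a plantable sequence motif, or on your own FASTA files.

## The model

Each peptide is reduced to its k N-terminal residues (k = 15 by default;
shorter sequences are post-padded with all-zero rows) and encoded three
ways:

| representation | shape | content |
|---|---|---|
| BPF | k × 20 | one-hot over the residues A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V |
| PHYSCHEM | k × 31 | 10 overlapping physicochemical group bits + 7 attributes × 3 disjoint groups (polarity, van der Waals volume, hydrophobicity, secondary structure, solvent accessibility, charge, polarizability) |
| BLO62 | k × 20 | the residue's row of the symmetric BLOSUM62 substitution matrix (raw integer scores) |

One convolutional group per active representation — two stacked stride-1
valid convolutions with ReLU, high dropout (≥ 0.5) and no pooling — is
flattened, concatenated with the other groups, recombined by dense ReLU
layer(s) with dropout, and classified by a two-unit softmax. Everything is
trained jointly with Adam on cross-entropy plus an L2 weight penalty. The
default kernel stack (length 4 then length 3) gives each final-layer unit an
effective receptive field of 6 consecutive residues.

The seven non-empty subsets of the three representations (C1…C7) define the
ablation: C1 = BPF only, …, C7 = all three (three parallel branches).

Metrics are the standard suite: accuracy, sensitivity, specificity and
precision on the percent scale, the Matthews correlation coefficient (MCC),
and ROC/AUC; protocols are stratified 5-fold cross-validation and
train-once/test-once independent evaluation.

## Worked example

`examples/02_train_and_predict.py` trains the published ACP-740
hyperparameter profile on a synthetic dataset of 600 peptides whose
positives carry the motif `KWKLFK` near the N-terminus:

```
trainable parameters: 1724
stopped after 200 epochs (best epoch 198)
held-out accuracy on 120 peptides: 0.917
example probability pair (neg, pos): [0.124 0.876]
```

91.7 % of the 120 held-out peptides are classified correctly — the
convolutional branch recovered the implanted motif — and every probability
pair sums to 1. `examples/04_combination_sweep.py` runs the C1…C7 ablation
in independent-test mode (train 500 / test 164 synthetic peptides) and
prints the standard ablation table; with all three representations (C7) it
reaches 99.4 % test accuracy on this synthetic benchmark. The other
examples cover encoding, cross-validation and architecture inspection.

## Command line

```bash
acpcnn simulate --n-pos 100 --n-neg 100 --seed 1 --out sim/
acpcnn cv --preset acp740 --combination C7 --seed 1 --out cv/ sim/dataset.fasta
acpcnn train --preset acp740 --out run/ sim/dataset.fasta
acpcnn predict --model run/model --out pred/ sim/dataset.fasta
acpcnn sweep --preset acp740 --out sweep/ sim/dataset.fasta
```

Labels travel either as a trailing `|1` / `|0` token on FASTA headers or as
paired positive/negative files. Every run writes a `provenance.json` with
the config snapshot, seed and package version.

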