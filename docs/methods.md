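# Methods

## Problem and model

The package classifies short peptides (≈10–50 residues) as anticancer
(positive) or not. The classifier is a multi-headed convolutional network:
one convolutional group per input representation, trained jointly so that
the dense recombination layer can mix features extracted from different
views of the same sequence.

Only the k N-terminal residues are used (default k = 15); the N-terminus is
where the discriminative signal for anticancer activity concentrates, and
restricting the window keeps the parameter count small. Sequences shorter
than k are post-padded: PAD positions are all-zero rows in every
representation, the neutral fill for convolution inputs. Full-sequence mode
(`k="max"`) pads everything to the longest sequence in the dataset instead.

### Representations

* **BPF (binary profile feature)** — one-hot rows in the fixed residue
  order A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V. All other encoders are
  re-indexed to this order on load.
* **PHYSCHEM** — 31 membership bits per residue: 10 overlapping
  physicochemical groups, then 7 attributes × 3 disjoint exhaustive groups,
  so the 21-bit segment always sums to exactly 7. The shipped table
  (`data/property_groups.tsv`) populates the attributes from the canonical
  composition/transition/distribution (CTD) three-group tables
  (Dubchak-style: polarity, normalized van der Waals volume,
  hydrophobicity, secondary structure, solvent accessibility, charge,
  polarizability) and the overlapping groups from the Taylor classification
  (aliphatic, aromatic, polar, positive, negative, charged, hydrophobic,
  small, tiny, proline). The table is an editable text file and its path a
  configuration option; all structural invariants (10 groups, 7 attributes,
  disjoint + exhaustive partitions) are enforced at load time regardless of
  content, so substituting a different grouping is safe.
* **BLO62** — each residue's row of the symmetric 20×20 BLOSUM62 matrix,
  used as raw integers exactly as published (the canonical NCBI-format file
  ships in `data/blosum62.txt`; extra B/Z/X/* rows are dropped on load and
  symmetry is validated). An optional switch z-scores each column for
  experimentation; it is off by default because no transformation is part
  of the method.

### Architecture

Per active representation: Conv1D → ReLU → dropout → Conv1D → ReLU →
dropout → flatten. Convolutions are 1-D along the sequence axis with the
representation columns as input channels, stride 1, valid padding (no
padding inside conv layers), and no pooling — the inputs are 15-row
windows, so reducing the temporal dimension is unnecessary and would
discard order information. Branch outputs are concatenated and passed
through one or two dense ReLU layers with dropout, then a two-unit softmax.
L2 applies to convolutional and dense weight matrices (not biases).

Two published hyperparameter profiles ship as presets:

| profile | conv-1 | conv-2 | dense |
|---|---|---|---|
| `acp740` | 10 filters, kernel 4, dropout 0.8 | 8 filters, kernel 3, dropout 0.7 | 8 units, dropout 0.7 |
| `acp500` | 16 filters, kernel 3, dropout 0.7 | 8 filters, kernel 3, dropout 0.5 | 16 units (0.6), then 8 units (0.5) |

With stride-1 stacks the effective receptive field is 1 + Σ(kernel−1):
6 residues for the `acp740` kernels (4, 3). Note an internal inconsistency
of the source material: the receptive-field-6 statement matches only the
(4, 3) profile; the `acp500` profile's kernels (3, 3) give 5. Both profiles
are implemented exactly as printed.

### Training

Adam on two-class cross-entropy against integer labels (softmax head),
inverted dropout active only during training, early stopping on validation
loss with best-weights restoration. When no validation set is supplied, a
seeded stratified 10 % of the training partition is held out. Defaults for
the hyperparameters the published configuration leaves unstated:

| parameter | default | rationale |
|---|---|---|
| learning rate | 3e-3 | selected by a small cross-validated sweep on synthetic motif data (the method's own stated procedure for this value); 1e-3 needs ≈2× more epochs to leave the early plateau induced by the heavy dropout |
| patience | 50 epochs | the validation loss plateaus for tens of epochs before the motif is learned; shorter patience stops inside the plateau |
| batch size | 32 | standard for datasets of a few hundred records |
| max epochs | 200 | training at these model sizes costs seconds, so the budget is generous |
| L2 weight | 1e-3 | mild; dropout is the main regularizer per the published design |

All randomness (weight init, shuffling, dropout masks, validation split)
flows through one seeded `numpy.random.Generator`, so identical config +
seed reproduces identical histories and predictions bitwise on the same
platform. The network is implemented in numpy inside the package
(`acpcnn.nn`), with backpropagation verified against central finite
differences in the test suite.

## Evaluation

Accuracy, sensitivity, specificity, precision (percent scale) and MCC are
computed from the 2×2 confusion table with ACP = 1 positive. Conventions
for degenerate tables: any zero denominator yields 0 for the affected
ratio, and an MCC with a vanishing denominator (any zero marginal) is
defined as 0, the no-correlation value. Predicted labels use threshold 0.5
on the positive-class probability with exact ties resolved to the negative
class (conservative positive calls).

ROC is the standard threshold sweep over distinct scores with trapezoid
AUC; tests verify it against the pairwise-concordance rank statistic.

Stratified k-fold (default 5) shuffles within class with the seed and
assigns round-robin, carrying the fold counter across classes so both the
per-class counts and the total fold sizes differ by at most 1. Fold models
are seeded `seed + fold_index`. Cross-validation reports per-fold metrics,
fold mean and standard deviation (single-run fold variance), and a single
pooled out-of-fold ROC curve per dataset — pooling, rather than averaging
per-fold curves, is this package's convention; per-fold AUCs are also
available. Independent testing trains once (internal validation split for
early stopping) and scores the untouched test set exactly once; shared
record ids between the two sets trigger a leakage warning.

The combination sweep evaluates all seven non-empty subsets C1…C7 of the
three representations, in either CV or independent mode, producing the
usual ablation table.

## Synthetic data

The generator emulates the anticancer-peptide setting: i.i.d. background
residues (uniform by default, configurable frequencies), lengths uniform in
[10, 50], and a motif (`KWKLFK`, length 6 = the default receptive field)
implanted in positives with probability `signal_prob` at a uniform offset
within 9 residues of the N-terminus, so the motif always falls inside the
default 15-residue window. `signal_prob=1` gives a fully separable task;
`signal_prob=0` makes the classes distributionally identical (the null).

What it does **not** emulate: real amino-acid composition biases, length–
class correlations, homology between records, distributed/degenerate
motifs, and negatives drawn from antimicrobial peptides rather than random
background. Passing tests on this generator therefore demonstrate that the
pipeline is wired correctly and that the architecture can recover a
plantable N-terminal signal — not that real-benchmark accuracies will be
reproduced. On the real benchmark FASTA files (obtainable from their public
repositories) the same entry points apply unchanged.

## Problem sizes used in tests and examples

The capability checks train on 480 records (600 with a 5-fold holdout) with
the `acp740` profile — the scale at which the default training budget
reliably escapes the early dropout-induced plateau; smaller protocol tests
use 120–200 records with capped epochs since they check plumbing, not
learning. The `acp500` profile trains harder on BLO62-heavy combinations of
this synthetic task (raw integer substitution scores are unnormalized
inputs); it is provided as printed and exercised structurally.

## Known limitations

* Training is CPU-bound numpy; fine at these model sizes, not intended for
  large architectures.
* Bitwise determinism is guaranteed per platform/BLAS build, not across
  differing floating-point environments (the generator's sequences are
  platform-independent; trained weights may differ in the last ulp).
* The 10 overlapping groups and CTD partitions are a documented choice of
  published tables; the method's source does not enumerate them, so other
  reasonable tables exist (the loader accepts any table satisfying the
  structural invariants).
* Exact ties at probability 0.5 are resolved negative by convention.
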