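# Methods

## Problem and scope

`nitrosite` predicts three post-translational modifications driven by
reactive nitrogen species — tyrosine nitration, tryptophan nitration and
cysteine S-nitrosylation — from primary sequence alone. These
modifications arise from chemical side reactions rather than enzyme
recognition, so they lack consensus motifs; the design bet of the toolkit
is that a discriminative per-position encoding (the tendency PSSM) plus a
deep feed-forward classifier can still extract the weak, distributed
sequence preferences (e.g. proximal basic residues favoring modification,
proximal aromatics or cysteines disfavoring it).

## Windows and alphabet

A candidate site is represented as a peptide window of odd length L
centered on the residue (Y, W or C), flanks of (L−1)/2 on each side,
positions past the protein termini padded with the gap symbol `-`. The
alphabet is the 20 natural amino acids in the fixed order
`ACDEFGHIKLMNPQRSTVWY` followed by the gap; the order is serialized with
every model and verified on load. Positions are 1-based in every
user-facing contract. The default L is 41: discrimination on both real
and synthetic data saturates around that width while the feature count
stays manageable, and the window-size sweep utility
(`sweep_window_size`, odd L only) lets users re-derive the choice for
their own data.

Nonstandard input letters (B, J, O, U, X, Z and `*`) have no row in any
encoding table and are mapped to the gap symbol with a logged warning.
This can, in principle, put gaps in a window interior; all encoders handle
that gracefully (indicator at the gap index for one-hot, zero block for
PFR, exclusion from pair counts for k-space, the gap row of E for the
PSSM), although generated windows only ever carry terminal gap runs.

Datasets built from FASTA + annotation TSV are deduplicated by exact
flanking peptide within each label class (stable, first occurrence wins).
A peptide occurring as both positive and negative is kept in both classes
with a warning: silently dropping either side would bias class
composition, and the conflict is information the user should see. The
toolkit does not perform homology clustering; callers concerned about
homologous redundancy should cluster their proteins before input.

## Encoders

**One-hot** — 21 indicator bits per position; 21·L values.

**Property factors (PFR)** — ten orthogonal physicochemical factors per
residue, 10·L values, gaps as zeros. The packaged table
(`data/property_factors_synthetic.tsv`) is a synthetic stand-in
constructed by principal-component analysis of the complete AAindex
property scales (standardized per scale, top ten components, unit
variance per factor). It preserves what the representation needs —
orthogonal factors summarizing the published physicochemical property
space — without reproducing any specific published table; any 20×10 TSV
can be substituted via the `table`/`property_table` parameters.

**k-space pairs** — for each k in 0..4, the count of every ordered
natural-residue pair with exactly k intervening positions, divided by
L′ − k + 1 where L′ is the window length after stripping terminal gap
runs. Two deliberate literalisms: the denominator is L′ − k + 1 even
though the number of k-spaced positions is L′ − k − 1, so blocks are not
probability vectors (the constant scale is irrelevant to a downstream
classifier); and "k-space" means k *intervening* residues (an `LxxxE`
pair is three-space). A k admitting no pairs yields a zero block rather
than an error. Correctness is pinned by an exhaustive double-loop
enumeration oracle in the tests.

**Tendency PSSM** — for every non-center position j and symbol a, the
binary indicator vectors of symbol occurrence in positive and negative
windows are compared by a Welch (unequal-variance) two-sample t-test,
computed in closed form from the counts. The encoding matrix is

    δ(a,j) = (f_pos(a,j) − f_neg(a,j)) / p(a,j)
    E(a,j) = sign(δ) · ln(|δ| + 1)

with p clamped to [1e-6, 1]. Numerical conventions, chosen where the
formula is silent:

* exactly equal class means give p = 1 (not a numerically noisy value),
  so identical class distributions give E ≡ 0 exactly;
* both variances zero with differing means (e.g. a residue fixed in every
  positive and absent from every negative) would make the t statistic
  undefined; such cells get the floor p = 1e-6, keeping δ finite and
  large — these are the most significant cells, and the floor is what
  bounds |E| (≈ ln(1/p_floor) for a saturated cell);
* the signed-log form is symmetric: swapping the classes negates E
  entrywise, and sign(E) always equals sign(f_pos − f_neg).

The center column is discarded (zero variance by construction), so the
matrices are 21 × (L−1) and a window encodes to L−1 values. Fitting
requires at least two windows per class. Models serialize to a diffable
plain-text format with full float precision.

One calibration property worth stating explicitly: under the null
(exchangeable classes) E is *not* uniformly tiny. The division by p
amplifies precisely the cells that look most significant by chance, so
the maximum |E| over the 840 cells of a 41-window fit on 1000 windows per
class is around 4 even with no signal. What distinguishes signal from
null is contrast, not absolute scale: a strongly planted cell (mixing
weight 0.8) hits the p-floor and scores |E| ≈ 13, far above every null
cell, and the calibration tests assert exactly that separation together
with the zero-median of the null.

**Combination** — any subset of the four schemes concatenates in the
fixed order one-hot, PFR, k-space, PSSM, with the layout recorded
alongside the vector. At L = 41: 861 + 410 + 2000 + 40 = 3311 features
for all four; 2040 for the default k-space + PSSM; 40 for PSSM alone
(the default for tryptophan models, whose small datasets are hurt by
high-dimensional schemes).

## Network and training

The site classifier is an eight-layer architecture: input, six dense
hidden layers with ReLU activations, two-unit softmax output. Default
widths (256, 128, 64, 32, 16, 8) form a fan-in-tapered ladder; they and
every other hyperparameter are plain constructor arguments. The loss is
mean categorical cross-entropy (log clamped at 1e-12) plus
λ1 Σ|θ| + λ2 Σθ² over all weights and biases (defaults λ1 = 1e-5,
λ2 = 1e-4).

Training is mini-batch gradient descent with classical momentum: a
velocity per parameter, v ← m·v − η·∇L, θ ← θ + v (defaults η = 0.01,
m = 0.9). Batch size defaults to 30 for nitration and 50 for
S-nitrosylation. Inverted dropout (rate 0.5) masks the first three hidden
layers during training, scaling kept units by 1/(1−p) so inference needs
no rescaling; inference mode never drops or scales. Weights initialize
from a seeded normal scaled by 1/√fan-in, biases at zero. Batch shuffling
and dropout masks draw from a generator reseeded per epoch from the
master seed, so training is bitwise reproducible given (seed, data). A
non-finite epoch loss raises an error naming the epoch. The default epoch
count is 100, a generic budget for datasets in the 10³–10⁴ range; the
bundled study protocols use 40 because the planted signal saturates well
before that (see below).

Correctness is established by a finite-difference gradient check
(relative error ~1e-8 on a tiny network) and by a hand-rolled
full-batch SGD oracle that the trainer must match bitwise in the
no-momentum, no-dropout, no-regularization special case. The gradient
check is run at a generic parameter point (small random biases): with
all-zero biases a deep narrow network can sit exactly on the ReLU kink,
where the subgradient convention and a central difference legitimately
disagree — a property of ReLU, not of the implementation.

The same class serves as the probe MLP of the abstraction analysis
(hidden widths (64, 32), no dropout, four layers total).

## Evaluation

ROC and precision–recall curves use descending-score sweeps with tied
scores grouped, so the trapezoidal AUC equals the Mann–Whitney statistic
with ties counted 1/2 (property-tested against a brute-force pairwise
count). Cross-validation is stratified; **every encoder, including the
PSSM, is refit on the training folds of each split**, so validation
windows never contribute to the matrix that encodes them — the package's
main leakage hazard. Both per-fold and pooled (concatenated-fold) curves
are reported; the pooled ROC is the headline statistic and the source of
stringency thresholds.

Stringency thresholds (high/medium/low) are defined as the smallest score
cutoff achieving specificity ≥ 0.95 / 0.90 / 0.85 (configurable); an
unattainable target falls back to the maximal cutoff with a warning.
Thresholds depend only on the ordering of scores, so they are invariant
to monotone transforms.

## Abstraction analysis

For each hidden layer i, inference-mode post-ReLU activations of a train
and a test partition feed a freshly trained probe MLP; its test AUC A_i
gives the per-unit score S_i = (A_i − 0.5)/D_i with D_i the layer width.
The baseline compresses the *raw* features to the same D_i by PCA fit on
the train partition only (fitting on train+test would leak test
structure into the comparison) and probes identically. On strongly
separable synthetic data both branches sit near ceiling, so the
meaningful check there is that hidden layers do not fall below the
matched PCA baseline; graded differences require harder data.

## Synthetic data

The generator emulates labeled site windows with known ground truth.
Negatives draw all flank positions iid from a background over the 20
residues; positives additionally, at each planted offset, emit the
planted residue with mixing weight e (else a background draw). The
defaults define the standard study conditions used throughout the tests
and the acceptance script: L = 41, 1000 windows per class, lysine planted
at offset −1 and arginine at +2 with e = 0.8 (mimicking the proximal
basic-residue preference of real modification data), terminal truncation
probability 0.1 (to exercise the gap paths; arbitrary and configurable).
The background is uniform by default so null calibration is exact; a
Swiss-Prot-composition preset (`natural_spec`) is included. Because
enrichment is a two-component mixture, the expected positive-class
frequency of a planted cell is e + (1−e)·q (background q), making the
true tendency sign analytically known — the basis of the sign-recovery
check.

What the generator does **not** emulate: homologous redundancy between
windows, position–position dependencies, realistic class imbalance, or
any structural context. Passing tests on this data demonstrate that the
machinery recovers planted positional signal and produces calibrated
nulls; they do not certify real-data accuracy, which depends on curated
site collections outside the package's scope.

## Study protocols and problem sizes

`nitrosite.protocols` bundles the three standing experiments:

* **planted recovery** — train PSSM + k-space + default network (40
  epochs) at study conditions; AUC on an independently generated
  1000-per-class held-out set. Typical value ≈ 0.96; the held-out size
  keeps the null sampling noise of an AUC near sd ≈ 0.013.
* **permutation null** — labels shuffled across a double-size dataset
  *before* the train/held-out split, scored against the shuffled held-out
  labels. This is the standard permutation control; scoring a
  shuffled-trained model against *true* labels instead would re-measure
  the chance correlation between the shuffled training labels and the
  planted motif, which the classifier amplifies — a property of that
  design, not of the implementation.
* **shuffled CV** — pooled cross-validated AUC on a label-shuffled
  dataset (1000 per class, 4 folds), exercising the per-fold PSSM refit.
  Any leak of validation windows into the fold PSSMs would push this far
  above 0.5.

Problem sizes (2000-window training sets, 40-epoch training, 40-epoch
probes) were chosen so each protocol completes in about a minute on one
CPU while keeping all sampling noise small against the assertion bands;
they are arguments, not constants.

## Known limitations

* The k-space denominator literalism makes those features non-normalized
  frequencies; comparability across different L′ is approximate.
* The p-floor (1e-6) sets the dynamic range of E; datasets large enough
  to produce genuine p-values below the floor will saturate there.
* Training is plain numpy on one CPU; it is fast at desk scale
  (10³–10⁴ windows) but not meant for large-scale retraining.
* The probe comparison quantifies layer content only relative to PCA at
  matched dimension; it says nothing about attribution of individual
  sequence positions.
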