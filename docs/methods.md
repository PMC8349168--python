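# Methods

## Problem and representation

`sumosite` predicts whether a lysine residue in a protein is a sumoylation
site. Each candidate site is a 41-residue window: the target K at 1-based
position 21 with 20 residues of context on either side; positions beyond a
terminus are filled with the virtual residue `X`. Residues are mapped to
integer codes 1–20 by the alphabetical order of their full names
(Alanine = 1 … Valine = 20), with 21 for `X`; ambiguity letters (B, J, O, U,
Z) also map to 21, since only the 20 standard residues plus the virtual pad
are defined.

## The 194-dimensional descriptor

A window of codes `c1 … c41` is summarised by order-aware positional
statistics:

* **FV** (21): count of each residue code — composition only.
* **SVV** (41): the codes themselves, in order.
* **AAPIV / R-AAPIV** (21 + 21): for each code, the sum of the 1-based
  positions where it occurs, on the forward and on the reversed window.
* **PRIM / R-PRIM** (21×21 each): entry (i, j) sums, over the positions p
  carrying code i, the offset `p − firstpos(j)`; rows/columns of absent
  residues are zero. PRIM's 441 coefficients are not used directly — they
  are compressed into moments.
* **Statistical moments** (3 × 30): for three matrices — the row-major 7×7
  matrixisation of the 41 codes (zero-padded; 7 = ⌈√41⌉ is the minimal
  square), PRIM and R-PRIM — the ten order-≤3 raw moments
  `M_qr = Σ i^q j^r m_ij`, ten centroid-centred central moments, and ten
  discrete orthogonal Hahn moments, with (q, r) in the fixed order
  (0,0),(0,1),(0,2),(0,3),(1,0),(1,1),(1,2),(2,0),(2,1),(3,0) and 0-based
  indices.

The final layout is `[seq raw|central|hahn, PRIM raw|central|hahn, R-PRIM
raw|central|hahn, FV, AAPIV, R-AAPIV, SVV]` = 90 + 63 + 41 = 194 slots,
fixed and exported via `features.feature_schema()`.

### Hahn moments

The Hahn family used is the member whose orthogonality weight on the
support {0, …, P−1} is uniform (both shape parameters 0, i.e. the
Gram/discrete-Chebyshev member). Degree-n values are computed by summing
the terminating hypergeometric series
`3F2(−n, n+1, −x; 1, −(P−1); 1)` term by term and dividing by the square
root of the explicitly summed squared norm over the support, so the basis
is orthonormal by construction (verified to ~1e−15 in tests, against an
exact-rational oracle). With orders ≤ 3 only degrees 0–3 are used; the full
P-degree basis is exposed for reconstruction checks. Printed forms of this
polynomial in the application literature circulate with mutually
inconsistent parameter conventions, several of which are not orthogonal
under any unit weight; the canonical hypergeometric form was chosen
because orthonormality is the property the descriptor actually relies on.

Central moments of an all-zero matrix are defined as 0 (logged); Hahn
moments require support ≥ 4 (orders up to 3 need four points).

## Classifier

A single-hidden-layer network 194 → 23 → 1, logistic activations, trained
with stochastic gradient descent with classical momentum on the logistic
loss (scikit-learn `MLPClassifier`, `solver="sgd"`). Defaults reproduce the
published tuned values: 23 hidden units, learning rate 0.001 (constant),
momentum 0.7, at most 437 epochs. Numerical choices:

* **Standardisation.** Features are z-scored with mean/SD fitted on the
  training rows only (zero-variance columns get unit scale). The moment
  blocks span ~6 orders of magnitude; momentum-SGD at lr 1e−3 does not move
  without it.
* **Minibatch size 32, no improvement-based stop.** At this learning rate
  the loss is nearly flat within the epoch budget using large batches; with
  batches of 32 the optimizer descends reliably, and the epoch cap itself
  (437) is the stopping rule.
* **Determinism.** Initialisation (Glorot-uniform) and epoch shuffling are
  seeded from `ModelConfig.seed`; two runs with the same seed produce
  identical weights.
* **Serialization.** A fitted model is frozen to plain arrays (scaler
  statistics, `W1`, `b1`, `W2`, `b2`) in a versioned JSON file; prediction
  is an explicit forward pass `σ(σ(xW1+b1)·W2+b2)`, so a save/load
  round-trip reproduces scores bit-for-bit and the file is portable across
  languages. Scores ≥ `threshold` (default 0.5, boundary inclusive) are
  predicted positive.

## Evaluation

Accuracy, sensitivity (recall on sites), specificity (recall on non-sites)
and Matthews correlation; MCC is defined as 0 when a denominator factor
vanishes, and Sn/Sp are reported as absent when their class is empty. ROC
curves come from a full threshold sweep with trapezoidal AUC. Protocols:

* **Self-consistency** — train and evaluate on the same rows (a
  memorisation check; informative mainly as an upper bound).
* **Independent test** — train on a stratified 70 % split, report on the
  held-out 30 %.
* **k-fold cross-validation** — stratified, seeded shuffling, one model per
  fold; headline numbers are unweighted means of the per-fold metrics.
  Stratification is required for per-fold Sn/Sp to be estimable.

## Synthetic data generator

Real positive windows are enriched for the sumoylation consensus motif
ψ-K-x-E/D (ψ hydrophobic, fixed here to {A, F, I, L, M, P, V}; E/D
glutamate or aspartate). The generator draws 41-mers with K at position 21
from a background composition (default: uniform over the 20 standard
residues); a positive window receives the motif anchors at positions 20 and
23 with probability `motif_probability` (default 0.8, roughly the motif
prevalence reported for curated sumoylation sites), position 22 ("x")
staying a background draw; negative windows are redrawn until they do not
carry the centred motif. Generation is bit-reproducible under the seed.

What it does *not* emulate: homology/redundancy structure, annotation
noise, non-uniform proteome composition, or any positional preference
beyond the three anchor positions. Consequently, passing pipeline tests on
this generator demonstrates that feature extraction, training and the
protocols work mechanically and that the pipeline finds a genuine
positional signal — it does not certify real-data accuracy.

### Attainable performance on the synthetic task

The generator has a sharp information ceiling: conditional on *not*
carrying the forced motif, a positive window is distributed identically to
a negative one, so an ideal classifier separates only the ~81 % of
positives that carry the motif (≈0.80 forced plus chance occurrences) and
ties on the rest. That caps held-out AUC at ≈0.90 and accuracy at ≈0.90.
The scalar residue coding pushes the practically reachable level well below
the ceiling: detecting the motif means recognising a union of disjoint
intervals of two scalar inputs (codes {1,10,11,13,14,15,20} at position 20,
{4,6} at position 23), which a 23-unit sigmoid network at learning rate
1e−3 and 437 epochs approximates only coarsely. Measured reference values
with default settings, 1,000+1,000 windows, seeds 1–3: held-out AUC ≈ 0.75,
10-fold mean accuracy ≈ 0.71, no-signal control AUC ≈ 0.5 (see
`scripts/acceptance.py`, which recomputes these). Driving the optimizer
harder (tiny batches) reaches training accuracy 1.0 but *lowers* held-out
AUC — the network memorises through the continuous moment features instead
of generalising the motif rule.

## Problem sizes

Default experiment sizes (synthetic benchmark, acceptance script and the
heavier tests) are 1,000 positive + 1,000 negative windows with three
seeds, 70:30 splits and 10-fold CV — large enough for stable AUC estimates
(±~0.02 across seeds) while keeping a full run in minutes on one core.

## Known limitations

* The published benchmark (4,987 positive / 5,000 negative windows from
  UniProtKB, CD-HIT-reduced) is not bundled; dataset construction against
  UniProt and CD-HIT clustering are out of scope. When a local copy of
  those peptide files exists, `seqio.verify_benchmark_counts` checks their
  shape and the standard pipeline runs on them unchanged.
* PRIM's definition in the source literature is ambiguous; the fixed
  reading used here (offsets to the *first* occurrence, zero for absent
  residues) is documented and oracle-tested, but other readings exist.
* Hyperparameter search (successive halving over the published ranges) is
  not re-run; the tuned values are taken as given defaults.
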