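# sumosite

Prediction of lysine **sumoylation** sites from protein sequence.

Sumoylation — the covalent attachment of a Small Ubiquitin-like MOdifier
(SUMO) protein to a substrate lysine — regulates nuclear transport,
transcription, chromatin remodelling and the cell cycle, and is implicated
in cancer and several neurodegenerative diseases. Experimental mapping of
SUMO acceptor lysines is slow and costly, so sequence-based predictors are
used to triage candidate sites. `sumosite` is for computational biologists
who want a transparent, fully reproducible implementation of a
moment-based positional descriptor plus a small neural classifier, with
the standard evaluation protocols built in.

## Method

Every lysine is represented by a 41-residue window (K at position 21,
termini padded with the virtual residue `X`; residues coded 1–21 by
alphabetical amino-acid-name order). The window is mapped to a
**194-dimensional descriptor**:

* frequency vector `FV = {r1, …, r21}`;
* site vicinity vector `SVV` — the 41 codes in order;
* accumulative absolute position incidence vectors `AAPIV`/`R-AAPIV`
  (`u_i = Σ positions of residue i`, forward and reversed);
* position-relative incidence matrices `PRIM`/`R-PRIM`
  (`Z_ij = Σ_{p: c_p = i} (p − firstpos(j))`, 21×21);
* for the 7×7 matrixised window, PRIM and R-PRIM: the ten order-≤3 **raw**
  moments `M_qr = Σ_ij i^q j^r m_ij`, **central** moments `μ_qr` about the
  centroid, and **Hahn** moments `H_qr = Σ_ij ĥ_q(i) ĥ_r(j) m_ij` built
  from orthonormal discrete Hahn polynomials.

Total: 3×30 moments + 21 + 21 + 21 + 41 = 194. A single-hidden-layer
network (194 → 23 → 1, logistic units, SGD with momentum 0.7, learning
rate 0.001, ≤ 437 epochs) classifies the standardised descriptor.
Evaluation: accuracy, sensitivity, specificity, MCC, ROC/AUC under
self-consistency, independent 70:30 and stratified 10-fold protocols.
See `docs/methods.md` for assumptions and numerical choices.

## Worked example

Generate a small labelled synthetic dataset (positives enriched for the
ψ-K-x-E/D consensus motif), featurize it, and cross-validate:

```bash
sumosite synth demo --n-positive 150 --n-negative 150 --seed 7
sumosite extract demo/positive_sequences.txt demo/pos.tsv --format peptide-lines
sumosite extract demo/negative_sequences.txt demo/neg.tsv --format peptide-lines
```

or, from Python:

```python
import numpy as np
from sumosite import (SyntheticConfig, generate, assemble_features,
                      kfold_cv, ModelConfig)

windows, labels = generate(SyntheticConfig(n_positive=150, n_negative=150, seed=7))
X = np.array([assemble_features(w) for w in windows])
report = kfold_cv(X, labels, k=5, config=ModelConfig(seed=7), seed=7)
print(report)
```

which prints

```
[kfold] n=300 Acc=60.00% Sn=58.00% Sp=62.00% MCC=0.2007 AUC=0.6222
```

i.e. five-fold mean accuracy 60.00 %, sensitivity 58.00 % (fraction of
true sites recovered), specificity 62.00 % (fraction of non-sites
recovered), Matthews correlation 0.20 and mean ROC AUC 0.62 on this small
sample — the pipeline finds the planted motif signal well above the
chance level (AUC 0.5) you get when generating with
`motif_probability=0`. Synthetic windows carry less signal than curated
benchmark data; see `docs/methods.md` for what is and is not attainable
on them.

Working with real data instead: `sumosite extract proteins.fasta
windows.tsv` cuts one window per lysine from FASTA, `sumosite featurize`
builds the 194-column table, and `sumosite train / evaluate / crossval /
predict` take it from there. Models are saved as portable JSON and
reloaded predictions are bit-identical.

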