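# itcep

A dual-input convolutional classifier that predicts whether a TCRβ CDR3
sequence recognizes a given MHC-I peptide. Each peptide–CDR3 pair is
encoded as two feature maps that are fused at feature level inside the
network:

- **Module 1** — a single-residue map of the zero-padded, concatenated
  pair: either one-hot (32 × 20, peptide block of 11 rows above a CDR3
  block of 21 rows) or 21 standardized physicochemical scales (32 × 21).
- **Module 2** — a residue-distribution map: either the stacked
  amino-acid composition vectors of peptide and CDR3 (2 × 20), or the
  peptide's **amino-acid position preference** (AAPP) map — the
  per-position residue probabilities over its cognate CDR3 repertoire at
  CDR3 positions 2–21 (20 × 20; position 1, the shared start cysteine,
  is excluded).

Peptides unseen during training are routed to the nearest training
peptide by minimum (Levenshtein) edit distance, whose AAPP map stands in
for the unknown one. Predicted probabilities are discretized into
non-binding / low / medium / high binding levels at 0.5, 0.8 and 0.95.

The network (two convolutional branches, batch normalization,
overlapping 2×2 max pooling, L2-regularized dense fusion head, dropout,
2-way softmax; Adagrad on an MSE loss) is implemented directly on NumPy
— no deep-learning framework is required — with explicit forward and
backward passes in `itcep.nn`, so training is fully deterministic for a
fixed seed.

## Layout

| module | contents |
|---|---|
| `itcep.io_data` | pair-table parsing, curation (length 8–11 peptides / 8–21 CDR3s, alphabet, confidence, dedup), negative sampling, shared/unique splits |
| `itcep.encoders` | one-hot, phychem, AAC and AAPP encoders and the four fusion schemes |
| `itcep.nearest_peptide` | Levenshtein distance and nearest-peptide lookup |
| `itcep.nn` | NumPy layers (conv, batch-norm, max-pool, dense, dropout), Adagrad, MSE-on-softmax loss |
| `itcep.model` | network assembly, training, persistence, prediction records, binding levels |
| `itcep.evaluation` | metrics (precision/accuracy/recall/F1/MCC/AUC) and repeated stratified k-fold CV with per-fold AAPP rebuilding |
| `itcep.fixtures` | synthetic epitope repertoires with planted positional motifs plus background repertoires |
| `itcep.cli` | the `itcep` command |

## CLI

```sh
# generate a synthetic labeled dataset with planted motifs
itcep simulate --n-peptides 10 --tcrs-per-peptide 20 --seed 1 --out runs/sim

# train (writes model weights, AAPP table, curation report, manifest)
itcep train --pairs runs/sim/pairs.csv --scheme onehot-aapp --seed 1 --out runs/model

# score peptide-CDR3 pairs -> five-column CSV
# (peptide, cdr3, probability, interaction, binding_level)
itcep predict-pairs --model runs/model --pairs runs/sim/pairs.csv --out runs/preds.csv

# rank candidate TCRs for peptides
itcep predict-peptide --model runs/model --peptides peps.txt \
    --candidates runs/sim/repertoire.txt --out runs/ranked.csv

# repeated stratified cross-validation
itcep evaluate --pairs runs/sim/pairs.csv --k 5 --repeats 4 --out runs/cv

# minimum-edit-distance lookup
itcep nearest --query NLVPMVATI --candidates peps.txt
```

Model hyperparameters (filters, kernels, dense widths, L2 penalty,
dropout, learning rate, epochs, batch size) default to the published
configuration and can be overridden with `--config config.yaml`.

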