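# cyspred

Toolkit for predicting cysteine-centered post-translational-modification
sites (e.g. S-sulfenylation) from protein sequence. It covers the full
workflow:

- **Fragment extraction** — `2n + 1`-residue windows (default 21-mer)
  centered on each cysteine, X-padded at protein termini.
- **Homology reduction** — pairwise global-alignment identity filtering
  (default 30 %) with exact-window deduplication; training data has
  priority over the independent test set.
- **Eight feature encodings** — per-residue one-hot (20D binary), amino
  acid composition (AAC, 21), amino acid pair composition (AAPC, 441),
  BLOSUM62 rows, position weight matrix (PWM), PSI-BLAST PSSM windows,
  AAindex physicochemical indices, and ASA / secondary-structure tracks.
- **Feature selection** — per-property F-scores, single-property
  accuracy ranking, and forward selection onto a base feature.
- **Classification** — SVM with an RBF kernel, per-feature [-1, 1]
  scaling fitted inside each fold, balanced class weighting, C/gamma
  grid search, stratified five-fold cross-validation reporting
  Sn/Sp/Acc/MCC from pooled confusion counts, and independent testing.
- **Composition analysis** — position-specific residue frequencies,
  two-sample logo enrichment statistics (per-cell two-proportion tests),
  per-position ASA profile comparison, and Venn overlap counts between
  site sets.
- **Synthetic data** — a generator that plants the canonical positional
  signal (K/R and E enrichment, elevated ASA, an informative
  physicochemical axis) so every stage is testable offline.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (encoder
dimensionalities, oracle checks for the metrics and F-score formulas,
planted-signal recovery, homology-reduction guarantees, and end-to-end
determinism).

## Command line

```sh
# synthetic dataset (FASTA + sites + ASA/SS tracks + PSSM profiles)
cyspred generate --n-pos 200 --n-neg 200 --seed 1 --out data/

# train from a YAML run config (see cyspred.pipeline.RunConfig fields)
cyspred train --config run.yaml --seed 1 --out run/

# predict every cysteine in a FASTA file
cyspred predict --model run/model.joblib --fasta data/proteins.fasta \
    --pssm-dir data/pssm --out preds.tsv

# score predictions, enrichment logos, F-score tables
cyspred evaluate --predictions preds.tsv --fragments run/fragments_train.tsv
cyspred logo --set-a pos.tsv --set-b neg.tsv --alpha 0.01 --out logo.tsv
cyspred fscore --fragments all.tsv --aaindex aaindex1.txt --out fscores.tsv
```

A minimal `run.yaml`:

```yaml
fasta: data/proteins.fasta
sites: data/sites.tsv
pssm_dir: data/pssm
encoders: [pssm]
test_fraction: 0.2
grid: {C: [1.0, 8.0], gamma: [0.003, 0.03]}
seed: 1
outdir: run
```

## File formats

- FASTA (non-standard residues normalized to `X` on read)
- site TSV: `protein_id<TAB>position<TAB>label` (1-based, label +-1)
- fragment TSV: `protein_id<TAB>center<TAB>window<TAB>label`
- AAindex1 flat file (entries with `NA` values are flagged and filtered)
- PSI-BLAST ASCII PSSM (`-out_ascii_pssm`; first 20 score columns)
- track TSV: `protein_id<TAB>position<TAB>value` (ASA percent, or H/E/C)
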