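# dtibalance

Drug–target interaction (DTI) prediction toolkit centered on
**reliable-negative selection**: instead of sampling random non-interacting
pairs, a one-class SVM is trained on the known-positive pairs of each of
four feature sets, every unlabeled drug–protein pair is scored by its
signed distance to the positive hyperplane, and the consensus outliers
(most negative combined distance) become predicted negatives — yielding a
balanced training set for a five-classifier benchmark.

## What's inside

| module        | role |
|---------------|------|
| `io_formats`  | FASTA / drug-table / pair-list / feature-matrix file contracts, pair-universe enumeration (streamed in chunks) |
| `descriptors` | Morgan (ECFP4, 1024-bit) + 30 constitutional descriptors per drug; AAC (20) + dipeptide composition (400) per protein; the five pair-feature recipes FS1 (1044), FS2 (1424), FS3 (50), FS4 (430), ALL (1474) |
| `negselect`   | one-class SVM fit on positives, signed distances, per-set z-scored consensus ranking, balanced-set assembly |
| `balance`     | baselines: random undersampling and SMOTE (implemented from the interpolation rule) |
| `classify`    | SVM / random forest / AdaBoost / two gradient-boosting variants under stratified 10-fold CV, with fold-internal balancing |
| `metrics`     | accuracy, precision, recall, F1, MCC, MSE, rank-based (Mann–Whitney) ROC AUC with curve points |
| `featselect`  | genetic-algorithm mask search + booster gain-importance top-k selection |
| `synthdata`   | latent bilinear generator with planted positives / latent positives / displaced true negatives and a held-out truth oracle |

RDKit is used for the drug descriptors only; all downstream stages also
accept precomputed feature blocks/matrices, so the pipeline runs without a
cheminformatics toolkit.

## CLI

```sh
# 1. synthesize a desk-scale dataset (drugs.tsv, proteins.fasta,
#    interactions.tsv, truth.tsv, features_FS*.tsv)
dtibalance synth --preset small --seed 5 --out data/

# 2. pick reliable negatives and build the balanced labeled set
dtibalance negselect --data data/ --seed 5 --out data/labeled.tsv

# 3. benchmark one classifier on one feature set
dtibalance benchmark --data data/ --labeled data/labeled.tsv \
    --features FS1 --model adaboost --folds 10 --seed 5 --out report.json

# 4. optional: feature selection
dtibalance select --data data/ --labeled data/labeled.tsv \
    --features FS3 --method booster --top-k 10 --seed 5 --out mask.txt
```

`truth.tsv` is a held-out oracle (planted labels) used only for evaluating
selections via `synthdata.truth_report`; no pipeline stage reads it.

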