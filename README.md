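# protclass

Protein sequence descriptor encoding and kernel-SVM classification.

`protclass` turns protein sequences into fixed-length numeric descriptor
vectors under five schemes, trains binary support-vector machines with four
kernels on them, and evaluates classifiers under balanced-resampling
cross-validation protocols designed for heavily imbalanced two-class
sequence data.

| scheme | meaning | dimension |
|--------|---------|-----------|
| AAC    | amino acid composition (residue frequencies) | 20 |
| DPC    | di-peptide composition (overlapping pair frequencies) | 400 |
| PAAC   | pseudo amino acid composition (Chou) | 20 + λ (21 for λ = 1) |
| CTD    | composition / transition / distribution (Dubchak, 7 attributes) | 147 |
| ACF    | lagged autocorrelations of AAindex physicochemical values | 531 × n |

The ACF scheme ships with a plain-text AAindex1 snapshot (544 entries;
the 531 with complete residue values are retained, entries containing `NA`
are excluded at load time).

## Library overview

```python
import protclass as pc

records = pc.read_fasta("proteins.fasta")            # validated ProteinRecord list
vec     = pc.encode_dpc(records[0])                  # one 400-vector
enc     = pc.get_encoder("DPC")                      # batch encoder with fingerprint
feats   = enc.transform(records)                     # FeatureMatrix

model = pc.train_svm(feats, labels, pc.KernelSpec("rbf"), c=1.0, seed=0)
pred  = pc.predict(model, feats)                     # labels, probabilities, scores

report = pc.evaluate_balanced(
    positives, negatives, enc,
    kernel=pc.KernelSpec("rbf"), n_sets=100, k=10, seed=0,
)
print(report.summary())                              # mean ± sd per metric
```

Evaluation follows the balanced-resampling protocol: each sample set
contains all positives plus an equal-size random draw of negatives;
each set is scored by stratified 10-fold cross-validation (or LOOCV for
small sets); Sn, Sp, Ac, Pre, MCC and trapezoidal AUC-ROC are averaged
over folds and sample sets.

A synthetic-data module (`protclass.synthetic`) generates labeled
first-order Markov sequence sets with controllable composition or
di-peptide signal, so every pipeline stage is testable offline.

## Command line

```sh
protclass simulate --preset leucine --n-pos 50 --n-neg 200 --seed 1 --out-prefix data/sim
protclass encode data/sim.fasta --scheme DPC --out features.csv
protclass train pos.fasta neg.fasta --scheme DPC --kernel rbf --out model.joblib
protclass cv pos.fasta neg.fasta --scheme DPC --n-sets 100 --k 10 --out-prefix report
protclass predict query.fasta --model model.joblib --out predictions.tsv
```

Options can also come from a `key = value` config file (`--config run.cfg`);
flags override the file, unknown keys are rejected, and the resolved
configuration is echoed as `<output>.config.json` next to every output.
Prediction output is a TSV of `sequence_id`, `predicted_label` and the
calibrated positive-class probability; sequences below a scheme's minimum
length are flagged `NA` rather than aborting the batch.

## Tests and acceptance report

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-measures the encoder output dimensions (AAC = 20,
DPC = 400, ACF at order 1 with the packaged snapshot = 531) by encoding a
seeded random 100-mer and writes them as JSON.
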