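# promokit

Promoter sequence classification toolkit for regulatory genomics.

Gene promoters — the regions around transcription start sites (TSSs) that
control transcription initiation — lack universally explicit sequence
features, which makes rule- and alignment-based prediction brittle.
`promokit` implements a complete machine-learning pipeline for promoter
classification on fixed-length sequences (by default the −700/+300
window around the TSS, 1,000 nt):

* **Sequence handling** — FASTA read/write, cleaning, strand-aware
  promoter-window extraction from a genome plus BED TSS table, and
  random genomic window sampling for negative-control testing.
* **Synthetic negatives** — each promoter is paired with a shuffled copy
  of itself (mononucleotide permutation, or a dinucleotide-preserving
  Altschul–Erickson Eulerian shuffle), giving an exactly 1:1,
  composition-matched background that forces classifiers to learn
  positional structure rather than GC content.
* **Encodings** — overlapping k-mers at stride 1 (k ∈ {1, 2, 4, 8}),
  either frequency-based tokenization (FBT: ranks 1..V by descending
  training-corpus count, 0 reserved for out-of-vocabulary) producing an
  integer vector of length L−k+1, or one-hot encoding producing a binary
  4^k × (L−k+1) matrix.
* **Models** — a CNN (3 × width-5 conv + max-pool(4, stride 1), dense
  1,025/512/128 with 20% dropout), an LSTM (128 units → dense 64 → 50%
  dropout) and a 300-tree random forest (bootstrap off), trained up to
  10 epochs, batch 128, Adam, early stopping on validation loss. The
  neural models run on a small gradient-checked NumPy engine
  (`promokit.nn`); the forest is scikit-learn.
* **Evaluation** — stratified 81/9/10 splits and four designs: binary
  (promoter vs shuffled negative), cross-species transfer, random-genome
  negative control, and multiclass species-of-promoter classification,
  all scored with accuracy, sensitivity, specificity and

  MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

A seeded synthetic-data module generates promoter-like fixture corpora
(planted, mutated, position-jittered motifs over controllable GC
backgrounds) so the whole pipeline is testable and benchmarkable with no
downloads. See `docs/methods.md` for the full model and generator
description.

## Worked example

```python
import promokit as pk

# promoter-like sequences for one pseudo-species + paired shuffled negatives
profile = pk.default_profiles(length=250)[0]
promoters = pk.generate_promoters(profile, n=1000, seed=0)
dataset = pk.build_binary_dataset(promoters, mode="mononucleotide", seed=1)

model = pk.PromoterClassifier(dataset, model="cnn", encoder="fbt", k=2)
result = model.fit(seed=1)
print(result.summary())
```

```
Promoter classification results
==============================================
model:            CNN
encoder:          fbt (k=2)
classes:          2
sequence length:  250 nt (249 k-mer positions)
train/val/test:   1620/180/200
seed:             1
----------------------------------------------
test Acc:         0.97
test Sn:          0.99
test Sp:          0.96
test MCC:         0.95
epochs run:       7 (early-stopped at epoch 7); final val loss 0.0708
==============================================
```

The model separates promoters from their own shuffled counterparts with
MCC 0.95: since every negative has exactly the composition of its paired
positive, that performance reflects learned positional motif structure,
not base content. `result.predict(records)`, `result.score_background(...)`
and `result.plot_history()` operate on the fitted result; the experiment
runners (`run_binary_experiment`, `run_cross_species`,
`run_multiclass_experiment`, `run_random_negative_test`) return tidy
result tables for multi-model comparisons.

A command line mirrors the library:

```bash
promokit simulate --n 1000 --length 250 --seed 1 -o fixtures/
promokit make-negatives --in fixtures/unicell.fa --mode mono --seed 2 -o ds.fa
promokit evaluate --model rf --encoder fbt --k 2 --data ds.fa --seed 3
promokit extract --genome genome.fa --tss tss.bed -o promoters.fa
```

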