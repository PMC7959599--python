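# Methods

## Problem and scope

`promokit` classifies fixed-length DNA sequences as promoters or
non-promoters, and promoters by species of origin. A promoter is
operationalised as the asymmetric window around a transcription start
site (TSS): by default 700 bp upstream and 300 bp downstream, a 1,000-nt
sequence. The package covers the full experimental pipeline: promoter
window extraction, synthetic negative construction by shuffling, k-mer
feature extraction and encoding, three classifier architectures, and
binary / cross-species / multiclass evaluation with Acc, Sn, Sp and MCC.

## Data model and conventions

Coordinates are 0-based half-open (BED convention). On the minus strand
the upstream/downstream offsets are mirrored in genome coordinates and
the extracted window is reverse-complemented, so every promoter reads
5'→3' relative to its own gene. Data cleaning keeps exactly the records
of the required length whose bases are all A/C/G/T; there is no N-masking
or imputation — the 4^k encodings leave no sensible slot for ambiguity
codes. FASTA ids are the header up to the first whitespace; class labels
and species tags round-trip through headers as `|label=1|species=tag|`
fields.

## Negative sets

The training negative class is built by shuffling each promoter once,
giving an exactly 1:1 paired dataset in which every negative has the
per-record base composition of its positive. Two shuffle modes:

* **mononucleotide** (default) — uniform random permutation of the
  characters; preserves single-nucleotide counts.
* **dinucleotide** — a random Eulerian walk over the dinucleotide
  transition multigraph (Altschul–Erickson construction): each adjacent
  pair of the input is an edge, a per-vertex "last exit" edge set forming
  a tree into the terminal character guarantees the walk completes, and
  the remaining edges are visited in random order. All 16 dinucleotide
  counts and the first/last characters are conserved exactly. This is
  the stricter control when CpG-like dinucleotide structure could act as
  a confound.

Per-record shuffle seeds are derived from the master seed and the record
index, so datasets are reproducible independent of iteration order.
Random genomic windows (uniform over all valid positions, forward strand,
non-ACGT windows rejected and redrawn) are supported as a *test-time*
negative set only; training against same-genome non-promoter regions is
deliberately out of scope because composition-matched shuffles are the
harder, less confounded control.

## Feature extraction and encoding

Sequences are decomposed into overlapping k-mers at stride 1 (a length-L
sequence gives L−k+1 windows; the supported grid is k ∈ {1, 2, 4, 8}).
Two encoders:

* **Frequency-based tokenization (FBT)** — k-mers are ranked by
  descending count over the *training split only* and mapped to indices
  1..V in rank order; ties break lexicographically so vocabularies are
  platform-independent. Index 0 is reserved: it is never assigned at fit
  time and marks out-of-vocabulary k-mers when a frozen vocabulary meets
  held-out or cross-species data. No size cap and no minimum count are
  applied, so at k=8 the vocabulary can approach 4^8 = 65,536 entries.
* **One-hot** — each k-mer becomes an indicator column over all 4^k
  k-mers in lexicographic channel order (A<C<G<T per position), a binary
  matrix of shape 4^k × (L−k+1); every column sums to 1. The matrix is
  losslessly decodable back to the sequence via the overlap-consistency
  of adjacent windows, which the decoder verifies.

Encoded corpora carry an input contract (encoder, k, source length,
vocabulary checksum); models refuse inputs whose contract does not match
the one they were trained under.

## Classifier architectures

* **CNN** — [embedding (FBT) or raw 4^k channels (one-hot)] → 3 ×
  (width-5 1D convolution, ReLU, same-length padding → max-pool size 4,
  stride 1) → flatten → dense 1,025 → 512 → 128 (ReLU, 20% dropout each)
  → head. The pool stride of 1 barely downsamples (3 positions per
  layer); it is kept as printed. The 1,025-unit layer is likewise kept
  verbatim rather than "corrected" to 1,024.
* **LSTM** — embedding → 128-unit LSTM (final state) → dense 64, ReLU →
  50% dropout → head.
* **Random forest** — 300 trees, `min_samples_split=2`, bootstrap off
  (so refits at a fixed seed are deterministic), consuming the flat FBT
  token vectors positionally. Token indices are nominal, not ordinal;
  feeding them to axis-aligned trees is a faithful reproduction of the
  design this package implements, not a recommendation. Bag-of-k-mer
  count features are deliberately not provided.

Binary heads are a single sigmoid unit with binary cross-entropy;
multiclass heads are a softmax over classes with sparse categorical
cross-entropy (a sigmoid multiclass head is incompatible with that loss,
so softmax is used). The decision rule is P ≥ 0.5 → positive (ties
positive) for binary and argmax with ties toward the smaller class index
for multiclass.

Unstated-by-design defaults, exposed in the specs: 64 convolution
filters per layer and embedding dimension 32 (mid-sized values typical
for 1D sequence models; the model *comparison*, not capacity, is the
point), early-stopping patience 2.

### The NumPy network engine

`promokit.nn` is a compact NumPy implementation of exactly the layers
these architectures need (embedding, same-padded 1D convolution via
im2col, max-pooling, dense, dropout, LSTM) with fused
sigmoid/softmax-cross-entropy losses, mini-batch Adam (step size 0.001,
β₁=0.9, β₂=0.999), Glorot-uniform initialisation, and early stopping on
validation loss. Training runs at most 10 epochs with batch size 128.
All parameters are float32; every layer's analytic gradient is validated
against central finite differences in the test suite. Max-pool gradients
route to the first position attaining the window maximum; forget-gate
biases initialise to 1.

## Splitting and evaluation

Splits are stratified: 10% test, then 10% of the remainder as validation
(81/9/10 overall), deterministic under the seed, with a runtime assertion
that the three parts are disjoint. Metrics follow the standard
definitions (1 = promoter = positive):

    Acc = (TP+TN)/(TP+TN+FP+FN)    Sn = TP/(TP+FN)    Sp = TN/(TN+FP)
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC with a zero denominator is reported as 0 (the conventional limit);
an undefined Sn or Sp (empty class) is NaN, never silently 0. Multiclass
runs report overall accuracy, unweighted macro one-vs-rest Sn/Sp, and
the multi-category MCC from the full confusion matrix (which reduces to
the binary MCC at two classes). Reports print to 2 decimals; stored
values are unrounded.

Cross-species evaluation trains on one species' training split and
scores every other species' *entire* dataset, encoded under the training
species' vocabulary (no leakage is possible across species, and using
the full dataset maximises test power).

## Synthetic fixture corpora

The generator emulates the statistical structure the classifiers
exploit: positional promoter elements over a species-specific
background. Each pseudo-species profile plants short motifs at fixed
offsets (anchored upstream of a notional TSS at 70% of the sequence
length, mirroring the −700/+300 layout) into an i.i.d. A/C/G/T
background. Three realism features, each with a clear knob:

* **per-position motif mutation** (default 0.10) — high enough that
  motif memorisation fails, low enough that a one-rule scan classifier
  still reaches the 0.95 learnability floor;
* **per-sequence GC spread** (`gc_sd`, default 0.07 in the default
  profiles) — real promoter sets have broad, overlapping GC
  distributions, so composition is a noisy cue rather than a species
  fingerprint;
* **motif position jitter** (±12 nt in the default profiles) — core
  elements such as TATA boxes occur at variable offsets relative to the
  TSS. Positional jitter is also what separates the learners: a
  convolution detects a motif wherever it lands, whereas axis-aligned
  splits on positional token features degrade, reproducing the
  CNN-over-RF ordering seen on real promoter data.

The three default profiles carry pairwise-distinct 12-nt motifs
(TATA-box-like, G-box/CAAT-like, GC-box-like) and distinct background GC
(0.38 / 0.36 / 0.46), so within-species classification is learnable
while cross-species transfer degrades by construction. Fixture sequences
default to 250 nt — the signal structure, not the length, is what
matters — with 1,000-nt generation available. An independent motif-scan
oracle (primary motif within the jitter window at ≤30% mismatches)
certifies each fixture: ≥0.95 accuracy within profile, ≤0.6 across
profiles, so end-to-end model tests measure the pipeline rather than the
data.

What the generator does *not* emulate: higher-order genomic background
structure (an i.i.d. background is the default; dinucleotide-structured
backgrounds would be needed to exercise the dinucleotide shuffle
meaningfully), CpG-island statistics, real TSS-distance distributions,
or repeat content. Passing fixture benchmarks therefore demonstrates
that the pipeline learns planted positional signal under composition
control — not that these accuracies transfer to real genomes.

## The benchmark study

`promokit.study.run_fixture_study` runs the full design at the default
study size (3 pseudo-species × (1,000 promoters + 1,000 paired shuffled
negatives), 250 nt, k=2, FBT): per-species binary CNNs, the 3×3
cross-species matrix reusing those models, a negative-control test of
the last species' model against 600 composition-matched random
background sequences, and the 3-way multiclass comparison of CNN vs RF
at the same seed. These sizes keep a full run in the tens of minutes on
a single CPU core while leaving all qualitative contrasts (binary
learnability, transfer degradation, CNN>RF ordering) comfortably
resolved.

## Known limitations

* The LSTM trains by full backpropagation through time in Python-loop
  steps; it is the slowest model per epoch and is excluded from the
  default benchmark study (binary and multiclass CNN/RF cover the
  headline contrasts).
* One-hot encoding at k=8 allocates 65,536 channels per position and is
  practically unusable, as expected; FBT is the intended encoder for
  large k.
* `clean_records` drops rather than repairs; genomes with heavy
  soft-masking or N-density simply yield fewer usable windows.
* The random-subsequence sampler draws the forward strand only.
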