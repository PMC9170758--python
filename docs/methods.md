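# Methods

## Problem and model

Pseudouridine (Ψ) is the most abundant post-transcriptional RNA
modification; whether a given uridine is pseudouridylated is largely
determined by its local sequence context (pseudouridine synthases such
as PUS4 and PUS7 recognize the contexts GUΨCNA and UGΨAG). This package
models that determination with a small convolutional network over the
101-nt window centered on a candidate uridine, written in the DNA
alphabet (T for U) as references are.

The network is:

    input 101×4 (one-hot, channels A,C,G,T; N = zero row)
    → conv(64 filters, width 8, valid)  → batch norm → PReLU → max-pool(2)
    → conv(32 filters, width 8, valid)  → batch norm → PReLU → max-pool(2)
    → flatten (20×32 = 640)
    → dense(64) → PReLU → dropout
    → dense(64) → PReLU → dropout
    → dense(1)  → sigmoid

yielding the local pseudouridylation potential score lPPS ∈ [0, 1]
for the central uridine. Feature-map lengths for the default constants
are 94 → 47 → 40 → 20. The classification head is a single logistic
unit; with one output this is exactly the two-class softmax with a
fixed reference logit. The hidden dense layers reuse PReLU (one
learnable negative-side slope per channel, initialized at 0.25).
The decision threshold is 0.5 everywhere, matching the indicator used
by the transcript score below.

The network, including backpropagation through convolution
(im2col cross-correlation), batch normalization, PReLU, max pooling,
dense layers and inverted dropout, is implemented directly in numpy.
This keeps the whole training trajectory bit-reproducible for a fixed
seed on a fixed platform, which the determinism guarantees below rely
on.

## Sample construction

* **Positives** — each validated Ψ site (reference base must resolve to
  T on its strand; other records are discarded and counted) yields the
  101-nt window with 50-nt flanks. Windows running off the sequence end
  are 'N'-padded rather than dropped, the same rule the transcriptome
  scanner uses, so one convention holds everywhere.
* **Negatives** — for each positive, the nearest thymine(s) on the same
  sequence and strand whose own 101-nt window overlaps no positive
  window. Equidistant candidates resolve to the downstream one.
  Imbalanced sets (PNR 1:n) take the nearest n such thymines.
  Negative windows may overlap each other; duplicates (same center)
  are emitted once.
* Coordinates are 0-based half-open; minus-strand windows are
  reverse-complemented so every sample reads 5′→3′ with the candidate
  at index 50.

## Training

Binary cross-entropy minimized by SGD with classical momentum 0.9,
batch size 64, up to 100 epochs, early stopping on a validation split
(10% of the training portion when no explicit validation set is given)
with patience 10 and min-delta 1e-4; the parameters from the best
validation epoch are restored. Gradients are clipped to global norm 10
— this leaves learnable-signal trajectories unchanged but prevents
float32 overflow when the data carry no signal (e.g. permuted labels).
Batch-norm running statistics use momentum 0.9 (≈25 batches per epoch
means the inference statistics settle within a few epochs, so the
early-stopping validation loss is meaningful from the start).

Default learning rate is 0.1 with dropout 0.5. These were chosen on the
synthetic benchmark: at lr 0.01 this SGD stack underfits (training AUC
plateaus near 0.97 on a perfectly separable planted-motif set), while
lr 0.2 diverges; 0.1 converges quickly and held-out AUC is ~0.95.
Both parameters are grid-searchable; the default grid is
learning rate {0.1, 0.01, 0.001} × dropout {0.25, 0.5}.

**Nested cross-validation.** Outer k-fold (default 10) estimates
generalization; within each outer-training portion an inner k-fold grid
search picks the hyperparameter combination with the highest mean inner
validation AUC, the winning configuration is refit on the full
outer-training portion, and out-of-fold predictions are pooled across
outer folds. All reported CV metrics are computed once on the pooled
out-of-fold score vector, never averaged per fold. Plain k-fold CV with
fixed hyperparameters follows the same pooling rule.

## Evaluation

AUC is the Mann–Whitney pair statistic (ties half credit; trapezoidal
ROC equivalence), delegated to scikit-learn and cross-checked in the
test suite against an O(n²) pair-counting oracle. Precision, recall,
F1 and MCC come from the strict score > 0.5 call; metrics whose
denominator is zero are reported as 0 with an explicit `degenerate`
flag instead of NaN.

## Motif extraction

Each first-layer filter (width 8) is slid over every positive sample;
the activation is the raw cross-correlation plus the filter bias,
computed in inference mode **before** batch normalization, PReLU and
pooling, following the visualization convention established for
sequence CNNs. Segments whose activation strictly exceeds half of the
filter's global maximum (over all positive samples and offsets) are
collected into an 8-column PWM of per-position base frequencies ('N'
contributes to no channel; columns renormalize over observed bases; no
pseudocount by default). Filters whose segments cover more than 1% of
the positive samples (configurable) are retained as high-confidence
motifs and can be exported in MEME minimal format. The per-filter
maximum is global rather than per-sequence — the natural reading for a
filter-level threshold — and segments are taken from positive samples
only.

Motif recovery is quantified by the best mean per-column Pearson
correlation between a discovered PWM and the planted consensus PWM over
all ungapped offsets; constant columns (uniform 'N' columns) are
skipped in the mean.

## Transcriptome scoring

* **lPPS** — every thymine of a transcript is scored from its 101-nt
  window, 'N'-padded at the transcript edges. Scanning is
  single-strand: transcripts are assumed to be supplied in transcript
  orientation.
* **tPPS** — for a transcript of length L with K thymines, of which
  numΨ have lPPS > 0.5 and numU have lPPS ≤ 0.5:
  tPPS = (numΨ / numU) / (K / L). The numerator is the Ψ:U odds among
  thymines; the denominator removes the bias toward uridine-rich
  transcripts. tPPS is undefined (flagged, not NaN-propagated) when
  K = 0 or numU = 0.
* **AFCP** — for an SNV with major allele M and minor allele m, both
  alleles are substituted into the reference context, the thymine
  nearest the variant that is T in *both* allele sequences and within
  ±50 nt is taken as the target (ties downstream; a single target
  uridine per variant), and
  AFCP = log2(lPPS_major + ε) − log2(lPPS_minor + ε) with ε = 1e-6.
  The ε guards against score underflow; computing the log ratio as a
  difference makes antisymmetry under an allele swap bit-exact.
  Variants with no eligible target are skipped with an explicit reason.

## Synthetic benchmark

The generator emulates the structure of a Ψ profiling training set
without any download. Defaults are the repository's study conditions:
1000 positives / 1000 negatives; planted contexts GT[T]CNA (PUS4) and
TG[T]AG (PUS7), chosen uniformly per positive; embedding probability
1.0; the motif's Ψ lands within ±2 nt of the window center (jitter 2);
uniform background composition (GC 0.5); seed 7. Consensus 'N' is
instantiated uniformly. Negatives get a forced central T and are
rejection-sampled to contain no occurrence of any configured consensus,
so labels are noise-free at embedding probability 1. Because the
central base is forced to T *after* embedding (the sample invariant is
hard), a jittered motif overlapping the center can lose one base — a
small, realistic label noise.

The transcriptome generator plants Poisson-distributed,
non-overlapping motif instances in random transcripts and emits the
truth BED; the variant generator places a stated fraction of SNVs
inside planted motif footprints (never on an 'N' consensus position)
and the rest in background at least 60 nt from any planted site.

What the benchmark does *not* emulate: experimental false negatives
(incomplete CMC labeling, mappability), transcript-level sequence
composition bias, multiple co-occurring synthase preferences with
unequal frequencies, and the weak, distributed contexts of real
profiling data. Passing the benchmark therefore demonstrates that the
implementation learns, localizes and quantifies planted contexts
correctly — not that the architecture reaches any particular accuracy
on real profiling data.

## Problem sizes and numerical choices

The repository's standing benchmark uses 5-fold CV at n = 2000 with the
default architecture (~90 s per CV on one CPU core), a full-data model
for motif extraction and variant scoring, a 30-transcript synthetic
transcriptome, 60 variants, and a 3-replicate permutation null. The
permutation null redraws both the label permutation and the weight
initialization per replicate and reports the mean held-out AUC: a fixed
initialization responds weakly but systematically to the planted motifs
even before training, so single-replicate nulls with a shared seed are
biased estimators of the chance level.

Other numerical conventions: ROC ties get half credit; exact-threshold
scores (lPPS = 0.5) are non-Ψ; all-zero filters produce no activation
segments (strict half-max threshold); model archives are versioned and
refuse to load on a version mismatch; encoding maps U→T and is
case-insensitive, rejecting anything outside {A,C,G,T,U,N}.

## Known limitations

* Training assumes the whole encoded sample set fits in memory
  (a 101×4 float32 matrix per sample; ~1.6 MB per 1000 samples).
* Single-strand scanning only; genome-wide both-strand scans require
  the caller to supply both orientations.
* The numpy implementation is single-core; nested CV with large grids
  is the dominant cost and scales as k_outer × k_inner × |grid|.
* AFCP evaluates one target uridine per variant (the nearest shared
  thymine), not an aggregate over all windows containing the variant.
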