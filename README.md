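# pulse-psi

Sequence-context modeling of RNA pseudouridylation (Ψ). A small
convolutional network reads the 101-nt window centered on a candidate
uridine (DNA alphabet, T for U) and emits its **local pseudouridylation
potential score** (lPPS ∈ [0, 1]). On top of the classifier the package
provides:

* construction of training sets from Ψ-site coordinates and a reference
  FASTA (nearest non-overlapping-thymine negatives, balanced or 1:n),
* plain and nested cross-validation with grid search,
* the evaluation statistics used for imbalanced Ψ-site benchmarks
  (ROC/AUC, precision, recall, F1, MCC),
* sequence-motif extraction from trained first-layer filters
  (half-max activation scanning → PWM → MEME minimal format),
* transcriptome-wide scoring: per-uridine lPPS, the per-transcript
  statistic **tPPS** = (numΨ/numU)/(K/L) for a transcript with K
  thymines and length L,
* variant-effect scoring: **AFCP**, the log2 fold change of lPPS
  between the major and minor allele of an SNV, and
* a seeded synthetic generator that plants the PUS4/PUS7 consensus
  contexts (GT[T]CNA, TG[T]AG) into background sequence, so the whole
  pipeline is testable end to end without downloads.

The intended users are computational biologists studying RNA
modifications who need either a trainable Ψ-site model for their own
profiling data or a controlled benchmark for modification-site
classifiers. The CNN — two valid convolution + max-pool blocks
(64×8 and 32×8 filters, pool 2), batch norm, PReLU, a 64-64-1 dense
head with dropout, SGD with momentum and early stopping — is
implemented directly in numpy with hand-written backpropagation, so
results are bit-reproducible for a fixed seed. See
[docs/methods.md](docs/methods.md) for the model, the sampling rules
and all numerical conventions.

## Worked example

Train on the default planted-motif benchmark, extract motifs, and score
a variant:

```python
from pulse import (SyntheticConfig, generate_dataset, ModelConfig,
                   cross_validate, train, high_confidence_motifs,
                   consensus_pwm, pwm_match_score, VariantRecord, afcp)
from pulse.evaluate import evaluate_cv
from pulse.seqdata import encode_samples

samples = generate_dataset(SyntheticConfig(seed=7))   # 1000 pos / 1000 neg
cv = cross_validate(samples, ModelConfig(seed=1), k=5, seed=7)
m = evaluate_cv(cv)
print(f"pooled AUC {m.auc:.3f}  precision {m.precision:.3f} "
      f"recall {m.recall:.3f}  MCC {m.mcc:.3f}")

X, y = encode_samples(samples)
model = train((X, y), None, ModelConfig(seed=1))
positives = [s for s in samples if s.label == 1]
motifs = high_confidence_motifs(model, positives)     # >1% coverage filter
best = max(pwm_match_score(mo.pwm, consensus_pwm("GTTCNA")) for mo in motifs)
print(f"{len(motifs)} motifs; best match to planted GT[T]CNA: r = {best:.2f}")
```

Output:

```
pooled AUC 0.934  precision 0.870  recall 0.892  MCC 0.759
64 motifs; best match to planted GT[T]CNA: r = 0.85
```

The pooled AUC is computed once over the out-of-fold predictions of all
2000 samples (never averaged per fold). The motif-match score is the
mean per-column Pearson correlation between a discovered 8-column PWM
and the planted consensus PWM at the best ungapped alignment — 0.85
means the filter has essentially re-learned the planted PUS4 context.

The same steps from a shell:

```bash
pulse simulate dataset --seed 7 --out work/
pulse cv    --samples work/samples.tsv --k 5 --seed 7 --out work/cv.json
pulse train --samples work/samples.tsv --seed 1 --out work/model.pulse
pulse motifs --model work/model.pulse --samples work/samples.tsv --out work/motifs.meme
pulse scan  --model work/model.pulse --fasta transcripts.fa --out work/lpps.tsv
pulse tpps  --scores work/lpps.tsv --fasta transcripts.fa --out work/tpps.tsv
pulse afcp  --model work/model.pulse --vcf snvs.vcf --fasta ref.fa --out work/afcp.tsv
```

For real data, `pulse prepare --sites sites.bed --fasta ref.fa --pnr 1
--out samples.tsv` builds the sample table from Ψ-site coordinates:
sites not on a (strand-resolved) thymine are discarded and counted, each
kept site becomes a positive 101-nt window, and negatives are the
nearest thymines whose windows overlap no positive window.

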