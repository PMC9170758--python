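"""Sequence motifs from trained first-layer convolution filters.

Each width-8 filter is slid over every positive 101-nt sample; the 8-mer
segments whose raw activation (convolution + bias, before batch
normalization, PReLU, and pooling) strictly exceeds half of the filter's
global maximum are collected and converted to an 8-column position
weight matrix.  Filters whose segments cover more than a configurable
fraction of the positive samples (default 1%) yield high-confidence
motifs.  Motifs can be exported in MEME minimal format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .model import TrainedModel
from .seqdata import LabeledSample, encode_samples, _BASE_INDEX

ALPHABET = "ACGT"


@dataclass
class ActivationSegment:
    sample_index: int
    offset: int            # 0-based window start within the 101-nt sample
    subsequence: str       # 8-mer
    activation: float


@dataclass
class FilterMotif:
    filter_id: int
    pwm: np.ndarray        # (width, 4) probabilities, columns sum to 1
    n_segments: int
    coverage: int          # distinct positive samples contributing >= 1 segment

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.pwm.argmax(axis=1))


def scan_filter_activations(
    model: TrainedModel,
    positives: Sequence[LabeledSample],
    filter_id: int,
) -> list[ActivationSegment]:
    """Half-max activation scan of one first-layer filter.

    Activations are the raw cross-correlation of the filter with the
    one-hot window plus the filter bias, in inference mode; the
    threshold is strict (> half of the global maximum over all samples
    and offsets).
    """
    conv1 = model.net.conv1
    if not 0 <= filter_id < conv1.out_channels:
        raise IndexError(f"filter_id {filter_id} out of range [0, {conv1.out_channels})")
    w = conv1.filter_weights(filter_id)          # (kernel, 4)
    b = float(conv1.b[filter_id])
    k = conv1.kernel
    X, _ = encode_samples(positives)             # (n, 101, 4)
    cols = sliding_window_view(X, k, axis=1)     # (n, offsets, 4, k)
    acts = np.einsum("nock,kc->no", cols, w) + b
    threshold = acts.max() / 2.0
    segments = []
    for n, o in zip(*np.nonzero(acts > threshold)):
        segments.append(
            ActivationSegment(
                sample_index=int(n),
                offset=int(o),
                subsequence=positives[n].sequence[o:o + k],
                activation=float(acts[n, o]),
            )
        )
    return segments


def build_pwm(segments: Sequence[ActivationSegment], filter_id: int = -1,
              pseudocount: float = 0.0) -> FilterMotif:
    """Per-position base frequencies across the collected 8-mers.

    'N' characters contribute to no channel; each column renormalizes
    over the bases actually observed (an all-'N' column is uniform).
    """
    if not segments:
        raise ValueError("cannot build a PWM from zero segments")
    width = len(segments[0].subsequence)
    counts = np.zeros((width, 4), dtype=np.float64)
    for seg in segments:
        for j, ch in enumerate(seg.subsequence):
            idx = _BASE_INDEX.get(ch)
            if idx is not None:
                counts[j, idx] += 1.0
    counts += pseudocount
    col_sums = counts.sum(axis=1, keepdims=True)
    pwm = np.where(col_sums > 0, counts / np.maximum(col_sums, 1e-300), 0.25)
    coverage = len({seg.sample_index for seg in segments})
    return FilterMotif(filter_id=filter_id, pwm=pwm,
                       n_segments=len(segments), coverage=coverage)


def high_confidence_motifs(
    model: TrainedModel,
    positives: Sequence[LabeledSample],
    min_coverage_fraction: float = 0.01,
) -> list[FilterMotif]:
    """Scan every first-layer filter and keep well-supported motifs.

    A motif is retained when its segments come from more than
    ``min_coverage_fraction`` of the positive samples.
    """
    cutoff = min_coverage_fraction * len(positives)
    motifs = []
    for f in range(model.net.conv1.out_channels):
        segments = scan_filter_activations(model, positives, f)
        if not segments:
            continue
        motif = build_pwm(segments, filter_id=f)
        if motif.coverage > cutoff:
            motifs.append(motif)
    return motifs


# ---------------------------------------------------------------------------
# motif comparison (used to validate recovery of a planted consensus)


def consensus_pwm(consensus: str) -> np.ndarray:
    """PWM of a consensus string; IUPAC 'N' becomes a uniform column."""
    pwm = np.zeros((len(consensus), 4))
    for j, ch in enumerate(consensus.upper().replace("U", "T")):
        if ch == "N":
            pwm[j] = 0.25
        else:
            pwm[j, _BASE_INDEX[ch]] = 1.0
    return pwm


def pwm_match_score(pwm: np.ndarray, target: np.ndarray) -> float:
    """Best mean per-column Pearson correlation over ungapped offsets.

    The shorter matrix slides along the longer one; columns where either
    side is constant (zero variance, e.g. a uniform 'N' column) are
    skipped in the mean.
    """
    if len(target) > len(pwm):
        pwm, target = target, pwm
    best = -1.0
    m = len(target)
    for off in range(len(pwm) - m + 1):
        rs = []
        for j in range(m):
            a, b = pwm[off + j], target[j]
            if np.std(a) < 1e-12 or np.std(b) < 1e-12:
                continue
            rs.append(np.corrcoef(a, b)[0, 1])
        if rs:
            best = max(best, float(np.mean(rs)))
    return best


# ---------------------------------------------------------------------------
# MEME minimal format


def write_meme(motifs: Sequence[FilterMotif], path: str | Path) -> None:
    """MEME minimal motif format, alphabet ACGT, uniform background."""
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: +", "",
        "Background letter frequencies",
        "A 0.25000 C 0.25000 G 0.25000 T 0.25000", "",
    ]
    for motif in motifs:
        lines.append(f"MOTIF filter_{motif.filter_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(motif.pwm)} "
            f"nsites= {motif.n_segments} E= 0"
        )
        for row in motif.pwm:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> list[FilterMotif]:
    """Parse the MEME minimal format written by :func:`write_meme`."""
    motifs = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            filter_id = int(name.rsplit("_", 1)[-1]) if "_" in name else -1
            i += 1
            header = lines[i].strip()
            if not header.startswith("letter-probability matrix"):
                raise ValueError(f"{path}: expected matrix header after MOTIF {name}")
            w = int(header.split("w=")[1].split()[0])
            nsites = int(header.split("nsites=")[1].split()[0])
            pwm = np.array(
                [[float(v) for v in lines[i + 1 + j].split()] for j in range(w)]
            )
            motifs.append(FilterMotif(filter_id=filter_id, pwm=pwm,
                                      n_segments=nsites, coverage=0))
            i += w
        i += 1
    return motifs


def write_segments_tsv(segments: Sequence[ActivationSegment], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "sample_index": [s.sample_index for s in segments],
            "offset": [s.offset for s in segments],
            "subsequence": [s.subsequence for s in segments],
            "activation": [s.activation for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)
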