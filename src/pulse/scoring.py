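"""Transcriptome-wide application of a trained Ψ-site model.

Three layers of scoring:

* **lPPS** — the per-uridine model score: every thymine in a transcript
  is scored from its 101-nt window ('N'-padded at the transcript edges).
* **tPPS** — the transcript-level statistic
  ``(numΨ / numU) / (K / L)`` where numΨ counts thymines with
  lPPS > 0.5, numU those with lPPS ≤ 0.5, K is the thymine count and L
  the transcript length; it measures Ψ abundance relative to the
  transcript's uridine content.
* **AFCP** — the allele fold change of pseudouridylation potential for
  an SNV: log2 of the lPPS ratio between the major- and minor-allele
  sequence contexts at the nearest affected uridine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import TrainedModel
from .seqdata import (
    WINDOW_FLANK,
    extract_window,
    get_sequence,
    normalize_sequence,
    one_hot_encode,
)

logger = logging.getLogger(__name__)

AFCP_EPSILON = 1e-6


@dataclass
class SiteScore:
    sequence_id: str
    position: int   # 0-based offset of the thymine
    lpps: float


@dataclass
class TranscriptScore:
    sequence_id: str
    tpps: float | None   # None when undefined (K == 0 or num_u == 0)
    K: int
    num_psi: int
    num_u: int
    L: int

    @property
    def defined(self) -> bool:
        return self.tpps is not None


@dataclass
class VariantRecord:
    variant_id: str
    sequence_id: str
    position: int   # 0-based
    major_allele: str
    minor_allele: str
    maf: float | None = None

    def __post_init__(self) -> None:
        self.major_allele = self.major_allele.upper()
        self.minor_allele = self.minor_allele.upper()
        for allele in (self.major_allele, self.minor_allele):
            if allele not in "ACGT" or len(allele) != 1:
                raise ValueError(f"invalid allele {allele!r} for {self.variant_id}")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"identical alleles for {self.variant_id}")


@dataclass
class AFCPRecord:
    variant_id: str
    target_position: int
    lpps_major: float
    lpps_minor: float
    afcp: float


class ReferenceMismatchError(ValueError):
    pass


def scan_transcript(
    model: TrainedModel,
    sequence_id: str,
    sequence: str,
    batch_size: int = 256,
) -> list[SiteScore]:
    """One lPPS per thymine of the transcript, 5'→3' as given.

    Windows extending past the transcript ends are 'N'-padded to 101 nt.
    """
    seq = normalize_sequence(sequence)
    t_positions = [i for i, ch in enumerate(seq) if ch == "T"]
    if not t_positions:
        return []
    windows = np.stack([
        one_hot_encode(extract_window(seq, p)) for p in t_positions
    ])
    scores = model.predict(windows, batch_size=batch_size)
    return [
        SiteScore(sequence_id, p, float(s)) for p, s in zip(t_positions, scores)
    ]


def call_sites(
    scores: Sequence[SiteScore], threshold: float = 0.5
) -> tuple[list[SiteScore], list[SiteScore]]:
    """Partition into (Ψ, non-Ψ) by the strict ``lpps > threshold`` rule."""
    psi = [s for s in scores if s.lpps > threshold]
    non_psi = [s for s in scores if s.lpps <= threshold]
    return psi, non_psi


def tpps(
    scores: Sequence[SiteScore],
    L: int,
    sequence_id: str = "",
    threshold: float = 0.5,
) -> TranscriptScore:
    """Transcript pseudouridylation potential score.

    tPPS = (numΨ / numU) / (K / L); undefined (``tpps=None``) when the
    transcript has no thymines or every thymine is called Ψ.
    """
    if L < 1:
        raise ValueError("transcript length must be >= 1")
    for s in scores:
        if s.position >= L:
            raise ValueError(
                f"site position {s.position} >= transcript length {L}"
            )
    if not sequence_id and scores:
        sequence_id = scores[0].sequence_id
    K = len(scores)
    psi, non_psi = call_sites(scores, threshold)
    num_psi, num_u = len(psi), len(non_psi)
    if K == 0 or num_u == 0:
        value = None
    else:
        value = (num_psi / num_u) / (K / L)
    return TranscriptScore(sequence_id=sequence_id, tpps=value, K=K,
                           num_psi=num_psi, num_u=num_u, L=L)


# ---------------------------------------------------------------------------
# variant effects


def _nearest_shared_thymine(major_ctx: str, minor_ctx: str, center: int,
                            max_dist: int = WINDOW_FLANK) -> int | None:
    """Offset (within the context strings) of the thymine nearest to
    ``center`` that is 'T' in both allele contexts; ties go downstream."""
    best = None
    for d in range(0, max_dist + 1):
        for pos in (center + d, center - d):  # downstream first on ties
            if 0 <= pos < len(major_ctx) and major_ctx[pos] == "T" and minor_ctx[pos] == "T":
                best = pos
                break
        if best is not None:
            break
    return best


def afcp(
    model: TrainedModel,
    variant: VariantRecord,
    reference,
    epsilon: float = AFCP_EPSILON,
) -> AFCPRecord | None:
    """Allele fold change of pseudouridylation potential for one SNV.

    Substitutes each allele at the variant position, scores the 101-nt
    window centered on the nearest thymine shared by both allele
    sequences (within ±50 nt of the variant), and returns
    ``log2((lpps_major + ε) / (lpps_minor + ε))``.  Returns None when no
    eligible thymine exists.  Raises :class:`ReferenceMismatchError`
    when the reference base does not equal the major allele.
    """
    seq = get_sequence(reference, variant.sequence_id)
    v = variant.position
    if not 0 <= v < len(seq):
        raise ValueError(
            f"variant {variant.variant_id} position {v} outside "
            f"{variant.sequence_id!r}"
        )
    if seq[v] != variant.major_allele:
        raise ReferenceMismatchError(
            f"variant {variant.variant_id}: reference base {seq[v]!r} at "
            f"{variant.sequence_id}:{v} != major allele {variant.major_allele!r}"
        )
    # context wide enough for any 101-nt window around a T within +/-50 nt
    span = 3 * WINDOW_FLANK
    ctx = extract_window(seq, v, flank=span)  # length 301, variant at index 150
    center = span
    major_ctx = ctx[:center] + variant.major_allele + ctx[center + 1:]
    minor_ctx = ctx[:center] + variant.minor_allele + ctx[center + 1:]
    t_off = _nearest_shared_thymine(major_ctx, minor_ctx, center)
    if t_off is None:
        logger.info("variant %s skipped: no shared thymine within +/-%d nt",
                    variant.variant_id, WINDOW_FLANK)
        return None
    windows = np.stack([
        one_hot_encode(extract_window(major_ctx, t_off)),
        one_hot_encode(extract_window(minor_ctx, t_off)),
    ])
    lpps_major, lpps_minor = model.predict(windows)
    # log2(M+eps) - log2(m+eps): algebraically the log fold change, and
    # bit-exactly antisymmetric under an allele swap
    value = float(np.log2(lpps_major + epsilon) - np.log2(lpps_minor + epsilon))
    return AFCPRecord(
        variant_id=variant.variant_id,
        target_position=v + (t_off - center),
        lpps_major=float(lpps_major),
        lpps_minor=float(lpps_minor),
        afcp=value,
    )


def afcp_batch(
    model: TrainedModel,
    variants: Sequence[VariantRecord],
    reference,
    epsilon: float = AFCP_EPSILON,
) -> tuple[list[AFCPRecord], list[tuple[str, str]]]:
    """AFCP for many variants; returns (records, skipped (id, reason))."""
    records, skipped = [], []
    for variant in variants:
        rec = afcp(model, variant, reference, epsilon)
        if rec is None:
            skipped.append((variant.variant_id, "no eligible thymine within 50 nt"))
        else:
            records.append(rec)
    return records, skipped


# ---------------------------------------------------------------------------
# variant I/O


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """TSV with columns variant_id, sequence_id, position (0-based),
    major_allele, minor_allele[, maf]."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
    records = []
    for row in df.itertuples(index=False):
        maf = float(row.maf) if hasattr(row, "maf") and pd.notna(row.maf) else None
        records.append(
            VariantRecord(str(row.variant_id), str(row.sequence_id),
                          int(row.position), str(row.major_allele),
                          str(row.minor_allele), maf)
        )
    return records


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """VCF 4.x; REF is taken as the major allele, the first ALT as minor."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == "N" or alt == "N":
                continue  # SNVs only
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            records.append(
                VariantRecord(vid, rec.chrom, rec.pos - 1, ref, alt)
            )
    return records


# ---------------------------------------------------------------------------
# tabular output


def write_site_scores_tsv(scores: Sequence[SiteScore], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sequence_id": [s.sequence_id for s in scores],
            "position": [s.position for s in scores],
            "lpps": [s.lpps for s in scores],
        }
    ).to_csv(path, sep="\t", index=False)


def read_site_scores_tsv(path: str | Path) -> list[SiteScore]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
    return [SiteScore(str(r.sequence_id), int(r.position), float(r.lpps))
            for r in df.itertuples(index=False)]


def write_transcript_scores_tsv(scores: Sequence[TranscriptScore], path) -> None:
    pd.DataFrame(
        {
            "sequence_id": [s.sequence_id for s in scores],
            "K": [s.K for s in scores],
            "num_psi": [s.num_psi for s in scores],
            "num_u": [s.num_u for s in scores],
            "L": [s.L for s in scores],
            "tpps": [s.tpps if s.defined else float("nan") for s in scores],
            "defined": [s.defined for s in scores],
        }
    ).to_csv(path, sep="\t", index=False)


def write_afcp_tsv(records: Sequence[AFCPRecord],
                   skipped: Sequence[tuple[str, str]], path) -> None:
    rows = [
        {
            "variant_id": r.variant_id,
            "target_position": r.target_position,
            "lpps_major": r.lpps_major,
            "lpps_minor": r.lpps_minor,
            "afcp": r.afcp,
            "skip_reason": "",
        }
        for r in records
    ] + [
        {
            "variant_id": vid,
            "target_position": -1,
            "lpps_major": float("nan"),
            "lpps_minor": float("nan"),
            "afcp": float("nan"),
            "skip_reason": reason,
        }
        for vid, reason in skipped
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
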