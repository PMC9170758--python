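"""Seeded synthetic data with planted Ψ-context motifs.

Generates everything the rest of the package consumes — labeled 101-nt
sample sets, transcript FASTA files with a truth BED of planted sites,
and variant tables — so the classifier, the motif extractor, the
transcriptome scanner, and the variant scorer can all be exercised
without any external download.

The planted contexts default to the DNA renderings of the two
best-characterized pseudouridine synthase recognition motifs: the PUS4
context GUΨCNA (DNA ``GT[T]CNA``, Ψ at index 2) and the PUS7 context
UGΨAG (DNA ``TG[T]AG``, Ψ at index 2).  Positives carry one embedded
motif instance whose Ψ position lands at the window center ± a small
jitter; negatives are background sequence with a forced central T and
are rejection-sampled to contain no occurrence of any configured
consensus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqdata import WINDOW_FLANK, WINDOW_LEN, GenomicSite, LabeledSample
from .scoring import VariantRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedMotif:
    """A consensus string (IUPAC N allowed) with the index of its Ψ."""

    consensus: str
    psi_index: int

    def __post_init__(self) -> None:
        consensus = self.consensus.upper().replace("U", "T")
        object.__setattr__(self, "consensus", consensus)
        if not 0 <= self.psi_index < len(consensus):
            raise ValueError("psi_index outside consensus")
        if consensus[self.psi_index] != "T":
            raise ValueError(
                f"psi_index of {consensus!r} must point at a T/U"
            )
        if len(consensus) > WINDOW_LEN:
            raise ValueError("motif longer than the 101-nt window")

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.consensus.replace("N", "[ACGT]"))


DEFAULT_MOTIFS = (PlantedMotif("GTTCNA", 2), PlantedMotif("TGTAG", 2))


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-motif benchmark.

    The defaults are the benchmark conditions used throughout this
    repository: 1000 positives vs 1000 negatives, every positive carries
    a motif (embed_prob 1.0), and the motif's Ψ lands within ±2 nt of
    the window center.
    """

    n_pos: int = 1000
    n_neg: int = 1000
    motifs: tuple[PlantedMotif, ...] = DEFAULT_MOTIFS
    embed_prob: float = 1.0
    jitter: int = 2
    gc_content: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.embed_prob <= 1.0:
            raise ValueError("embed_prob must be in [0, 1]")
        if not 0 <= self.jitter <= 40:
            raise ValueError("jitter must be in [0, 40]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        self.motifs = tuple(
            m if isinstance(m, PlantedMotif) else PlantedMotif(*m)
            for m in self.motifs
        )

    @property
    def base_probs(self) -> np.ndarray:
        at = (1.0 - self.gc_content) / 2.0
        gc = self.gc_content / 2.0
        return np.array([at, gc, gc, at])  # A, C, G, T


def _random_seq(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _instantiate(motif: PlantedMotif, rng: np.random.Generator) -> str:
    return "".join(
        rng.choice(_BASES) if ch == "N" else ch for ch in motif.consensus
    )


def _contains_any_motif(seq: str, motifs: Sequence[PlantedMotif]) -> bool:
    return any(m.regex.search(seq) for m in motifs)


def generate_dataset(config: SyntheticConfig) -> list[LabeledSample]:
    """Labeled 101-nt windows with planted motifs in the positives.

    Positives: background with one motif embedded (with probability
    ``embed_prob``) so its Ψ index lands at 50 ± jitter; the window
    center is forced to 'T' last, preserving the sample invariant.
    Negatives: background with a central 'T', rejection-sampled to be
    free of every configured consensus.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    probs = config.base_probs
    samples: list[LabeledSample] = []
    for i in range(config.n_pos):
        seq = list(_random_seq(rng, WINDOW_LEN, probs))
        if rng.random() < config.embed_prob:
            motif = config.motifs[rng.integers(len(config.motifs))]
            offset = int(rng.integers(-config.jitter, config.jitter + 1))
            start = WINDOW_FLANK + offset - motif.psi_index
            instance = _instantiate(motif, rng)
            for j, ch in enumerate(instance):
                if 0 <= start + j < WINDOW_LEN:
                    seq[start + j] = ch
        seq[WINDOW_FLANK] = "T"
        origin = GenomicSite(f"synthetic_pos_{i}", WINDOW_FLANK, "+", "synthetic")
        samples.append(LabeledSample("".join(seq), 1, origin=origin))
    for i in range(config.n_neg):
        while True:
            seq = list(_random_seq(rng, WINDOW_LEN, probs))
            seq[WINDOW_FLANK] = "T"
            candidate = "".join(seq)
            if not _contains_any_motif(candidate, config.motifs):
                break
        origin = GenomicSite(f"synthetic_neg_{i}", WINDOW_FLANK, "+", "synthetic")
        samples.append(LabeledSample(candidate, 0, origin=origin))
    return samples


def generate_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int],
    planted_site_rate: float,
    config: SyntheticConfig | None = None,
) -> tuple[dict[str, str], list[GenomicSite]]:
    """Random transcripts with known planted Ψ contexts.

    ``planted_site_rate`` is the expected number of planted sites per
    nucleotide; each transcript receives a Poisson number of
    non-overlapping motif instances.  Returns the sequences and the
    truth list of planted Ψ positions (each guaranteed to sit on a 'T').
    """
    if config is None:
        config = SyntheticConfig()
    if length_range[0] < 1 or length_range[1] < length_range[0]:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(config.seed)
    probs = config.base_probs
    records: dict[str, str] = {}
    truth: list[GenomicSite] = []
    for t in range(n_transcripts):
        tid = f"synthetic_tx_{t}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list(_random_seq(rng, length, probs))
        n_sites = int(rng.poisson(planted_site_rate * length))
        used: list[tuple[int, int]] = []
        for _ in range(n_sites):
            motif = config.motifs[rng.integers(len(config.motifs))]
            m = len(motif.consensus)
            if length < m:
                continue
            for _attempt in range(50):
                start = int(rng.integers(0, length - m + 1))
                if all(start + m <= s or start >= e for s, e in used):
                    break
            else:
                continue
            used.append((start, start + m))
            instance = _instantiate(motif, rng)
            seq[start:start + m] = list(instance)
            truth.append(GenomicSite(tid, start + motif.psi_index, "+", "planted"))
        records[tid] = "".join(seq)
    return records, truth


def generate_variants(
    transcriptome: tuple[dict[str, str], list[GenomicSite]],
    n_variants: int,
    motif_hit_fraction: float,
    seed: int = 0,
    motifs: Sequence[PlantedMotif] = DEFAULT_MOTIFS,
) -> tuple[list[VariantRecord], list[bool]]:
    """SNVs over a synthetic transcriptome, a stated fraction inside
    planted motif instances (expected to perturb the model score) and
    the rest in motif-free background at least 60 nt from any planted
    site.  Returns (variants, in_motif truth flags); every major allele
    equals the reference base.
    """
    records, truth = transcriptome
    rng = np.random.default_rng(seed)
    n_hit = int(round(n_variants * motif_hit_fraction))

    # motif footprints around each planted site
    footprints: list[tuple[str, int]] = []
    for site in truth:
        seq = records[site.sequence_id]
        for motif in motifs:
            start = site.position - motif.psi_index
            end = start + len(motif.consensus)
            if start < 0 or end > len(seq):
                continue
            if motif.regex.fullmatch(seq[start:end]):
                footprints.extend(
                    (site.sequence_id, p) for p in range(start, end)
                    if motif.consensus[p - start] != "N"
                )
                break
    truth_positions = {(s.sequence_id, s.position) for s in truth}

    variants: list[VariantRecord] = []
    flags: list[bool] = []
    if n_hit and not footprints:
        raise ValueError("no planted motif footprints available for hit variants")
    for i in range(n_hit):
        tid, pos = footprints[rng.integers(len(footprints))]
        ref = records[tid][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        variants.append(VariantRecord(f"synthetic_var_hit_{i}", tid, pos, ref, alt))
        flags.append(True)

    tids = list(records)
    made = 0
    while made < n_variants - n_hit:
        tid = tids[rng.integers(len(tids))]
        seq = records[tid]
        pos = int(rng.integers(len(seq)))
        near_site = any(
            (tid, p) in truth_positions
            for p in range(pos - 60, pos + 61)
        )
        if near_site:
            continue
        ref = seq[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        variants.append(
            VariantRecord(f"synthetic_var_bg_{made}", tid, pos, ref, alt)
        )
        flags.append(False)
        made += 1
    return variants, flags


# ---------------------------------------------------------------------------
# file export (plain-text formats consumable by the other modules)


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(sites: Sequence[GenomicSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.sequence_id}\t{s.position}\t{s.position + 1}\t"
                f"{s.source or '.'}\t0\t{s.strand}\n"
            )


def write_variants_tsv(variants: Sequence[VariantRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "sequence_id": [v.sequence_id for v in variants],
            "position": [v.position for v in variants],
            "major_allele": [v.major_allele for v in variants],
            "minor_allele": [v.minor_allele for v in variants],
            "maf": [v.maf for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)
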