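"""Site loading, sample construction, and sequence encoding.

Training examples are 101-nt windows centered on a candidate uridine
(written 'T' in the DNA alphabet): a pseudouridine (Ψ) site with 50 nt of
flanking sequence on each side is a positive sample, and the nearest
thymine whose window does not overlap any positive window supplies the
matched negative.  Imbalanced sets take the nearest *n* such thymines per
positive.  Coordinates are 0-based half-open throughout; minus-strand
windows are reverse-complemented so every sample reads 5'→3' with the
candidate base at index 50.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_FLANK = 50
WINDOW_LEN = 2 * WINDOW_FLANK + 1

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = np.array(list("ACGT"))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA 'U' to DNA 'T'."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GenomicSite:
    """A candidate Ψ position on a reference or transcript sequence."""

    sequence_id: str
    position: int  # 0-based
    strand: str = "+"
    source: str = ""


@dataclass
class LabeledSample:
    """A 101-nt window centered on a thymine with a binary Ψ label."""

    sequence: str
    label: int
    origin: GenomicSite | None = None
    window_start: int = 0  # 0-based start on the source sequence (may be <0 when padded)

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LEN:
            raise ValueError(
                f"sample length {len(self.sequence)} != {WINDOW_LEN}"
            )
        if self.sequence[WINDOW_FLANK] != "T":
            raise ValueError(
                f"sample center base is {self.sequence[WINDOW_FLANK]!r}, expected 'T'"
            )


@dataclass
class FoldAssignment:
    fold_index: np.ndarray  # int array, one entry per sample
    k: int
    seed: int


# ---------------------------------------------------------------------------
# reference access


def get_sequence(reference, sequence_id: str) -> str:
    """Fetch a full sequence from a dict-like or pyfaidx.Fasta reference."""
    try:
        record = reference[sequence_id]
    except KeyError as exc:
        raise KeyError(f"sequence id {sequence_id!r} not found in reference") from exc
    if isinstance(record, str):
        return normalize_sequence(record)
    # pyfaidx.FastaRecord
    return normalize_sequence(str(record[:]))


# ---------------------------------------------------------------------------
# site tables


def read_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a BED (3+ columns, strand in column 6 if present) into site tuples.

    The site position is the interval start (0-based); single-base BED
    records are the expected input.
    """
    rows: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED record: {line!r}")
            try:
                start = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer start: {parts[1]!r}") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
            rows.append((parts[0], start, strand))
    return rows


def read_site_table(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a TSV of (sequence_id, position, strand); positions 0-based."""
    rows: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed site record: {line!r}")
            try:
                pos = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer position: {parts[1]!r}") from exc
            strand = parts[2] if len(parts) >= 3 and parts[2] in "+-" else "+"
            rows.append((parts[0], pos, strand))
    return rows


def load_sites(
    records: Iterable[tuple[str, int, str] | GenomicSite],
    reference,
    source: str = "",
) -> tuple[list[GenomicSite], int]:
    """Validate candidate sites against the reference.

    A site is kept only if its strand-resolved base is a thymine: 'T' on
    the plus strand, 'A' (the complement) on the minus strand.  Returns
    the retained sites and the number of discarded records.
    """
    sites: list[GenomicSite] = []
    discarded = 0
    cache: dict[str, str] = {}
    for rec in records:
        if isinstance(rec, GenomicSite):
            seq_id, pos, strand = rec.sequence_id, rec.position, rec.strand
            src = rec.source or source
        else:
            seq_id, pos, strand = rec
            src = source
        if strand not in ("+", "-"):
            raise ValueError(f"invalid strand {strand!r} for site {seq_id}:{pos}")
        if seq_id not in cache:
            cache[seq_id] = get_sequence(reference, seq_id)
        seq = cache[seq_id]
        if not 0 <= pos < len(seq):
            raise ValueError(
                f"position {pos} outside sequence {seq_id!r} (length {len(seq)})"
            )
        base = seq[pos]
        resolved = base if strand == "+" else base.translate(_COMPLEMENT)
        if resolved == "T":
            sites.append(GenomicSite(seq_id, pos, strand, src))
        else:
            discarded += 1
    if discarded:
        logger.info("load_sites: discarded %d non-thymine sites", discarded)
    return sites, discarded


# ---------------------------------------------------------------------------
# sample construction


def extract_window(seq: str, center: int, flank: int = WINDOW_FLANK, strand: str = "+") -> str:
    """101-nt window around ``center``; out-of-sequence positions become 'N'.

    Minus-strand windows are reverse-complemented so the output reads
    5'→3' on the transcript with the center base at index ``flank``.
    """
    start, stop = center - flank, center + flank + 1
    left_pad = max(0, -start)
    right_pad = max(0, stop - len(seq))
    window = "N" * left_pad + seq[max(0, start):min(len(seq), stop)] + "N" * right_pad
    if strand == "-":
        window = reverse_complement(window)
    return window


def build_positive_samples(
    sites: Sequence[GenomicSite],
    reference,
    flank: int = WINDOW_FLANK,
) -> list[LabeledSample]:
    """One label-1 window per validated Ψ site."""
    cache: dict[str, str] = {}
    samples = []
    for site in sites:
        if site.sequence_id not in cache:
            cache[site.sequence_id] = get_sequence(reference, site.sequence_id)
        window = extract_window(cache[site.sequence_id], site.position, flank, site.strand)
        samples.append(
            LabeledSample(window, 1, origin=site, window_start=site.position - flank)
        )
    return samples


def _merged_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, stop in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
        else:
            merged.append((start, stop))
    return merged


def _overlaps(merged: list[tuple[int, int]], start: int, stop: int) -> bool:
    import bisect

    i = bisect.bisect_right([m[0] for m in merged], start)
    if i > 0 and merged[i - 1][1] > start:
        return True
    return i < len(merged) and merged[i][0] < stop


def build_negative_samples(
    positives: Sequence[LabeledSample],
    reference,
    ratio_n: int = 1,
    flank: int = WINDOW_FLANK,
) -> list[LabeledSample]:
    """Nearest-thymine negatives that never overlap a positive window.

    For each positive the ``ratio_n`` nearest thymines on the same
    sequence and strand are taken (absolute genomic distance; equidistant
    candidates resolve downstream), subject to their 101-nt windows being
    disjoint from every positive window on that sequence.  Duplicate
    centers arising from different positives are emitted once.
    """
    cache: dict[str, str] = {}
    # positive windows per sequence, clipped to the sequence
    pos_windows: dict[str, list[tuple[int, int]]] = {}
    for p in positives:
        if p.origin is None:
            raise ValueError("positives must carry their origin site")
        sid = p.origin.sequence_id
        if sid not in cache:
            cache[sid] = get_sequence(reference, sid)
        L = len(cache[sid])
        c = p.origin.position
        pos_windows.setdefault(sid, []).append(
            (max(0, c - flank), min(L, c + flank + 1))
        )
    merged = {sid: _merged_intervals(iv) for sid, iv in pos_windows.items()}

    # strand-resolved thymine positions per (sequence, strand)
    t_positions: dict[tuple[str, str], np.ndarray] = {}

    def thymines(sid: str, strand: str) -> np.ndarray:
        key = (sid, strand)
        if key not in t_positions:
            arr = np.frombuffer(cache[sid].encode(), dtype=np.uint8)
            target = ord("T") if strand == "+" else ord("A")
            t_positions[key] = np.flatnonzero(arr == target)
        return t_positions[key]

    chosen: dict[tuple[str, int, str], LabeledSample] = {}
    for p in positives:
        site = p.origin
        sid, strand = site.sequence_id, site.strand
        seq = cache[sid]
        ts = thymines(sid, strand)
        merged_iv = merged[sid]
        # walk outward from the positive position, nearer first, ties downstream
        right = int(np.searchsorted(ts, site.position))
        left = right - 1
        picked = 0
        while picked < ratio_n and (left >= 0 or right < len(ts)):
            dl = site.position - ts[left] if left >= 0 else None
            dr = ts[right] - site.position if right < len(ts) else None
            if dr is not None and (dl is None or dr <= dl):
                cand = int(ts[right]); right += 1
            else:
                cand = int(ts[left]); left -= 1
            w0, w1 = max(0, cand - flank), min(len(seq), cand + flank + 1)
            if _overlaps(merged_iv, w0, w1):
                continue
            key = (sid, cand, strand)
            if key not in chosen:
                window = extract_window(seq, cand, flank, strand)
                origin = GenomicSite(sid, cand, strand, source="negative")
                chosen[key] = LabeledSample(window, 0, origin=origin,
                                            window_start=cand - flank)
            picked += 1
        if picked < ratio_n:
            warnings.warn(
                f"only {picked}/{ratio_n} eligible negative thymines for positive "
                f"{sid}:{site.position}({strand})",
                stacklevel=2,
            )
    return list(chosen.values())


# ---------------------------------------------------------------------------
# encoding


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a sequence as a (len, 4) binary matrix, channels A,C,G,T.

    Case-insensitive; 'U' maps to 'T'; 'N' becomes an all-zero row.
    """
    seq = normalize_sequence(sequence)
    mat = np.zeros((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq):
        if ch == "N":
            continue
        j = _BASE_INDEX.get(ch)
        if j is None:
            raise ValueError(f"illegal character {ch!r} at position {i}")
        mat[i, j] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to 'N'."""
    matrix = np.asarray(matrix)
    chars = np.where(matrix.sum(axis=1) == 0, "N", _INDEX_BASE[matrix.argmax(axis=1)])
    return "".join(chars)


def encode_samples(samples: Sequence[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (n, 101, 4) inputs and an int label vector."""
    X = np.stack([one_hot_encode(s.sequence) for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    return X, y


# ---------------------------------------------------------------------------
# folds


def make_folds(samples: Sequence, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Random partition into k folds whose sizes differ by at most one."""
    n = len(samples)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_index = np.empty(n, dtype=np.int64)
    # first (n % k) folds get one extra sample
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for f, size in enumerate(sizes):
        fold_index[perm[start:start + size]] = f
        start += size
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


# ---------------------------------------------------------------------------
# sample table I/O


def write_samples_tsv(samples: Sequence[LabeledSample], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sequence_id": [s.origin.sequence_id if s.origin else "" for s in samples],
            "window_start": [s.window_start for s in samples],
            "strand": [s.origin.strand if s.origin else "+" for s in samples],
            "label": [s.label for s in samples],
            "sequence": [s.sequence for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_samples_tsv(path: str | Path) -> list[LabeledSample]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
    samples = []
    for row in df.itertuples(index=False):
        center = int(row.window_start) + WINDOW_FLANK
        origin = GenomicSite(str(row.sequence_id), center, str(row.strand))
        samples.append(
            LabeledSample(str(row.sequence), int(row.label), origin=origin,
                          window_start=int(row.window_start))
        )
    return samples
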