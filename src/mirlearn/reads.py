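"""Adapter trimming, length/quality filtering and size-class histograms.

This module reimplements the preprocessing semantics of a typical small-RNA
sequencing run: strip the 3' ligation adapter (allowing a partial adapter at
the read end and a bounded mismatch fraction), discard reads in which no
adapter is found, drop inserts shorter than 15 nt or with any base at or
below Q20, and summarise retained insert lengths into the biologically
meaningful size classes — 20–23 nt (mature miRNAs), 26–28 nt
(Piwi-interacting RNAs) and the minor 41-nt class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from ._seq import check_alphabet, to_dna

#: Inclusive length bounds of the read size classes.
SIZE_CLASSES = {
    "mature_miRNA": (20, 23),
    "piRNA": (26, 28),
    "minor41": (41, 41),
}

DEFAULT_MIN_OVERLAP = 3  # shortest adapter prefix accepted at the read end


@dataclass(frozen=True)
class SmallRNARead:
    """A quality-scored small-RNA read (DNA alphabet)."""

    read_id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SizeHistogram:
    """Counts of retained reads by exact length and by size class."""

    counts_by_length: dict[int, int] = field(default_factory=dict)
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts_by_length.values())


def classify_length(length: int) -> str:
    for name, (lo, hi) in SIZE_CLASSES.items():
        if lo <= length <= hi:
            return name
    return "other"


def read_fastq(path) -> Iterator[SmallRNARead]:
    """Parse a Phred+33 FASTQ file into SmallRNARead records.

    Malformed records raise ValueError naming the offending record.
    """
    with open(path) as fh:
        lines = (line.rstrip("\n") for line in fh)
        for header in lines:
            if not header:
                continue
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record at {header!r}: missing '@'")
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            try:
                seq = next(lines)
                plus = next(lines)
                qual = next(lines)
            except StopIteration:
                raise ValueError(
                    f"malformed FASTQ record {read_id!r}: truncated record"
                ) from None
            if not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record {read_id!r}: missing '+'")
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {read_id!r}: sequence/quality length mismatch"
                )
            seq = check_alphabet(to_dna(seq), name=f"read {read_id!r}")
            yield SmallRNARead(read_id, seq, tuple(ord(c) - 33 for c in qual))


def write_fastq(reads: Iterable[SmallRNARead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quality)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def trim_adapter(
    read: SmallRNARead,
    adapter3p: str,
    max_error_rate: float = 0.1,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> SmallRNARead | None:
    """Strip the 3' adapter; return the insert, or None if no adapter found.

    The adapter may begin at any position of the read, including partially
    running off the read end. A candidate occurrence at position ``k`` is
    accepted when the Hamming mismatch fraction over the overlapping bases is
    at most ``max_error_rate``; the leftmost accepted occurrence wins, giving
    the longest-adapter (shortest-insert) interpretation the same priority a
    semi-global trimmer uses. Rejection (no adapter anywhere) is a value
    (None), not an exception.
    """
    if not adapter3p:
        raise ValueError("adapter3p must be non-empty")
    if not (0 <= max_error_rate < 0.5):
        raise ValueError("max_error_rate must be in [0, 0.5)")
    adapter = to_dna(adapter3p)
    seq = read.sequence
    n, alen = len(seq), len(adapter)
    for k in range(0, n):
        overlap = min(alen, n - k)
        if overlap < min(min_overlap, alen):
            break
        mism = sum(1 for a, b in zip(seq[k : k + overlap], adapter) if a != b)
        if mism <= max_error_rate * overlap:
            if k == 0:
                # adapter dimer: no insert to keep
                return None
            return SmallRNARead(read.read_id, seq[:k], read.quality[:k])
    return None


@dataclass
class FilterTally:
    """Per-reason rejection counts from read filtering."""

    retained: int = 0
    too_short: int = 0
    low_quality: int = 0
    no_adapter: int = 0
    blacklisted: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "retained": self.retained,
            "too_short": self.too_short,
            "low_quality": self.low_quality,
            "no_adapter": self.no_adapter,
            "blacklisted": self.blacklisted,
        }


def filter_reads(
    reads: Iterable[SmallRNARead],
    min_len: int = 15,
    min_q: int = 20,
    blacklist: Sequence[str] = (),
) -> tuple[list[SmallRNARead], FilterTally]:
    """Keep reads with length >= min_len and every base quality > min_q.

    The quality cut is strict (a base at exactly ``min_q`` rejects the read).
    ``blacklist`` holds contaminant sequences (rRNA/tRNA/snRNA fragments)
    removed by exact sequence match.
    """
    if min_len < 0 or min_q < 0:
        raise ValueError("thresholds must be non-negative")
    black = {to_dna(s) for s in blacklist}
    kept: list[SmallRNARead] = []
    tally = FilterTally()
    for r in reads:
        if len(r) < min_len:
            tally.too_short += 1
        elif min(r.quality) <= min_q:
            tally.low_quality += 1
        elif r.sequence in black:
            tally.blacklisted += 1
        else:
            kept.append(r)
            tally.retained += 1
    return kept, tally


def _trim_positions_batch(
    seqs: list[str], adapter: str, max_error_rate: float, min_overlap: int
) -> list[int]:
    """Leftmost accepted adapter start per read (-1 = none), vectorized.

    Semantics identical to trim_adapter, computed per read-length group with
    numpy over all candidate start positions.
    """
    import numpy as np

    ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
    alen = len(ad)
    result = [-1] * len(seqs)
    by_len: dict[int, list[int]] = {}
    for idx, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(idx)
    for L, idxs in by_len.items():
        mat = np.frombuffer("".join(seqs[i] for i in idxs).encode(), dtype=np.uint8)
        mat = mat.reshape(len(idxs), L)
        found = np.full(len(idxs), -1)
        for k in range(L):
            overlap = min(alen, L - k)
            if overlap < min(min_overlap, alen):
                break
            mism = (mat[:, k : k + overlap] != ad[:overlap]).sum(axis=1)
            ok = (found == -1) & (mism <= max_error_rate * overlap)
            found[ok] = k
        for local, idx in enumerate(idxs):
            result[idx] = int(found[local])
    return result


def process_library(
    reads: Iterable[SmallRNARead],
    adapter3p: str,
    max_error_rate: float = 0.1,
    min_len: int = 15,
    min_q: int = 20,
    blacklist: Sequence[str] = (),
) -> tuple[list[SmallRNARead], FilterTally]:
    """Trim then filter a whole library, pooling the rejection tally.

    Trimming uses a vectorized batch path with the same semantics as
    trim_adapter applied read by read.
    """
    if not adapter3p:
        raise ValueError("adapter3p must be non-empty")
    if not (0 <= max_error_rate < 0.5):
        raise ValueError("max_error_rate must be in [0, 0.5)")
    read_list = list(reads)
    positions = _trim_positions_batch(
        [r.sequence for r in read_list], to_dna(adapter3p), max_error_rate, DEFAULT_MIN_OVERLAP
    )
    trimmed: list[SmallRNARead] = []
    no_adapter = 0
    for r, k in zip(read_list, positions):
        if k <= 0:  # no adapter, or adapter dimer with empty insert
            no_adapter += 1
        else:
            trimmed.append(SmallRNARead(r.read_id, r.sequence[:k], r.quality[:k]))
    kept, tally = filter_reads(trimmed, min_len=min_len, min_q=min_q, blacklist=blacklist)
    tally.no_adapter = no_adapter
    return kept, tally


def size_histogram(reads: Iterable[SmallRNARead]) -> SizeHistogram:
    """Histogram of read lengths with size-class totals (closed intervals)."""
    by_len = Counter(len(r) for r in reads)
    classes = Counter()
    for length, n in by_len.items():
        classes[classify_length(length)] += n
    for name in (*SIZE_CLASSES, "other"):
        classes.setdefault(name, 0)
    return SizeHistogram(dict(sorted(by_len.items())), dict(classes))
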