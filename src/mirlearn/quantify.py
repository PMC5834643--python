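"""Read-to-hairpin assignment and count-table construction.

Processed inserts are assigned to miRNAs by ungapped substring matching
against hairpin precursor references (sense strand, DNA alphabet), keeping
the hit with the fewest mismatches and discarding reads whose best hit is
tied across distinct miRNA names. Assigned reads are tabulated into a
miRNA x library count matrix whose column totals are the library sizes used
by the Audic-Claverie test, and can be rescaled to counts per million.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import VALID_DNA, check_alphabet, to_dna
from .reads import SmallRNARead


@dataclass(frozen=True)
class HairpinRecord:
    """A hairpin precursor with the mature miRNA's location within it.

    ``mature_start``/``mature_end`` are 0-based half-open offsets into the
    hairpin sequence (DNA alphabet).
    """

    name: str
    hairpin_seq: str
    mature_start: int
    mature_end: int

    def __post_init__(self) -> None:
        seq = check_alphabet(to_dna(self.hairpin_seq), name=f"hairpin {self.name!r}")
        object.__setattr__(self, "hairpin_seq", seq)
        if not (0 <= self.mature_start < self.mature_end <= len(seq)):
            raise ValueError(f"hairpin {self.name!r}: mature coordinates out of bounds")
        mlen = self.mature_end - self.mature_start
        if not (20 <= mlen <= 23):
            raise ValueError(f"hairpin {self.name!r}: mature length {mlen} outside 20-23")

    @property
    def mature_seq(self) -> str:
        return self.hairpin_seq[self.mature_start : self.mature_end]


@dataclass
class AssignmentResult:
    """Per-read assignment plus ambiguity/unassigned tallies."""

    assignments: dict[str, str]  # read_id -> miRNA name
    ambiguous: int
    unassigned: int


@dataclass
class CountTable:
    """Per-miRNA read frequencies across libraries.

    ``counts`` is a (miRNA x library) integer matrix; ``library_totals`` are
    its column sums — the N1, N2 entering the Audic-Claverie test.
    """

    mirna_names: list[str]
    libraries: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.mirna_names), len(self.libraries)):
            raise ValueError("counts shape does not match names/libraries")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.mirna_names)) != len(self.mirna_names):
            raise ValueError("miRNA names must be unique")

    @property
    def library_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, library: str) -> np.ndarray:
        return self.counts[:, self.libraries.index(library)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.mirna_names, columns=self.libraries)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.loc["library_total"] = self.library_totals
        df.to_csv(path, sep="\t", index_label="mirna")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="mirna")
        if "library_total" in df.index:
            df = df.drop(index="library_total")
        return cls(list(df.index), list(df.columns), df.to_numpy())


def _load_hairpins(hairpins: Iterable[HairpinRecord]) -> list[HairpinRecord]:
    hp = list(hairpins)
    if not hp:
        raise ValueError("empty hairpin set")
    for h in hp:
        if set(h.hairpin_seq) - (VALID_DNA - {"N"}):
            raise ValueError(f"hairpin {h.name!r} contains degenerate bases")
    return hp


def _best_hit(seq: str, arrays: list[tuple[str, np.ndarray]], max_mm: int) -> tuple[str | None, int]:
    """Fewest-mismatch substring hit of ``seq`` over all hairpins.

    Returns (name or None, mismatch count); name is None when unassigned,
    and the sentinel "*" when the best hit ties across distinct names.
    """
    q = np.frombuffer(seq.encode(), dtype=np.uint8)
    m = len(q)
    best_name: str | None = None
    best_mm = max_mm + 1
    tied = False
    for name, ref in arrays:
        n = len(ref)
        if n < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref, m)
        mms = (windows != q).sum(axis=1)
        mm = int(mms.min())
        if mm < best_mm:
            best_name, best_mm, tied = name, mm, False
        elif mm == best_mm and best_name is not None and name != best_name:
            tied = True
    if best_mm > max_mm:
        return None, best_mm
    if tied:
        return "*", best_mm
    return best_name, best_mm


def map_reads(
    reads: Iterable[SmallRNARead],
    hairpins: Iterable[HairpinRecord],
    max_mismatches: int = 0,
) -> AssignmentResult:
    """Assign each read to the hairpin it matches with fewest mismatches.

    A read is assigned when it occurs as a substring of a hairpin (sense
    strand) with at most ``max_mismatches`` mismatches; best-hit ties across
    distinct miRNA names are discarded as ambiguous.
    """
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1 or 2")
    hp = _load_hairpins(hairpins)
    arrays = [
        (h.name, np.frombuffer(h.hairpin_seq.encode(), dtype=np.uint8)) for h in hp
    ]

    # exact-match fast path: one substring search over all hairpins at once
    concat = "#".join(h.hairpin_seq for h in hp)
    offsets = []
    pos = 0
    for h in hp:
        offsets.append((pos, pos + len(h.hairpin_seq), h.name))
        pos += len(h.hairpin_seq) + 1

    def exact_hits(seq: str) -> set[str]:
        names: set[str] = set()
        start = concat.find(seq)
        while start != -1:
            for lo, hi, name in offsets:
                if lo <= start and start + len(seq) <= hi:
                    names.add(name)
                    break
            start = concat.find(seq, start + 1)
        return names
    assignments: dict[str, str] = {}
    ambiguous = unassigned = 0
    cache: dict[str, str | None] = {}
    for r in reads:
        hit = cache.get(r.sequence, "?")
        if hit == "?":
            exact = exact_hits(r.sequence)
            if len(exact) == 1:
                hit = exact.pop()  # an exact hit cannot be beaten
            elif len(exact) > 1:
                hit = "*"
            elif max_mismatches == 0:
                hit = None
            else:
                hit, _ = _best_hit(r.sequence, arrays, max_mismatches)
            cache[r.sequence] = hit
        if hit is None:
            unassigned += 1
        elif hit == "*":
            ambiguous += 1
        else:
            assignments[r.read_id] = hit
    return AssignmentResult(assignments, ambiguous, unassigned)


def build_count_table(
    assignments: Mapping[str, AssignmentResult],
    mirna_names: Sequence[str],
    libraries: Sequence[str] | None = None,
) -> CountTable:
    """Tabulate per-library assignments into a CountTable.

    ``assignments`` maps library id -> AssignmentResult from map_reads.
    """
    libs = list(libraries) if libraries is not None else list(assignments)
    unknown = set(libs) - set(assignments)
    if unknown:
        raise ValueError(f"assignments missing for libraries {sorted(unknown)}")
    names = list(mirna_names)
    idx = {n: i for i, n in enumerate(names)}
    counts = np.zeros((len(names), len(libs)), dtype=np.int64)
    for j, lib in enumerate(libs):
        for mirna in assignments[lib].assignments.values():
            counts[idx[mirna], j] += 1
    return CountTable(names, libs, counts)


def normalize_cpm(table: CountTable) -> pd.DataFrame:
    """Counts per million miRNA-assigned reads; column sums are 1e6."""
    totals = table.library_totals
    zero = [lib for lib, t in zip(table.libraries, totals) if t == 0]
    if zero:
        raise ValueError(f"zero-total libraries: {zero}")
    cpm = table.counts / totals[None, :] * 1e6
    return pd.DataFrame(cpm, index=table.mirna_names, columns=table.libraries)


def write_hairpin_references(hairpins: Sequence[HairpinRecord], fasta_path, tsv_path) -> None:
    """Write hairpins as FASTA plus a sidecar TSV of mature coordinates."""
    with open(fasta_path, "w") as fh:
        for h in hairpins:
            fh.write(f">{h.name}\n{h.hairpin_seq}\n")
    pd.DataFrame(
        [(h.name, h.mature_start, h.mature_end) for h in hairpins],
        columns=["name", "mature_start", "mature_end"],
    ).to_csv(tsv_path, sep="\t", index=False)


def read_hairpin_references(fasta_path, tsv_path) -> list[HairpinRecord]:
    from Bio import SeqIO

    coords = pd.read_csv(tsv_path, sep="\t").set_index("name")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = coords.loc[rec.id]
        records.append(
            HairpinRecord(rec.id, str(rec.seq), int(row.mature_start), int(row.mature_end))
        )
    return records
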