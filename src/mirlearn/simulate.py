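"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything the analysis consumes can be generated here, fully determined by
an integer seed: hairpin references with known mature coordinates,
adapter-ligated FASTQ libraries for a naive / 1 h / 6 h three-library
design with Poisson counts and planted fold changes, target UTRs carrying a
perfect seed-complementary site with G-U wobbles in the 3' supplementary
pairing region, and comparative-CT qPCR tables with planted expression
ratios.

Counts are Poisson (the sampling model the Audic-Claverie test assumes),
with an optional negative-binomial overdispersion switch; per-miRNA
relative abundances are log-uniform over three orders of magnitude, a
simple stand-in for a realistic rank-abundance curve. Sequencing errors,
ligation bias and real miRBase content are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp_dna, to_dna, to_rna
from .quantify import HairpinRecord
from .reads import SmallRNARead
from .targets import SeedSpec, scan_utr

#: Mature sequence of the CREB2-targeting miRNA, Lym-miR-137 (RNA alphabet).
MIR137_MATURE = "UUAUUGCUUGAGAAUACACGUA"
MIR137_NAME = "Lym-miR-137"

#: 3' ligation adapter used by common small-RNA library preparations.
DEFAULT_ADAPTER3P = "AGATCGGAAGAGCACACGTCT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# internal RNG stream labels, combined with the config seed
_STREAM_HAIRPINS = 1
_STREAM_ABUNDANCE = 2
_STREAM_LIBRARY = 3
_STREAM_UTR = 4
_STREAM_QPCR = 5


@dataclass
class SimulationConfig:
    """Study-level parameters of a simulated small-RNA experiment.

    The defaults emulate the three-library single-trial conditioning design:
    libraries from naive animals and from animals 1 h and 6 h post-training,
    ~74% of reads drawn from known miRNA matures, the 20-23 / 26-28 / 41 nt
    size-class structure, a 1.5-fold up-regulation planted for a subset of
    miRNAs (mostly at 1 h, a smaller pool at 6 h), and per-base qualities
    almost all above Q20.
    """

    rng_seed: int
    n_mirnas: int = 100
    library_depths: dict[str, int] = field(
        default_factory=lambda: {"naive": 100_000, "1h": 100_000, "6h": 100_000}
    )
    size_class_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "mature_miRNA": 0.78,
            "piRNA": 0.15,
            "minor41": 0.02,
            "other": 0.05,
        }
    )
    mapped_fraction: float = 0.74
    planted_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    adapter3p: str = DEFAULT_ADAPTER3P
    read_length: int = 50
    # all above Q20 by default, so the quality filter is lossless
    base_quality: dict[int, float] = field(
        default_factory=lambda: {40: 0.60, 37: 0.25, 33: 0.10, 28: 0.05}
    )
    overdispersion: float | None = None  # NB shape; None = pure Poisson

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if abs(sum(self.size_class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("size_class_mixture proportions must sum to 1")
        if any(d < 0 for d in self.library_depths.values()):
            raise ValueError("library depths must be non-negative")
        if not (0 < self.mapped_fraction <= self.size_class_mixture["mature_miRNA"]):
            raise ValueError(
                "mapped_fraction must be positive and no larger than the "
                "20-23 nt class proportion"
            )
        for mir, (lib, fold) in self.planted_effects.items():
            if lib not in self.library_depths:
                raise ValueError(f"planted effect for {mir!r} names unknown library {lib!r}")
            if fold <= 0:
                raise ValueError(f"planted fold change for {mir!r} must be > 0")
        if abs(sum(self.base_quality.values()) - 1.0) > 1e-9:
            raise ValueError("base_quality probabilities must sum to 1")
        if not self.adapter3p:
            raise ValueError("adapter3p must be non-empty")


def default_config(rng_seed: int) -> SimulationConfig:
    """The default three-library study with 14 planted 1.5-fold effects."""
    planted = {MIR137_NAME: ("1h", 1.5)}
    planted.update({f"Lym-sim-miR-{i:03d}": ("1h", 1.5) for i in range(1, 10)})
    planted.update({f"Lym-sim-miR-{i:03d}": ("6h", 1.5) for i in range(10, 14)})
    return SimulationConfig(rng_seed=rng_seed, planted_effects=planted)


def _rng(cfg_seed: int, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg_seed % 2**31, stream, extra])


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def generate_hairpin_set(cfg: SimulationConfig) -> list[HairpinRecord]:
    """n_mirnas hairpins with unique names and pairwise-distinct matures.

    The first record is always Lym-miR-137 with its known mature sequence;
    the rest carry random 20-23 nt matures embedded in random hairpin arms.
    Matures are re-drawn if they collide or occur inside another hairpin.
    """
    rng = _rng(cfg.rng_seed, _STREAM_HAIRPINS)
    records: list[HairpinRecord] = []
    matures: set[str] = set()

    def add(name: str, mature_dna: str) -> None:
        left = _random_seq(rng, 20)
        right = _random_seq(rng, 25)
        records.append(
            HairpinRecord(name, left + mature_dna + right, 20, 20 + len(mature_dna))
        )
        matures.add(mature_dna)

    add(MIR137_NAME, to_dna(MIR137_MATURE))
    for i in range(1, cfg.n_mirnas):
        while True:
            mature = _random_seq(rng, int(rng.integers(20, 24)))
            if mature not in matures:
                break
        add(f"Lym-sim-miR-{i:03d}", mature)
    # reject matures that occur inside a different hairpin (ambiguity guard)
    for rec in records:
        for other in records:
            if other.name != rec.name and rec.mature_seq in other.hairpin_seq:
                raise RuntimeError("mature collision across hairpins; change rng_seed")
    return records


def relative_abundances(cfg: SimulationConfig, hairpins: Sequence[HairpinRecord]) -> dict[str, float]:
    """Log-uniform relative abundances over 3 orders of magnitude, summing to 1.

    Shared across libraries so that the only between-library differences are
    the planted effects and Poisson noise.
    """
    rng = _rng(cfg.rng_seed, _STREAM_ABUNDANCE)
    raw = 10.0 ** rng.uniform(-3, 0, size=len(hairpins))
    raw /= raw.sum()
    return {h.name: float(a) for h, a in zip(hairpins, raw)}


def expected_count(
    cfg: SimulationConfig,
    abundances: Mapping[str, float],
    mirna: str,
    library_id: str,
) -> float:
    """Poisson mean of one miRNA's read count in one library."""
    depth = cfg.library_depths[library_id]
    fold = 1.0
    if mirna in cfg.planted_effects:
        lib, f = cfg.planted_effects[mirna]
        if lib == library_id:
            fold = f
    return depth * cfg.mapped_fraction * abundances[mirna] * fold


@dataclass
class LibrarySim:
    """One simulated library: raw adapter-ligated reads plus ground truth."""

    library_id: str
    reads: list[SmallRNARead]
    true_counts: dict[str, int]  # per-miRNA reads actually emitted
    class_counts: dict[str, int]  # insert size classes actually emitted


def _quality_string(rng: np.random.Generator, length: int, dist: Mapping[int, float]) -> tuple[int, ...]:
    qs = np.array(sorted(dist))
    ps = np.array([dist[q] for q in qs])
    return tuple(int(q) for q in rng.choice(qs, size=length, p=ps))


def generate_library(
    cfg: SimulationConfig,
    hairpins: Sequence[HairpinRecord],
    library_id: str,
) -> LibrarySim:
    """Simulate one adapter-ligated FASTQ library.

    Per-miRNA counts are Poisson with mean depth x mapped_fraction x
    abundance x planted fold (negative-binomial when overdispersion is on);
    the non-miRNA size classes are random sequence at their mixture
    proportions. Each read is insert + 3' adapter truncated to the machine
    read length, with Phred+33 qualities drawn from the configured
    distribution.
    """
    if library_id not in cfg.library_depths:
        raise KeyError(f"unknown library id {library_id!r}")
    lib_index = sorted(cfg.library_depths).index(library_id)
    rng = _rng(cfg.rng_seed, _STREAM_LIBRARY, lib_index)
    depth = cfg.library_depths[library_id]
    abund = relative_abundances(cfg, hairpins)

    def draw(mean: float) -> int:
        if mean <= 0:
            return 0
        if cfg.overdispersion:
            shape = cfg.overdispersion
            lam = rng.gamma(shape, mean / shape)
            return int(rng.poisson(lam))
        return int(rng.poisson(mean))

    inserts: list[tuple[str, str]] = []  # (origin, insert sequence)
    true_counts: dict[str, int] = {}
    for h in hairpins:
        n = draw(expected_count(cfg, abund, h.name, library_id))
        true_counts[h.name] = n
        inserts.extend((h.name, h.mature_seq) for _ in range(n))

    mix = cfg.size_class_mixture
    decoy_specs = {
        "mature_miRNA_decoy": (mix["mature_miRNA"] - cfg.mapped_fraction, (20, 23)),
        "piRNA": (mix["piRNA"], (26, 28)),
        "minor41": (mix["minor41"], (41, 41)),
        "other": (mix["other"], None),
    }
    other_lengths = list(range(15, 20)) + list(range(29, 39))
    class_counts: dict[str, int] = {"mature_miRNA": sum(true_counts.values())}
    for cls, (prop, bounds) in decoy_specs.items():
        n = draw(depth * prop)
        class_counts[cls] = n
        for _ in range(n):
            if bounds is None:
                length = int(rng.choice(other_lengths))
            else:
                length = int(rng.integers(bounds[0], bounds[1] + 1))
            inserts.append((cls, _random_seq(rng, length)))

    order = rng.permutation(len(inserts))
    adapter = to_dna(cfg.adapter3p)
    seqs = [(inserts[idx][1] + adapter)[: cfg.read_length] for idx in order]
    # one bulk quality draw for the whole library
    qs = np.array(sorted(cfg.base_quality))
    ps = np.array([cfg.base_quality[q] for q in qs])
    flat = rng.choice(qs, size=sum(len(s) for s in seqs), p=ps)
    flat_list = flat.tolist()
    reads = []
    pos = 0
    for serial, seq in enumerate(seqs):
        n = len(seq)
        reads.append(
            SmallRNARead(f"{library_id}:{serial:07d}", seq, tuple(flat_list[pos : pos + n]))
        )
        pos += n
    return LibrarySim(library_id, reads, true_counts, class_counts)


@dataclass
class PlantedUTR:
    """A synthetic UTR with one planted miRNA target site.

    Coordinates are 0-based half-open on the UTR: ``seed_start``/``seed_end``
    bracket the exact Watson-Crick complement of the miRNA seed (the window
    scan_utr reports); ``site_start``/``site_end`` bracket the full-mature
    footprint.
    """

    utr: str  # DNA alphabet
    seed_start: int
    seed_end: int
    site_start: int
    site_end: int
    mature: str
    n_wobbles: int


def generate_target_utr(
    mirna_mature: str,
    flank_len: int,
    rng_seed: int,
    gc: float = 0.5,
    spec: SeedSpec = SeedSpec(),
    n_wobbles: int = 2,
) -> PlantedUTR:
    """A UTR carrying one planted site complementary to ``mirna_mature``.

    The site is the Watson-Crick reverse complement of the full mature, with
    up to ``n_wobbles`` G-U wobbles introduced at the 5'-most eligible
    positions of the 3' supplementary pairing region (never inside the
    seed). Flanks are random sequence at the stated GC fraction, re-drawn
    until the UTR contains no seed-complementary window other than the
    planted one.
    """
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    mature_rna = to_rna(mirna_mature)
    if len(mature_rna) < 8:
        raise ValueError("mature must be at least 8 nt")
    if spec.end > len(mature_rna):
        raise ValueError("seed spec exceeds mature length")
    rng = _rng(rng_seed, _STREAM_UTR)
    L = len(mature_rna)
    site = list(revcomp_dna(to_dna(mature_rna)))
    # a G-U wobble against mature G uses T->...: mature G pairs U (site T->T?);
    # in DNA letters the site base complementary to G is C; the wobble is U (T).
    # Against mature U (site A), the wobble partner is G.
    placed = 0
    for p in range(spec.end + 1, L + 1):  # supplementary region, 5'->3' on mature
        if placed >= n_wobbles:
            break
        base = mature_rna[p - 1]
        idx = L - p  # site index opposite mature position p
        if base == "G":
            site[idx] = "T"
            placed += 1
        elif base == "U":
            site[idx] = "G"
            placed += 1
    site_seq = "".join(site)
    seed_lo_in_site = L - spec.end
    seed_hi_in_site = L - spec.start + 1
    for _ in range(200):
        utr = _random_seq(rng, flank_len, gc) + site_seq + _random_seq(rng, flank_len, gc)
        hits = scan_utr(utr, mature_rna, spec)
        starts = [h.utr_start for h in hits]
        if starts == [flank_len + seed_lo_in_site]:
            return PlantedUTR(
                utr=utr,
                seed_start=flank_len + seed_lo_in_site,
                seed_end=flank_len + seed_hi_in_site,
                site_start=flank_len,
                site_end=flank_len + L,
                mature=mature_rna,
                n_wobbles=placed,
            )
    raise RuntimeError("could not generate seed-free flanks; change rng_seed")


def generate_qpcr_table(
    true_fold_changes: Mapping[str, float],
    ct_noise_sd: float,
    rng_seed: int,
    n_replicates: int = 10,
    ct_reference: float = 20.0,
    base_delta: float = 5.0,
    calibrator_group: str = "control",
) -> pd.DataFrame:
    """Comparative-CT table with planted expression ratios.

    Each group's samples satisfy CT_target = CT_reference + base_delta
    - log2(fold) + noise, so the noiseless 2^-ddCT relative to the
    calibrator group recovers the planted fold exactly. The calibrator
    group (fold 1) is always included and flagged.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    for g, f in true_fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for group {g!r} must be > 0")
    rng = _rng(rng_seed, _STREAM_QPCR)
    groups = {calibrator_group: 1.0}
    groups.update(true_fold_changes)
    rows = []
    for g, fold in groups.items():
        for i in range(n_replicates):
            noise = rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample_id": f"{g}_{i + 1:02d}",
                    "group": g,
                    "ct_target": ct_reference + base_delta - np.log2(fold) + noise,
                    "ct_reference": ct_reference,
                    "is_calibrator": g == calibrator_group,
                }
            )
    return pd.DataFrame(rows)
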