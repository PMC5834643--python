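"""miRNA target-site discovery and accessibility-corrected scoring.

A candidate site is a UTR window whose pairing to the miRNA seed (mature
positions 2-8 by default) is perfect Watson-Crick; pairing is then extended
over the full mature length, annotating each position as WC, G-U wobble or
unpaired — wobbles are forbidden inside the seed but allowed (and counted)
in the 3' supplementary region. Each site is scored by the
accessibility-corrected free energy: the hybridization energy of the miRNA
with the site region plus the cost of opening the site's local secondary
structure (see TargetScore for the sign convention).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import check_alphabet, revcomp_rna, to_rna
from .thermo import (
    DuplexResult,
    EnergyModel,
    duplex_energy,
    open_energy_window,
    pair_type,
)

DEFAULT_FLANK = 70  # nt of UTR context on each side of a site for dG_open


@dataclass(frozen=True)
class SeedSpec:
    """Seed definition: 1-based inclusive positions within the mature miRNA."""

    start: int = 2
    end: int = 8
    require_perfect_wc: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end):
            raise ValueError("seed start must satisfy 1 <= start < end")
        if self.length not in (6, 7, 8):
            raise ValueError("seed length must be 6, 7 or 8 nt")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SiteMatch:
    """A seed-complementary UTR site with its full-length pairing diagram.

    ``utr_start``/``utr_end`` are 0-based half-open coordinates of the
    seed-pairing window on the UTR sense strand. ``pairing_map`` lists
    (mature position, UTR position, pair type) for every mature position
    whose antiparallel partner falls inside the UTR; mature positions are
    1-based, UTR positions 0-based.
    """

    utr_start: int
    utr_end: int
    n_wobbles_3prime: int
    pairing_map: list[tuple[int, int, str]]


@dataclass
class TargetScore:
    """Free-energy score of one miRNA/site pair (kcal/mol).

    ``dG_open`` is reported as the non-negative cost of opening the site
    (G_constrained - G_free); the accessibility-corrected score is
    ddG = dG_duplex + dG_open, i.e. ddG = dGduplex - dGopen in the sign
    convention where dGopen = G_free - G_constrained <= 0. An inaccessible
    site therefore scores less negative (weaker) than its naked duplex.
    """

    site: SiteMatch
    dG_duplex: float
    dG_open: float
    ddG: float
    duplex: DuplexResult | None = None


def extract_seed(mature: str, spec: SeedSpec = SeedSpec()) -> str:
    """The seed substring of the mature miRNA (1-based inclusive spec)."""
    seq = check_alphabet(to_rna(mature), rna=True, name="mature")
    if spec.end > len(seq):
        raise ValueError(
            f"seed spec {spec.start}-{spec.end} exceeds mature length {len(seq)}"
        )
    return seq[spec.start - 1 : spec.end]


def scan_utr(utr: str, mature: str, spec: SeedSpec = SeedSpec()) -> list[SiteMatch]:
    """All UTR windows perfectly Watson-Crick complementary to the seed.

    For each hit the pairing is extended across the whole mature sequence
    (antiparallel), recording per-position WC/GU/none status; overlapping
    sites are all reported, sorted by UTR coordinate.
    """
    u = check_alphabet(to_rna(utr), rna=True, name="utr")
    m = check_alphabet(to_rna(mature), rna=True, name="mature")
    seed = extract_seed(m, spec)
    if len(u) < len(seed):
        raise ValueError("UTR shorter than the seed")
    target_word = revcomp_rna(seed)  # exact WC complement, read 5'->3' on the UTR
    hits: list[SiteMatch] = []
    k = len(target_word)
    for start in range(0, len(u) - k + 1):
        if u[start : start + k] != target_word:
            continue
        # mature position p pairs UTR index q, antiparallel through the seed:
        # seed start (position spec.start) pairs the 3'-most site base.
        site_end = start + k
        pairing: list[tuple[int, int, str]] = []
        n_wob = 0
        for p in range(1, len(m) + 1):
            q = (site_end - 1) - (p - spec.start)
            if not (0 <= q < len(u)):
                continue
            pt = pair_type(m[p - 1], u[q])
            pairing.append((p, q, pt))
            if pt == "GU" and p > spec.end:
                n_wob += 1
        hits.append(SiteMatch(start, site_end, n_wob, pairing))
    return hits


def site_region(utr: str, site: SiteMatch) -> tuple[str, int, int]:
    """UTR subsequence opposite the full mature length, with coordinates."""
    u = to_rna(utr)
    positions = [q for _, q, _ in site.pairing_map]
    lo, hi = min(positions), max(positions) + 1
    return u[lo:hi], lo, hi


def score_site(
    mature: str,
    utr: str,
    site: SiteMatch,
    model: EnergyModel | None = None,
    flank: int = DEFAULT_FLANK,
) -> TargetScore:
    """ddG = dG_duplex - dG_open for one site.

    dG_duplex hybridizes the mature miRNA against the UTR region opposite
    its full length; dG_open is the cost of unpairing that region within a
    window extended by ``flank`` nt on each side.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    model = model or EnergyModel.default()
    u = check_alphabet(to_rna(utr), rna=True, name="utr")
    region, lo, hi = site_region(u, site)
    dup = duplex_energy(mature, region, model)
    wlo = max(0, lo - flank)
    whi = min(len(u), hi + flank)
    dg_open = open_energy_window(u[wlo:whi], lo - wlo, hi - wlo, model)
    return TargetScore(
        site=site,
        dG_duplex=dup.energy,
        dG_open=dg_open,
        ddG=dup.energy + dg_open,
        duplex=dup,
    )


def predict_targets(
    mature: str,
    utr: str,
    spec: SeedSpec = SeedSpec(),
    model: EnergyModel | None = None,
    flank: int = DEFAULT_FLANK,
) -> list[TargetScore]:
    """Scan a UTR and score every seed site; sorted by ddG ascending."""
    model = model or EnergyModel.default()
    scores = [
        score_site(mature, utr, s, model, flank) for s in scan_utr(utr, mature, spec)
    ]
    scores.sort(key=lambda t: t.ddG)
    return scores
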