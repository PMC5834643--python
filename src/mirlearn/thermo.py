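"""Nearest-neighbor RNA thermodynamics: duplex MFE and site accessibility.

Two free-energy computations live here, both over a simplified Turner-style
nearest-neighbor model at 37 degrees C whose parameters ship as versioned
package data (``data/nn_params_37C.json``):

* ``duplex_energy`` — minimum free energy of intermolecular hybridization of
  a miRNA with a target-site region (no intramolecular pairs, no
  pseudoknots), by dynamic programming over Watson-Crick and G-U pairs with
  stacking, bulge/internal-loop penalties, a duplex initiation penalty and
  terminal AU/GU penalties at the outermost pairs.

* ``open_energy`` — the energetic cost of making a target site
  single-stranded within its local window, as the difference of two ensemble
  free energies G = -RT ln Z computed with a McCaskill-style partition
  function (hairpin loops of at least 3 nt, stacks, bulge/internal loops
  and affine multiloops), once unconstrained and once with every site base
  forced unpaired.

The accessibility-corrected interaction score used downstream is
ddG = dG_duplex - dG_open; more negative means a stronger predicted
miRNA-target interaction.

Model simplifications relative to the full Turner 2004 set, all declared:
no terminal-mismatch/dangling-end terms, no special small-loop tables
(1x1/1x2/2x2 interior loops use the generic size cost), bulges interrupt
stacking, no coaxial stacking, no loop-asymmetry penalty. The parameter
file is a swappable artifact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from ._seq import check_alphabet, to_rna

#: Allowed base pairs (RNA alphabet): Watson-Crick plus G-U wobble.
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})
ALL_PAIRS = WC_PAIRS | GU_PAIRS

MIN_HAIRPIN = 3  # minimum unpaired bases closed by an intramolecular pair


def pair_type(a: str, b: str) -> str:
    """'WC', 'GU' or 'none' for an (a, b) base pair (RNA alphabet)."""
    if (a, b) in WC_PAIRS:
        return "WC"
    if (a, b) in GU_PAIRS:
        return "GU"
    return "none"


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor parameter set (kcal/mol at a fixed temperature)."""

    stacks: dict[str, float]
    hairpin_loop: dict[int, float]
    bulge_loop: dict[int, float]
    internal_loop: dict[int, float]
    loop_extrapolation_coef: float
    max_loop_size: int
    multiloop_closing: float
    multiloop_branch: float
    multiloop_unpaired: float
    init_penalty: float
    au_end_penalty: float
    RT: float

    def __post_init__(self) -> None:
        for table in (self.hairpin_loop, self.bulge_loop, self.internal_loop):
            sizes = sorted(table)
            # loop costs must not decrease with size once extrapolation starts
            if self._extrapolate(table, max(sizes) + 5) < table[max(sizes)]:
                raise ValueError("loop extrapolation must be non-decreasing")

    @classmethod
    def default(cls) -> "EnergyModel":
        with resources.files("mirlearn.data").joinpath("nn_params_37C.json").open() as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyModel":
        return cls(
            stacks=dict(d["stacks"]),
            hairpin_loop={int(k): float(v) for k, v in d["hairpin_loop"].items()},
            bulge_loop={int(k): float(v) for k, v in d["bulge_loop"].items()},
            internal_loop={int(k): float(v) for k, v in d["internal_loop"].items()},
            loop_extrapolation_coef=float(d["loop_extrapolation_coef"]),
            max_loop_size=int(d["max_loop_size"]),
            multiloop_closing=float(d["multiloop"]["closing"]),
            multiloop_branch=float(d["multiloop"]["branch"]),
            multiloop_unpaired=float(d["multiloop"]["unpaired"]),
            init_penalty=float(d["init_penalty"]),
            au_end_penalty=float(d["au_end_penalty"]),
            RT=float(d["RT"]),
        )

    # -- parameter lookups ------------------------------------------------

    def stack_energy(self, p1: tuple[str, str], p2: tuple[str, str]) -> float:
        """Energy of the stack outer pair p1 on inner pair p2."""
        return self.stacks[f"{p1[0]}{p1[1]}:{p2[0]}{p2[1]}"]

    def _extrapolate(self, table: dict[int, float], size: int) -> float:
        m = max(table)
        if size <= m:
            return table[size]
        return table[m] + self.loop_extrapolation_coef * self.RT * math.log(size / m)

    def hairpin_energy(self, size: int) -> float:
        if size < MIN_HAIRPIN:
            raise ValueError(f"hairpin loop of {size} < {MIN_HAIRPIN} nt")
        return self._extrapolate(self.hairpin_loop, size)

    def loop_energy(self, g1: int, g2: int) -> float:
        """Bulge/internal-loop cost between consecutive pairs (g1, g2 unpaired)."""
        total = g1 + g2
        if total == 0:
            raise ValueError("use stack_energy for adjacent pairs")
        if g1 == 0 or g2 == 0:
            return self._extrapolate(self.bulge_loop, total)
        return self._extrapolate(self.internal_loop, total)

    def end_penalty(self, p: tuple[str, str]) -> float:
        """Terminal penalty for a helix-closing AU or GU pair."""
        return self.au_end_penalty if p not in {("G", "C"), ("C", "G")} else 0.0


# ---------------------------------------------------------------------------
# Intermolecular duplex minimum free energy
# ---------------------------------------------------------------------------


@dataclass
class DuplexResult:
    """MFE and one optimal pairing trace of an intermolecular duplex.

    ``pairs`` lists (i, j): position i of strand 1 paired with position j of
    strand 2, both 0-based on their 5'->3' sequences; i ascending, j
    descending (antiparallel). When no pair is possible the energy is 0 by
    convention and ``pairs`` is empty.
    """

    energy: float
    pairs: list[tuple[int, int]] = field(default_factory=list)


def duplex_energy(
    strand1: str, strand2: str, model: EnergyModel | None = None
) -> DuplexResult:
    """Minimum free energy of intermolecular hybridization.

    Both strands are given 5'->3' (RNA or DNA letters; converted to RNA).
    Structures are non-crossing sets of intermolecular pairs; consecutive
    pairs contribute a stack when adjacent on both strands, otherwise a
    bulge/internal-loop penalty. The duplex initiation penalty and the
    terminal penalties of the two outermost pairs are added once.
    """
    model = model or EnergyModel.default()
    s1 = check_alphabet(to_rna(strand1), rna=True, name="strand1")
    s2 = check_alphabet(to_rna(strand2), rna=True, name="strand2")
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("both strands must be at least 2 nt")
    m, n = len(s1), len(s2)
    maxloop = model.max_loop_size
    NEG = -math.inf

    # B[i][j]: best energy of a structure whose 3'-most (on strand 1) pair is
    # (i, j), including the 5' terminal penalty but not the 3' one.
    B = np.full((m, n), math.inf)
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    pairable = [
        [(s1[i], s2[j]) in ALL_PAIRS for j in range(n)] for i in range(m)
    ]
    for i in range(m):
        for j in range(n - 1, -1, -1):
            if not pairable[i][j]:
                continue
            best = model.end_penalty((s1[i], s2[j]))  # start a new helix
            origin: tuple[int, int] | None = None
            for ip in range(max(0, i - maxloop - 1), i):
                if math.isinf(B[ip].min()):
                    continue
                for jp in range(j + 1, min(n, j + maxloop + 2)):
                    if math.isinf(B[ip, jp]):
                        continue
                    g1 = i - ip - 1
                    g2 = jp - j - 1
                    if g1 + g2 > maxloop:
                        continue
                    if g1 == 0 and g2 == 0:
                        link = model.stack_energy((s1[ip], s2[jp]), (s1[i], s2[j]))
                    else:
                        link = model.loop_energy(g1, g2)
                    cand = B[ip, jp] + link
                    if cand < best:
                        best = cand
                        origin = (ip, jp)
            B[i, j] = best
            back[(i, j)] = origin

    best_total = 0.0
    best_end: tuple[int, int] | None = None
    for i in range(m):
        for j in range(n):
            if math.isinf(B[i, j]):
                continue
            total = model.init_penalty + B[i, j] + model.end_penalty((s1[i], s2[j]))
            if total < best_total:
                best_total = total
                best_end = (i, j)
    if best_end is None:
        return DuplexResult(0.0, [])
    pairs: list[tuple[int, int]] = []
    node: tuple[int, int] | None = best_end
    while node is not None:
        pairs.append(node)
        node = back[node]
    pairs.reverse()
    return DuplexResult(float(best_total), pairs)


# ---------------------------------------------------------------------------
# McCaskill partition function and site opening energy
# ---------------------------------------------------------------------------


def partition_function(
    seq: str,
    model: EnergyModel | None = None,
    unpaired: Iterable[int] = (),
) -> float:
    """ln Z of the intramolecular secondary-structure ensemble of ``seq``.

    Structures are non-crossing sets of WC/GU pairs with hairpin loops of at
    least MIN_HAIRPIN nt. Energies follow the loop decomposition: hairpin
    and bulge/internal penalties, stacking for adjacent pairs, and an affine
    multiloop cost (closing + per-branch + per-unpaired). Exterior bases are
    free. Positions in ``unpaired`` (0-based) are constrained single-stranded.
    """
    model = model or EnergyModel.default()
    s = check_alphabet(to_rna(seq), rna=True, name="sequence")
    n = len(s)
    beta = 1.0 / model.RT
    forbidden = set(unpaired)
    maxloop = model.max_loop_size

    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if i in forbidden:
            continue
        for j in range(i + MIN_HAIRPIN + 1, n):
            if j in forbidden:
                continue
            can[i, j] = (s[i], s[j]) in ALL_PAIRS

    if not can.any():
        return 0.0

    # generic loop weights by (g1, g2); the (0,0) stack entry is base-dependent
    wloop = np.zeros((maxloop + 1, maxloop + 1))
    for g1 in range(maxloop + 1):
        for g2 in range(maxloop + 1):
            if g1 == 0 and g2 == 0:
                continue
            if g1 + g2 <= maxloop:
                wloop[g1, g2] = math.exp(-beta * model.loop_energy(g1, g2))

    wb = math.exp(-beta * model.multiloop_branch)
    wu = math.exp(-beta * model.multiloop_unpaired)
    wclose = math.exp(-beta * model.multiloop_closing)

    Zb = np.zeros((n, n))  # closed by pair (i, j)
    ZM1 = np.zeros((n, n))  # multiloop segment: one branch starting at i
    ZM = np.zeros((n, n))  # multiloop segment: >= 1 branch
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if can[i, j]:
                z = math.exp(-beta * model.hairpin_energy(j - i - 1))
                # stack / bulge / internal loop closing an inner pair (k, l)
                kmax = min(i + maxloop + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (maxloop - g1))
                    row = Zb[k]
                    for l in range(lmin, j):
                        if row[l] == 0.0:
                            continue
                        g2 = j - l - 1
                        if g1 == 0 and g2 == 0:
                            w = math.exp(
                                -beta * model.stack_energy((s[i], s[j]), (s[k], s[l]))
                            )
                        else:
                            w = wloop[g1, g2]
                        z += w * row[l]
                # multiloop: >= 2 branches inside [i+1, j-1]
                if span >= 2 * (MIN_HAIRPIN + 2):
                    acc = 0.0
                    for k in range(i + 2, j - MIN_HAIRPIN - 1):
                        if ZM1[k, j - 1] > 0.0:
                            acc += ZM[i + 1, k - 1] * ZM1[k, j - 1]
                    z += wclose * wb * acc
                Zb[i, j] = z
            # ZM1: exactly one branch, starting at i
            zm1 = 0.0
            for l in range(i + MIN_HAIRPIN + 1, j + 1):
                if Zb[i, l] > 0.0:
                    zm1 += Zb[i, l] * wb * wu ** (j - l)
            ZM1[i, j] = zm1
            # ZM: at least one branch anywhere in [i, j]
            zm = 0.0
            for k in range(i, j + 1):
                if ZM1[k, j] == 0.0:
                    continue
                zm += (wu ** (k - i)) * ZM1[k, j]
                if k > i:
                    zm += ZM[i, k - 1] * ZM1[k, j]
            # subtract double counting: the first term covers "all unpaired
            # before k"; the second "some branch before k" — disjoint, no overlap
            ZM[i, j] = zm

    # exterior loop
    Z = np.ones(n + 1)
    for j in range(1, n + 1):
        z = Z[j - 1]
        for i in range(0, j):
            if Zb[i, j - 1] > 0.0:
                z += Z[i] * Zb[i, j - 1]
        Z[j] = z
    return float(math.log(Z[n]))


def ensemble_free_energy(
    seq: str, model: EnergyModel | None = None, unpaired: Iterable[int] = ()
) -> float:
    """G = -RT ln Z over the (optionally constrained) ensemble."""
    model = model or EnergyModel.default()
    return -model.RT * partition_function(seq, model, unpaired)


def open_energy_window(
    window: str,
    site_start: int,
    site_end: int,
    model: EnergyModel | None = None,
) -> float:
    """dG_open of the site [site_start, site_end) within ``window``.

    The cost of forcing every site base single-stranded:
    G_constrained - G_unconstrained >= 0 (the constrained ensemble is a
    subset of the free one). Clipped at 0 against roundoff.
    """
    model = model or EnergyModel.default()
    if not (0 <= site_start < site_end <= len(window)):
        raise ValueError("site must lie within the window")
    g_free = ensemble_free_energy(window, model)
    g_con = ensemble_free_energy(window, model, range(site_start, site_end))
    return max(0.0, g_con - g_free)
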