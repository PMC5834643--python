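"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's dynamic-programming / special-function
code paths: duplex structures are enumerated recursively and scored by
direct summation over the explicit pair list; intramolecular ensembles are
enumerated structure by structure and Boltzmann-summed; the exact-test tail
is summed via the probability-mass recurrence.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

from mirlearn.thermo import ALL_PAIRS, MIN_HAIRPIN, EnergyModel

# ---- intermolecular duplex -------------------------------------------------


def enumerate_duplex_structures(s1: str, s2: str) -> Iterator[list[tuple[int, int]]]:
    """All non-crossing sets of intermolecular pairs (antiparallel)."""
    m, n = len(s1), len(s2)

    def rec(i: int, jmax: int) -> Iterator[list[tuple[int, int]]]:
        yield []
        for ii in range(i, m):
            for jj in range(0, jmax):
                if (s1[ii], s2[jj]) in ALL_PAIRS:
                    for rest in rec(ii + 1, jj):
                        yield [(ii, jj)] + rest

    yield from rec(0, n)


def duplex_structure_energy(
    pairs: list[tuple[int, int]], s1: str, s2: str, model: EnergyModel
) -> float:
    if not pairs:
        return 0.0
    e = model.init_penalty
    e += model.end_penalty((s1[pairs[0][0]], s2[pairs[0][1]]))
    e += model.end_penalty((s1[pairs[-1][0]], s2[pairs[-1][1]]))
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        g1, g2 = k - i - 1, j - l - 1
        if g1 == 0 and g2 == 0:
            e += model.stack_energy((s1[i], s2[j]), (s1[k], s2[l]))
        else:
            e += model.loop_energy(g1, g2)
    return e


def brute_force_duplex_mfe(s1: str, s2: str, model: EnergyModel) -> float:
    best = 0.0
    for pairs in enumerate_duplex_structures(s1, s2):
        if pairs:
            best = min(best, duplex_structure_energy(pairs, s1, s2, model))
    return best


# ---- intramolecular ensembles ----------------------------------------------


def enumerate_structures(
    s: str, forbidden: frozenset[int] = frozenset()
) -> Iterator[list[tuple[int, int]]]:
    """All non-crossing secondary structures with hairpin loops >= 3 nt."""
    n = len(s)
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_HAIRPIN + 1, n)
        if (s[i], s[j]) in ALL_PAIRS and i not in forbidden and j not in forbidden
    ]

    def rec(avail: list[tuple[int, int]]) -> Iterator[list[tuple[int, int]]]:
        yield []
        for idx, (i, j) in enumerate(avail):
            inside = [(k, l) for (k, l) in avail[idx + 1 :] if i < k and l < j]
            outside = [(k, l) for (k, l) in avail[idx + 1 :] if k > j]
            for sin in rec(inside):
                for sout in rec(outside):
                    yield [(i, j)] + sin + sout

    yield from rec(candidates)


def loop_decomposition_energy(
    structure: Iterable[tuple[int, int]], s: str, model: EnergyModel
) -> float:
    """Energy of one explicit structure by loop decomposition."""
    S = sorted(structure)
    if not S:
        return 0.0
    opens = {i: (i, j) for (i, j) in S}
    e = 0.0
    for i, j in S:
        children = []
        k = i + 1
        while k < j:
            if k in opens:
                children.append(opens[k])
                k = opens[k][1] + 1
            else:
                k += 1
        if not children:
            e += model.hairpin_energy(j - i - 1)
        elif len(children) == 1:
            (a, b) = children[0]
            if a == i + 1 and b == j - 1:
                e += model.stack_energy((s[i], s[j]), (s[a], s[b]))
            else:
                e += model.loop_energy(a - i - 1, j - b - 1)
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for (a, b) in children)
            e += (
                model.multiloop_closing
                + model.multiloop_branch * (len(children) + 1)
                + model.multiloop_unpaired * unpaired
            )
    return e


def brute_force_log_partition(
    s: str, model: EnergyModel, forbidden: frozenset[int] = frozenset()
) -> float:
    z = sum(
        math.exp(-loop_decomposition_energy(S, s, model) / model.RT)
        for S in enumerate_structures(s, forbidden)
    )
    return math.log(z)


# ---- Audic-Claverie test ---------------------------------------------------


def ac_pmf_sequence(x: int, n1: int, n2: int, y_max: int) -> list[float]:
    """p(y | x) for y = 0..y_max via the mass recurrence (no special functions)."""
    rho = n2 / n1
    p0 = (1.0 / (1.0 + rho)) ** (x + 1)
    out = [p0]
    for y in range(y_max):
        out.append(out[-1] * (x + y + 1) / (y + 1) * (rho / (1.0 + rho)))
    return out


def _logaddexp(a: float | None, b: float) -> float:
    if a is None:
        return b
    hi, lo = (a, b) if a >= b else (b, a)
    return hi + math.log1p(math.exp(lo - hi))


def brute_force_ac_test(x: int, y: int, n1: int, n2: int, sidedness: str) -> float:
    """Tail sums of the p(y | x) recurrence, carried out in log space.

    Both tails are summed term by term (no special functions, no CDF), so
    the only shared machinery with the implementation under test is
    elementary arithmetic. The upper tail P(Y >= y) is summed directly
    rather than as 1 - P(Y < y), avoiding cancellation when it is tiny;
    terms decay geometrically with ratio -> q once k passes the mode, so a
    geometric bound closes the truncated remainder.
    """
    rho = n2 / n1
    log_q = math.log(rho) - math.log1p(rho)
    log_t = -(x + 1) * math.log1p(rho)  # log p(0 | x)
    lower_log: float | None = None
    for k in range(y + 1):
        lower_log = _logaddexp(lower_log, log_t)
        if k < y:
            log_t += math.log((x + k + 1) / (k + 1)) + log_q
    # log_t now holds log p(y | x)
    upper_log: float | None = None
    k = y
    mode = (x + 1) * rho
    log_cut = math.log(1e-18) + math.log1p(-math.exp(log_q))
    while k < mode or upper_log is None or log_t > upper_log + log_cut:
        upper_log = _logaddexp(upper_log, log_t)
        log_t += math.log((x + k + 1) / (k + 1)) + log_q
        k += 1
    # geometric bound on the truncated remainder: next_term / (1 - q)
    upper_log = _logaddexp(upper_log, log_t - math.log1p(-math.exp(log_q)))
    lower = math.exp(lower_log) if lower_log is not None else 0.0
    upper = math.exp(upper_log)
    if sidedness == "greater":
        return min(1.0, upper)
    if sidedness == "less":
        return min(1.0, lower)
    return min(1.0, 2.0 * min(lower, upper))
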