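"""Audic-Claverie exact test, Benjamini-Hochberg correction, DE calls.

The Audic-Claverie test compares a tag's counts x and y between two
sequencing libraries of totals N1 and N2 without replicates, under Poisson
sampling with a flat prior on the common rate. The probability of observing
y in library 2 given x in library 1 is

    p(y | x) = (N2/N1)^y * (x + y)! / (x! y! (1 + N2/N1)^(x + y + 1)),

which is the negative-binomial predictive distribution with r = x + 1
successes and success probability N1 / (N1 + N2). All mass computations run
in log space; tail probabilities use the same distribution's CDF/SF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .quantify import CountTable

SIDEDNESS = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class ACTestInput:
    """Counts x, y of one tag in two libraries with totals N1, N2."""

    x: int
    y: int
    N1: int
    N2: int

    def __post_init__(self) -> None:
        for f in ("x", "y", "N1", "N2"):
            v = getattr(self, f)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{f} must be a non-negative integer, got {v!r}")
        if self.N1 < 1 or self.N2 < 1:
            raise ValueError("library totals must be >= 1")
        if self.x > self.N1 or self.y > self.N2:
            raise ValueError("counts cannot exceed library totals")


@dataclass
class DifferentialResult:
    """One miRNA's differential-expression summary for a library pair."""

    mirna: str
    x: int
    y: int
    N1: int
    N2: int
    fold_change: float  # (y/N2) / (x/N1); inf when x == 0 and y > 0
    p_raw: float
    p_adj: float
    significant: bool


def _nb_params(inp: ACTestInput) -> tuple[int, float]:
    # y | x ~ NB(r = x + 1, p = N1 / (N1 + N2))
    return inp.x + 1, inp.N1 / (inp.N1 + inp.N2)


def ac_probability(inp: ACTestInput) -> float:
    """Probability mass p(y | x, N1, N2), computed via log-gamma."""
    x, y = inp.x, inp.y
    log_ratio = math.log(inp.N2) - math.log(inp.N1)
    log_p = (
        y * log_ratio
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(inp.N2 / inp.N1)
    )
    return float(math.exp(log_p))


def ac_test(inp: ACTestInput, sidedness: str = "two_sided") -> float:
    """Exact Audic-Claverie p-value.

    One-sided p-values are the cumulative mass of outcomes as or more
    extreme than the observed y (the observed point included once); the
    two-sided p-value doubles the smaller tail, capped at 1.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    r, p = _nb_params(inp)
    lower = float(nbinom.cdf(inp.y, r, p))
    upper = float(nbinom.sf(inp.y - 1, r, p))  # P(Y >= y)
    if sidedness == "greater":
        pval = upper
    elif sidedness == "less":
        pval = lower
    else:
        pval = min(1.0, 2.0 * min(lower, upper))
    return max(min(pval, 1.0), 5e-324)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def fold_change(x: int, y: int, N1: int, N2: int) -> float:
    """Rate ratio (y/N2) / (x/N1); inf when x == 0 < y, nan when both 0."""
    if x == 0 and y == 0:
        return float("nan")
    if x == 0:
        return float("inf")
    return (y / N2) / (x / N1)


def call_differential(
    table: CountTable,
    pair: tuple[str, str],
    alpha: float = 0.01,
    sidedness: str = "two_sided",
) -> list[DifferentialResult]:
    """Per-miRNA A-C test between two libraries with BH correction.

    A miRNA is called significant when its BH-adjusted p-value is strictly
    below ``alpha``. Results are sorted by adjusted p then name.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    lib1, lib2 = pair
    for lib in pair:
        if lib not in table.libraries:
            raise ValueError(f"library {lib!r} not in count table")
    xs = table.column(lib1)
    ys = table.column(lib2)
    N1 = int(xs.sum())
    N2 = int(ys.sum())
    p_raw = [
        ac_test(ACTestInput(int(x), int(y), N1, N2), sidedness)
        for x, y in zip(xs, ys)
    ]
    p_adj = bh_adjust(p_raw)
    results = [
        DifferentialResult(
            mirna=name,
            x=int(x),
            y=int(y),
            N1=N1,
            N2=N2,
            fold_change=fold_change(int(x), int(y), N1, N2),
            p_raw=float(pr),
            p_adj=float(pa),
            significant=bool(pa < alpha),
        )
        for name, x, y, pr, pa in zip(table.mirna_names, xs, ys, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.mirna))
    return results


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (r.mirna, r.x, r.y, r.N1, r.N2, r.fold_change, r.p_raw, r.p_adj, r.significant)
            for r in results
        ],
        columns=["mirna", "x", "y", "N1", "N2", "fold_change", "p_raw", "p_adj", "significant"],
    )
    return df


def write_results(results: Sequence[DifferentialResult], path) -> None:
    df = results_to_frame(results)
    # TSV renders infinite fold changes as "Inf"
    df["fold_change"] = df["fold_change"].map(
        lambda v: "Inf" if math.isinf(v) else ("NA" if math.isnan(v) else f"{v:.6g}")
    )
    df.to_csv(path, sep="\t", index=False)
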