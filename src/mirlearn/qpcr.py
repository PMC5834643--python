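"""Relative quantification of qPCR data by the comparative CT method.

Expression of a target RNA relative to a calibrator condition is
2^-ddCT, where dCT = CT(target) - CT(reference) within each sample and
ddCT = dCT - dCT(calibrator). The calibrator may be a single designated
sample or (default) the mean dCT of a designated group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CTMeasurement:
    """One sample's threshold cycles for target and reference assays."""

    sample_id: str
    group: str
    ct_target: float
    ct_reference: float
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        for f in ("ct_target", "ct_reference"):
            v = getattr(self, f)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{self.sample_id}: {f} must be finite and > 0")


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float


def delta_ct(m: CTMeasurement) -> float:
    """dCT = CT(target) - CT(reference)."""
    return m.ct_target - m.ct_reference


def relative_quantity(sample: CTMeasurement, calibrator: CTMeasurement | float) -> float:
    """2^-(dCT(sample) - dCT(calibrator)).

    ``calibrator`` may be a CTMeasurement or a precomputed calibrator dCT.
    A sample measured against itself yields exactly 1.
    """
    cal_dct = calibrator if isinstance(calibrator, (int, float)) else delta_ct(calibrator)
    return 2.0 ** -(delta_ct(sample) - cal_dct)


def calibrator_delta_ct(
    measurements: Sequence[CTMeasurement], policy: str = "group_mean"
) -> float:
    """dCT of the calibrator under the chosen policy.

    ``group_mean``: mean dCT over all samples flagged is_calibrator.
    ``single``: exactly one flagged sample is required.
    """
    cal = [m for m in measurements if m.is_calibrator]
    if not cal:
        raise ValueError("no calibrator samples flagged")
    if policy == "single":
        if len(cal) != 1:
            raise ValueError(f"'single' calibrator policy requires one sample, got {len(cal)}")
        return delta_ct(cal[0])
    if policy == "group_mean":
        return float(np.mean([delta_ct(m) for m in cal]))
    raise ValueError(f"unknown calibrator policy {policy!r}")


def summarize_groups(
    measurements: Sequence[CTMeasurement], calibrator_policy: str = "group_mean"
) -> list[GroupSummary]:
    """Per-group mean and SEM of 2^-ddCT relative quantities."""
    if not measurements:
        raise ValueError("no measurements")
    cal_dct = calibrator_delta_ct(measurements, calibrator_policy)
    groups: dict[str, list[float]] = {}
    for m in measurements:
        groups.setdefault(m.group, []).append(relative_quantity(m, cal_dct))
    out = []
    for g, vals in groups.items():
        n = len(vals)
        if n == 1:
            warnings.warn(f"group {g!r} has a single sample; SEM reported as 0")
            sem = 0.0
        else:
            sem = float(np.std(vals, ddof=1) / math.sqrt(n))
        out.append(GroupSummary(g, n, float(np.mean(vals)), sem))
    return out


def read_ct_table(path) -> list[CTMeasurement]:
    """Read the TSV schema sample_id, group, ct_target, ct_reference, is_calibrator."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "ct_target", "ct_reference", "is_calibrator"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns {sorted(missing)}")
    return [
        CTMeasurement(
            str(r.sample_id),
            str(r.group),
            float(r.ct_target),
            float(r.ct_reference),
            bool(r.is_calibrator),
        )
        for r in df.itertuples()
    ]


def quantities_frame(
    measurements: Sequence[CTMeasurement], calibrator_policy: str = "group_mean"
) -> pd.DataFrame:
    """Sample-level relative quantities as a DataFrame."""
    cal_dct = calibrator_delta_ct(measurements, calibrator_policy)
    return pd.DataFrame(
        [
            (m.sample_id, m.group, delta_ct(m), relative_quantity(m, cal_dct))
            for m in measurements
        ],
        columns=["sample_id", "group", "delta_ct", "relative_quantity"],
    )
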