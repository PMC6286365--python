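"""Plate-level quality-control statistics for screening plates.

Z' (Z-prime) summarises the separation between saturating positive-control
and no-enzyme negative-control wells::

    Z' = 1 - 3 * (sd_pos + sd_neg) / |mean_pos - mean_neg|

with sample (n-1) standard deviations.  A Z' >= 0.5 conventionally denotes an
excellent assay.  Signal/background is the ratio of the control means.  The
positional-effect screen flags rows or columns of the compound field whose
median signal deviates from the plate median by more than a configurable
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, UndefinedSeparationError
from .plates import ROLE_NEG, ROLE_POS, ROLE_TEST

__all__ = ["PlateQC", "z_prime", "signal_to_background", "positional_effect", "plate_qc"]


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    pos_mean: float
    pos_sd: float
    neg_mean: float
    neg_sd: float
    z_prime: float
    signal_to_background: float
    positional_flag: bool
    positional_offenders: tuple = ()

    @property
    def passed(self) -> bool:
        return self.z_prime >= 0.5 and not self.positional_flag


def _arm(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidParameterError(f"{name} control arm needs >= 2 wells")
    return arr


def z_prime(pos, neg) -> float:
    """Z' separation statistic of the two control arms (symmetric in arms)."""
    p, n = _arm(pos, "positive"), _arm(neg, "negative")
    mu_p, mu_n = p.mean(), n.mean()
    if mu_p == mu_n:
        raise UndefinedSeparationError("control means are equal; Z' undefined")
    sd_p, sd_n = p.std(ddof=1), n.std(ddof=1)
    return 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)


def signal_to_background(pos, neg) -> float:
    """Ratio of positive to negative control means."""
    p, n = _arm(pos, "positive"), _arm(neg, "negative")
    if n.mean() <= 0:
        raise InvalidParameterError("background mean must be > 0")
    return float(p.mean() / n.mean())


def positional_effect(
    plate: pd.DataFrame, threshold: float = 0.2
) -> tuple[bool, pd.DataFrame]:
    """Median-deviation screen of the compound field for row/column artefacts.

    Flags the plate when any row or column median of test-well RFU deviates
    from the overall test-field median by more than ``threshold`` (fraction).
    Returns ``(flag, report)`` where the report has one line per row/column
    with its median, relative deviation, and flag.
    """
    if threshold <= 0:
        raise InvalidParameterError("threshold must be > 0")
    test = plate[plate["role"] == ROLE_TEST]
    if test.empty:
        raise InvalidParameterError("plate has no test wells")
    grand = float(test["rfu"].median())
    if grand <= 0:
        raise InvalidParameterError("test-field median must be > 0")
    records = []
    for axis, key in (("row", "row"), ("col", "col")):
        med = test.groupby(key)["rfu"].median()
        for label, m in med.items():
            dev = (m - grand) / grand
            records.append((axis, label, float(m), float(dev), abs(dev) > threshold))
    report = pd.DataFrame(
        records, columns=["axis", "label", "median_rfu", "rel_deviation", "flagged"]
    )
    return bool(report["flagged"].any()), report


def plate_qc(plate: pd.DataFrame, positional_threshold: float = 0.2) -> PlateQC:
    """All QC statistics for one plate table (columns per the plate schema)."""
    pos = plate.loc[plate["role"] == ROLE_POS, "rfu"].to_numpy()
    neg = plate.loc[plate["role"] == ROLE_NEG, "rfu"].to_numpy()
    flag, report = positional_effect(plate, threshold=positional_threshold)
    offenders = tuple(
        (r.axis, r.label) for r in report.itertuples() if r.flagged
    )
    plate_ids = plate["plate_id"].unique()
    return PlateQC(
        plate_id=str(plate_ids[0]) if len(plate_ids) else "",
        pos_mean=float(np.mean(pos)),
        pos_sd=float(np.std(pos, ddof=1)),
        neg_mean=float(np.mean(neg)),
        neg_sd=float(np.std(neg, ddof=1)),
        z_prime=z_prime(pos, neg),
        signal_to_background=signal_to_background(pos, neg),
        positional_flag=flag,
        positional_offenders=offenders,
    )
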