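"""Hyperactivity classification against a control-referenced threshold.

The hyperactivity criterion is computed per timepoint from the control
(pCtrl) group only: threshold = mean + 2 · sample SD (ddof = 1) of the
control spikes/min.  Neurons are then classified exhaustively and mutually
exclusively:

* silent       — exactly zero spikes;
* active       — 0 < rate ≤ threshold (a rate exactly at threshold is
                 active, because hyperactivity requires "larger than");
* hyperactive  — rate > threshold.

Group summaries report class fractions (exact rational arithmetic on counts
before float conversion) and mean rates normalized to a reference group and
timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateReferenceError,
    InsufficientControlError,
    InvalidParameterError,
    LabelMismatchError,
)

__all__ = [
    "ActivityThreshold",
    "CLASSES",
    "control_threshold",
    "classify_neurons",
    "class_fractions",
    "normalize_rates",
]

CLASSES = ("silent", "active", "hyperactive")


@dataclass
class ActivityThreshold:
    """Control mean + 2·SD hyperactivity cut for one timepoint (spikes/min)."""

    timepoint_label: str
    control_mean: float
    control_sd: float
    n_control: int

    @property
    def threshold(self) -> float:
        return self.control_mean + 2.0 * self.control_sd


def control_threshold(control_rates, timepoint_label: str = "") -> ActivityThreshold:
    """Hyperactivity threshold from control spikes/min at one timepoint.

    Uses the sample standard deviation (ddof = 1).  Requires at least two
    control neurons.  A zero-variance control pool is allowed but warned
    about, since the threshold then collapses to the mean.
    """
    rates = np.asarray(list(control_rates), dtype=float)
    if rates.size < 2:
        raise InsufficientControlError("need at least 2 control neurons for mean + 2*SD")
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise InvalidParameterError("control rates must be finite and non-negative")
    sd = float(np.std(rates, ddof=1))
    if sd == 0.0:
        warnings.warn(
            f"zero-variance control rates at timepoint {timepoint_label!r}: "
            "threshold equals the control mean",
            stacklevel=2,
        )
    return ActivityThreshold(
        timepoint_label=timepoint_label,
        control_mean=float(np.mean(rates)),
        control_sd=sd,
        n_control=int(rates.size),
    )


def classify_neurons(rates: pd.DataFrame, threshold: ActivityThreshold) -> pd.DataFrame:
    """Classify each ROI of a spike-rate table as silent/active/hyperactive.

    ``rates`` is the table produced by :func:`iglonquant.events.spike_rates`
    (columns roi_id, rate, timepoint, ...).  The threshold must come from the
    same timepoint, else :class:`LabelMismatchError`.
    """
    if "rate" not in rates.columns or "roi_id" not in rates.columns:
        raise InvalidParameterError("rates table needs roi_id and rate columns")
    if "timepoint" in rates.columns and len(rates):
        tps = set(rates["timepoint"].astype(str))
        if tps and tps != {str(threshold.timepoint_label)}:
            raise LabelMismatchError(
                f"rates are from timepoint(s) {sorted(tps)} but threshold is for "
                f"{threshold.timepoint_label!r}"
            )
    r = rates["rate"].to_numpy(dtype=float)
    if np.any(r < 0):
        raise InvalidParameterError("negative spike rate")
    cls = np.where(r == 0, "silent", np.where(r > threshold.threshold, "hyperactive", "active"))
    out = rates.copy()
    out["class"] = cls
    out["threshold"] = threshold.threshold
    return out


def class_fractions(classifications: pd.DataFrame | list[str]) -> dict[str, float]:
    """Fractions of (silent, active, hyperactive); sums to exactly 1.

    Counts are reduced with exact rational arithmetic before conversion to
    float, so the three fractions always add to 1.0.
    """
    if isinstance(classifications, pd.DataFrame):
        labels = list(classifications["class"])
    else:
        labels = list(classifications)
    if not labels:
        raise InvalidParameterError("no classified neurons")
    unknown = set(labels) - set(CLASSES)
    if unknown:
        raise InvalidParameterError(f"unknown class labels {sorted(unknown)}")
    n = len(labels)
    return {c: float(Fraction(labels.count(c), n)) for c in CLASSES}


def normalize_rates(
    rates: pd.DataFrame,
    reference_group: str,
    reference_timepoint: str,
) -> pd.DataFrame:
    """Mean spikes/min per (group, timepoint), divided by the reference mean.

    Emulates figure-style normalization such as "normalized to NT at 60 min":
    every group/timepoint mean is expressed relative to the mean rate of
    ``reference_group`` at ``reference_timepoint``.
    """
    for col in ("group", "timepoint", "rate"):
        if col not in rates.columns:
            raise InvalidParameterError(f"rates table needs a {col!r} column")
    summary = (
        rates.groupby(["group", "timepoint"], sort=False)["rate"]
        .agg(mean_rate="mean", n="size")
        .reset_index()
    )
    ref = summary[
        (summary["group"] == reference_group) & (summary["timepoint"] == reference_timepoint)
    ]
    if ref.empty:
        raise InvalidParameterError(
            f"reference ({reference_group!r}, {reference_timepoint!r}) not present"
        )
    ref_mean = float(ref["mean_rate"].iloc[0])
    if ref_mean <= 0:
        raise DegenerateReferenceError("reference group mean rate is zero")
    summary["normalized_rate"] = summary["mean_rate"] / ref_mean
    return summary
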