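"""Screening performance against pathology ground truth.

Paraffin-section H&E is the reference standard: label P (tumor present) or
N (tumor-free).  A specimen is screen-positive when its triage call is
``++`` or ``+`` and screen-negative when it is ``-``.  Beyond the usual
confusion rates we always report NPV, because the clinical promise of a
pre-screen ("a negative margin can close the case") is an NPV statement,
not a specificity one.  Rates with a zero denominator are reported as
``None`` — never silently coerced to 0 or 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from marginscreen.image_quant import SampleRecord
from marginscreen.screening import DEFINITE_POS, SUSPECT_POS, NEG

__all__ = ["ConfusionSummary", "GroupCrosstab", "confusion_summary",
           "group_crosstab", "write_report_json", "write_crosstab_csv"]

_CALLS = (DEFINITE_POS, SUSPECT_POS, NEG)
_LABELS = ("P", "N")


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 screen-vs-pathology counts with the derived rates."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroupCrosstab:
    """3x2 contingency of triage call vs H&E label."""

    counts: dict[tuple[str, str], int]

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        data = {lab: [self.counts[(c, lab)] for c in _CALLS] for lab in _LABELS}
        return pd.DataFrame(data, index=list(_CALLS)).rename_axis("call")


def _rate(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def _check_complete(records: Sequence[SampleRecord]) -> None:
    for r in records:
        if r.call is None:
            raise ValueError(f"record {r.sample_id!r} has no triage call")
        if r.he_label is None:
            raise ValueError(f"record {r.sample_id!r} has no H&E label")


def confusion_summary(records: Sequence[SampleRecord]) -> ConfusionSummary:
    """Confusion counts and rates with H&E as truth.

    Screen-positive = {++, +}; condition-positive = label P.
    """
    _check_complete(records)
    tp = fp = tn = fn = 0
    for r in records:
        screen_pos = r.call in (DEFINITE_POS, SUSPECT_POS)
        truth_pos = r.he_label == "P"
        if screen_pos and truth_pos:
            tp += 1
        elif screen_pos and not truth_pos:
            fp += 1
        elif not screen_pos and truth_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
    )


def group_crosstab(records: Sequence[SampleRecord]) -> GroupCrosstab:
    """3x2 count table of (triage call, H&E label)."""
    _check_complete(records)
    counts = {(c, lab): 0 for c in _CALLS for lab in _LABELS}
    for r in records:
        counts[(r.call, r.he_label)] += 1
    return GroupCrosstab(counts=counts)


def write_report_json(path: str | Path, summary: ConfusionSummary, **extra) -> None:
    """Emit the evaluation report (counts, rates, plus caller context)."""
    payload = dict(extra)
    payload["confusion"] = summary.to_dict()
    payload["n_evaluated"] = summary.n
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def write_crosstab_csv(path: str | Path, crosstab: GroupCrosstab) -> None:
    crosstab.to_frame().to_csv(path)
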