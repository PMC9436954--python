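"""Confusion-matrix performance of signal-detection methods.

Methods are judged against the label-derived reference standard:
sensitivity is the share of label-positive (Y) pairs flagged, specificity
the share of label-negative (N) pairs not flagged, and the summary AUROC
is their arithmetic mean (the balanced form appropriate for a single
operating point).  Score-producing methods additionally get a full ROC
curve; its trapezoidal area equals the Mann-Whitney concordance
probability with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PerformanceSummary",
    "confusion",
    "auroc_balanced",
    "roc_points",
    "roc_area",
]


@dataclass(frozen=True)
class PerformanceSummary:
    """One method's confusion counts and derived rates."""

    method: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    auroc_balanced: float
    roc_points: tuple[tuple[float, float], ...] = ()
    universe: str = ""

    @classmethod
    def from_flags(
        cls,
        method: str,
        flags: Mapping[str, bool],
        reference: Mapping[str, str],
        roc: Sequence[tuple[float, float]] = (),
        universe: str = "",
    ) -> "PerformanceSummary":
        tp, fp, tn, fn = confusion(flags, reference)
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return cls(
            method=method, tp=tp, fp=fp, tn=tn, fn=fn,
            sensitivity=sens, specificity=spec,
            auroc_balanced=auroc_balanced(sens, spec),
            roc_points=tuple(roc), universe=universe,
        )


def confusion(
    flags: Mapping[str, bool], reference: Mapping[str, str]
) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) of binary flags against Y/N reference classes.

    Pairs whose reference class is U are excluded; a flagged pair missing
    from the reference entirely is an error.
    """
    tp = fp = tn = fn = 0
    for pair, flag in flags.items():
        cls = reference.get(pair)
        if cls is None:
            raise ValueError(f"pair {pair!r} has no reference class")
        if cls == "U":
            continue
        if cls not in ("Y", "N"):
            raise ValueError(f"reference class {cls!r} for {pair!r} not in Y/N/U")
        if cls == "Y":
            tp, fn = (tp + 1, fn) if flag else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if flag else (fp, tn + 1)
    return tp, fp, tn, fn


def auroc_balanced(sens: float, spec: float) -> float:
    """(sensitivity + specificity) / 2 — the single-threshold AUROC."""
    for name, value in (("sensitivity", sens), ("specificity", spec)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} {value} outside [0, 1]")
    return (sens + spec) / 2.0


def roc_points(
    scores: Mapping[str, float], reference: Mapping[str, str]
) -> list[tuple[float, float]]:
    """ROC curve of a score against the Y/N reference.

    One point per distinct score value (thresholds swept from +inf down),
    with the (0,0) and (1,1) sentinels; monotone nondecreasing in both
    coordinates.  U pairs are excluded; both classes must remain.
    """
    pairs = [p for p in scores if reference.get(p) in ("Y", "N")]
    unknown = [p for p in scores if reference.get(p) is None]
    if unknown:
        raise ValueError(f"pair(s) with no reference class: {unknown[:5]}")
    y = np.array([reference[p] == "Y" for p in pairs])
    s = np.array([scores[p] for p in pairs], dtype=float)
    if y.all() or (~y).all():
        raise ValueError("both classes must be present for a ROC curve")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j])
            fp += int(not y_sorted[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def roc_area(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a ROC polyline."""
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))
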