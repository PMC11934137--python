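"""Univariate yield-threshold classification.

For each descriptor, find the single cut value and direction that best
separates high-yield from low-yield ligands.  A "maximum threshold" predicts
high yield at or below the cut (e.g. a steric length that must stay small); a
"minimum threshold" predicts high yield at or above it (e.g. a stabilizing
interaction energy that must be large enough).

Candidate cuts are the midpoints of consecutive sorted unique feature values,
plus two boundary cuts just outside the observed range representing the
trivial one-class rules; this guarantees the reported accuracy never falls
below the majority-class baseline.  A result is flagged ``degenerate`` when a
boundary cut wins, i.e. no interior threshold beats always-predicting one
class.  Ties are broken toward the widest separating gap, then the smallest
cut value (logged via the stored cut_interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .table import DescriptorTable, resolve_alias

__all__ = [
    "ThresholdResult",
    "binarize_yield",
    "best_threshold",
    "classify_all",
]

HIGH, LOW = 1, 0


@dataclass(frozen=True)
class ThresholdResult:
    feature: str
    cut: float
    direction: str  # 'at_or_below' (maximum threshold) or 'at_or_above' (minimum)
    accuracy: float
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN); positive = high yield
    cut_interval: tuple[float, float]  # open gap the cut lies strictly inside
    degenerate: bool = False  # boundary cut: rule predicts a single class

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError(f"accuracy out of range: {self.accuracy}")
        lo, hi = self.cut_interval
        if not lo < self.cut < hi:
            raise ValueError(f"cut {self.cut} not strictly inside {self.cut_interval}")

    @property
    def n(self) -> int:
        return sum(self.confusion)

    @property
    def kind(self) -> str:
        """The field's wording: maximum vs minimum threshold."""
        return "maximum" if self.direction == "at_or_below" else "minimum"


def binarize_yield(
    table: DescriptorTable, cutoff: float
) -> tuple[np.ndarray, bool]:
    """Labels (1 = high yield, 0 = low) from percent yield at ``cutoff``.

    A row whose yield equals the cutoff is classified high (>= convention).
    Returns ``(labels, degenerate)`` where ``degenerate`` warns that all rows
    landed in one class.
    """
    table.require_complete(["yield_percent"])
    y = table.column("yield_percent")
    labels = np.where(y >= cutoff, HIGH, LOW)
    degenerate = bool(labels.min() == labels.max())
    return labels, degenerate


def _score(values: np.ndarray, labels: np.ndarray, cut: float, direction: str):
    pred_high = values <= cut if direction == "at_or_below" else values >= cut
    tp = int(np.sum(pred_high & (labels == HIGH)))
    fp = int(np.sum(pred_high & (labels == LOW)))
    fn = int(np.sum(~pred_high & (labels == HIGH)))
    tn = int(np.sum(~pred_high & (labels == LOW)))
    return (tp + tn) / len(values), (tp, fp, fn, tn)


def best_threshold(
    values: Sequence[float], labels: Sequence[int], feature: str = ""
) -> ThresholdResult:
    """Max-accuracy single cut over both directions for one feature.

    Selection: highest accuracy, then widest separating gap, then smallest
    cut, then 'at_or_below' before 'at_or_above' -- fully deterministic.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) < 2:
        raise ValueError("need at least 2 rows to place a threshold")
    if len(values) != len(labels):
        raise ValueError("values and labels length mismatch")
    if labels.min() == labels.max():
        raise ValueError(
            "only one yield class present; check the binarize_yield degenerate flag"
        )
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("feature is constant; no threshold can separate classes")

    gaps = np.diff(uniq)
    mean_gap = float(gaps.mean())
    candidates: list[tuple[float, tuple[float, float], float, bool]] = []
    # interior midpoints: (cut, open interval, gap width, degenerate=False)
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        candidates.append(((lo + hi) / 2.0, (float(lo), float(hi)), float(hi - lo), False))
    # boundary cuts = trivial one-class rules, so accuracy >= majority baseline
    candidates.append((float(uniq[0] - mean_gap / 2), (-np.inf, float(uniq[0])), 0.0, True))
    candidates.append((float(uniq[-1] + mean_gap / 2), (float(uniq[-1]), np.inf), 0.0, True))

    best: ThresholdResult | None = None
    best_key: tuple | None = None
    for cut, interval, gap, degenerate in candidates:
        for direction in ("at_or_below", "at_or_above"):
            acc, confusion = _score(values, labels, cut, direction)
            # maximize accuracy, then gap width; prefer non-degenerate; then
            # smaller cut; at_or_below first
            key = (-acc, degenerate, -gap, cut, direction != "at_or_below")
            if best_key is None or key < best_key:
                best_key = key
                best = ThresholdResult(
                    feature=feature,
                    cut=cut,
                    direction=direction,
                    accuracy=acc,
                    confusion=confusion,
                    cut_interval=interval,
                    degenerate=degenerate,
                )
    assert best is not None
    return best


def classify_all(
    table: DescriptorTable,
    features: Sequence[str],
    cutoff: float,
) -> tuple[list[ThresholdResult], list[tuple[str, str]]]:
    """Best single-feature threshold for each feature, by descending accuracy.

    The most accurately classifying feature comes first.  Per-feature
    failures (constant feature, etc.) are collected as ``(feature, reason)``
    entries and do not abort the remaining features.
    """
    labels, degenerate = binarize_yield(table, cutoff)
    if degenerate:
        raise ValueError(
            f"yield cutoff {cutoff} puts every ligand in one class; "
            "classification is degenerate"
        )
    results: list[ThresholdResult] = []
    failures: list[tuple[str, str]] = []
    for feat in features:
        col = resolve_alias(feat, table.df.columns)
        try:
            results.append(best_threshold(table.column(col), labels, feature=col))
        except ValueError as exc:
            failures.append((col, str(exc)))
    results.sort(key=lambda r: (-r.accuracy, r.feature))
    return results, failures
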