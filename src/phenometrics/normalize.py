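"""Rescaling of per-tree observation series to the [0, 1] proportion scale.

Three conventions, one per class of stream:

* ordinal bud scores: ``(score - 1) / (max_stage - 1)``, so a fully dormant
  crown (score 1) maps to 0 and full leaf (stage 5, or 7 for oaks) maps to 1;
* state variables (effective LAI, mean crown NDVI): min-max within the
  tree's own series;
* event streams (caterpillar counts, frass mass): cumulative total up to each
  visit divided by the season total, giving a nondecreasing curve ending at 1.

Exact 0s and 1s are emitted here; the open-interval squeeze needed by the
Beta likelihood is the fitter's concern.  A tree whose season total is zero
has no defined half-fall and comes back flagged, never as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormalizedTrajectory",
    "normalize_bud_scores",
    "normalize_minmax",
    "cumulative_proportion",
]


@dataclass
class NormalizedTrajectory:
    tree_id: str
    metric: str
    days: np.ndarray
    y: np.ndarray
    kind: str  # "state" or "cumulative"
    flag: str = "ok"  # "ok" or "undefined"
    observer_id: np.ndarray | None = None
    notes: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.flag == "ok"

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.flag != "ok":
            return
        if self.days.size != self.y.size:
            raise ValueError("days and y must have equal length")
        if np.any(np.diff(self.days) <= 0):
            order = np.argsort(self.days, kind="stable")
            self.days = self.days[order]
            self.y = self.y[order]
            if self.observer_id is not None:
                self.observer_id = np.asarray(self.observer_id)[order]
            if np.any(np.diff(self.days) <= 0):
                raise ValueError("days must be strictly increasing (duplicate visit days)")


def _undefined(tree_id, metric, kind, reason) -> NormalizedTrajectory:
    return NormalizedTrajectory(
        tree_id, metric, np.array([]), np.array([]), kind,
        flag="undefined", notes=[reason],
    )


def normalize_bud_scores(days, scores, max_stage: int, tree_id: str = "",
                         observer_id=None) -> NormalizedTrajectory:
    """Map (possibly fractional, crown-section-averaged) bud scores in
    [1, max_stage] onto [0, 1]."""
    if max_stage not in (5, 7):
        raise ValueError(f"max_stage must be 5 or 7, got {max_stage}")
    days = np.asarray(days, dtype=float)
    scores = np.asarray(scores, dtype=float)
    bad = (scores < 1.0 - 1e-9) | (scores > max_stage + 1e-9)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"bud score {scores[i]} outside [1, {max_stage}] "
            f"(tree {tree_id or '?'}, day {days[i]:g})"
        )
    y = (scores - 1.0) / (max_stage - 1.0)
    obs = None if observer_id is None else np.asarray(observer_id)
    return NormalizedTrajectory(tree_id, "bud_score", days, np.clip(y, 0.0, 1.0),
                                "state", observer_id=obs)


def normalize_minmax(days, values, metric: str = "lai",
                     tree_id: str = "", winsorize: float | None = None
                     ) -> NormalizedTrajectory:
    """Min-max normalize a state stream within the tree's own series.

    ``winsorize``, if given, clips values to the (q, 1-q) empirical quantiles
    before taking the min and max — a hook for crude outlier damping, off by
    default (outlier screening proper is the caller's job).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size < 3:
        return _undefined(tree_id, metric, "state", "fewer than 3 visits")
    v = values
    if winsorize is not None:
        lo_q, hi_q = np.quantile(values, [winsorize, 1.0 - winsorize])
        v = np.clip(values, lo_q, hi_q)
    vmin, vmax = float(np.min(v)), float(np.max(v))
    if vmax <= vmin:
        return _undefined(tree_id, metric, "state", "flat series (max == min)")
    y = np.clip((v - vmin) / (vmax - vmin), 0.0, 1.0)
    return NormalizedTrajectory(tree_id, metric, days, y, "state")


def cumulative_proportion(days, amounts, metric: str = "count_total",
                          tree_id: str = "") -> NormalizedTrajectory:
    """Cumulative capture divided by the season total.

    The season total is the sum over all visits; a zero total means the tree
    caught nothing and its half-fall is undefined.
    """
    days = np.asarray(days, dtype=float)
    amounts = np.asarray(amounts, dtype=float)
    if np.any(amounts < 0):
        raise ValueError(f"negative amounts in cumulative stream (tree {tree_id or '?'})")
    total = float(np.sum(amounts))
    if total <= 0:
        return _undefined(tree_id, metric, "cumulative", "zero season total")
    y = np.cumsum(amounts) / total
    y[-1] = 1.0  # guard against fp drift in the terminal value
    return NormalizedTrajectory(tree_id, metric, days, np.clip(y, 0.0, 1.0), "cumulative")
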