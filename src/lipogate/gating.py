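"""Declarative gates over feature tables, ordered pipelines, and
threshold-setting utilities.

A *gate* is a selection rule on one feature (threshold / interval) or on a
pair of features (rectangle or polygon region). A *pipeline* applies gates
sequentially to the surviving subset, with full per-stage accounting.
Events with undefined (NaN) features fail gates rather than raising — the
counts of such events are reported per stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

__all__ = [
    "Gate",
    "ThresholdGate",
    "RectGate",
    "RegionGate",
    "Pipeline",
    "GatingResult",
    "evaluate_gate",
    "run_pipeline",
    "cumulative_fraction",
    "threshold_from_negative",
    "calibrate_threshold",
    "ThresholdCalibration",
]


@dataclass(frozen=True)
class ThresholdGate:
    """Pass events whose feature lies in (lo, hi]; either bound optional."""

    name: str
    feature: str
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.lo is None and self.hi is None:
            raise ValueError("threshold gate needs at least one bound")
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValueError("interval bounds must be ordered")

    @property
    def features(self) -> tuple[str, ...]:
        return (self.feature,)

    def __call__(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature].to_numpy(dtype=float)
        ok = np.ones(len(x), dtype=bool)
        if self.lo is not None:
            ok &= x > self.lo
        if self.hi is not None:
            ok &= x <= self.hi
        return ok & np.isfinite(x)


@dataclass(frozen=True)
class RectGate:
    """Axis-aligned rectangle in a feature pair plane."""

    name: str
    x_feature: str
    y_feature: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    inside: bool = True

    def __post_init__(self) -> None:
        if self.x_range[0] > self.x_range[1] or self.y_range[0] > self.y_range[1]:
            raise ValueError("rectangle bounds must be ordered")

    @property
    def features(self) -> tuple[str, ...]:
        return (self.x_feature, self.y_feature)

    def __call__(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.x_feature].to_numpy(dtype=float)
        y = table[self.y_feature].to_numpy(dtype=float)
        defined = np.isfinite(x) & np.isfinite(y)
        hit = (
            (x >= self.x_range[0]) & (x <= self.x_range[1])
            & (y >= self.y_range[0]) & (y <= self.y_range[1])
        )
        return defined & (hit if self.inside else ~hit)


@dataclass(frozen=True)
class RegionGate:
    """Polygonal region(s) in a feature pair plane.

    Membership uses even-odd counting over the polygon list, so disjoint
    lobes and holes both behave correctly. ``inside=False`` inverts the
    gate (exclusion region). An empty polygon tuple is a region matching
    nothing (useful for calibrated rejection regions that turned out
    unnecessary).
    """

    name: str
    x_feature: str
    y_feature: str
    polygons: tuple[tuple[tuple[float, float], ...], ...]
    inside: bool = True

    def __post_init__(self) -> None:
        for poly in self.polygons:
            if len(poly) < 3:
                raise ValueError("polygons need >= 3 vertices")

    @property
    def features(self) -> tuple[str, ...]:
        return (self.x_feature, self.y_feature)

    def __call__(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.x_feature].to_numpy(dtype=float)
        y = table[self.y_feature].to_numpy(dtype=float)
        defined = np.isfinite(x) & np.isfinite(y)
        pts = np.column_stack([np.where(defined, x, 0.0), np.where(defined, y, 0.0)])
        count = np.zeros(len(pts), dtype=int)
        for poly in self.polygons:
            count += MplPath(np.asarray(poly)).contains_points(pts)
        hit = (count % 2) == 1
        return defined & (hit if self.inside else ~hit)


Gate = ThresholdGate | RectGate | RegionGate


def evaluate_gate(table: pd.DataFrame, gate: Gate) -> np.ndarray:
    """Boolean membership per row; rows with undefined features fail."""
    for feat in gate.features:
        if feat not in table.columns:
            raise KeyError(f"gate {gate.name!r} references unknown feature {feat!r}")
    if len(table) == 0:
        return np.zeros(0, dtype=bool)
    return gate(table)


def _undefined_rows(table: pd.DataFrame, gate: Gate) -> np.ndarray:
    if len(table) == 0:
        return np.zeros(0, dtype=bool)
    und = np.zeros(len(table), dtype=bool)
    for feat in gate.features:
        und |= ~np.isfinite(table[feat].to_numpy(dtype=float))
    return und


@dataclass(frozen=True)
class Pipeline:
    """Ordered, named gates applied sequentially to the surviving subset."""

    name: str
    stages: tuple[tuple[str, Gate], ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("pipeline must have at least one stage")
        names = [s for s, _ in self.stages]
        if len(set(names)) != len(names):
            raise ValueError("stage names must be unique")


@dataclass
class GatingResult:
    """Per-stage accounting and per-event membership of one pipeline run."""

    pipeline: str
    stage_counts: pd.DataFrame  # index: stage; columns: entering, passing, undefined, fraction
    membership: pd.DataFrame    # index: event_id; one boolean column per stage
    final_mask: pd.Series       # True for events surviving all stages

    @property
    def final_fraction(self) -> float:
        n = len(self.final_mask)
        return float(self.final_mask.sum() / n) if n else 0.0

    def stage_report(self) -> dict:
        return {
            "pipeline": self.pipeline,
            "n_input": int(len(self.final_mask)),
            "n_final": int(self.final_mask.sum()),
            "stages": [
                {
                    "stage": idx,
                    "entering": int(row.entering),
                    "passing": int(row.passing),
                    "undefined": int(row.undefined),
                    "fraction": float(row.fraction),
                }
                for idx, row in self.stage_counts.iterrows()
            ],
        }


def run_pipeline(table: pd.DataFrame, pipeline: Pipeline) -> GatingResult:
    """Apply the pipeline stages in order with full accounting.

    At every stage ``passing + failing + undefined = entering``; the stage-k
    input is exactly the stage-(k-1) output.
    """
    alive = np.ones(len(table), dtype=bool)
    counts = []
    membership = {}
    for stage_name, gate in pipeline.stages:
        entering = int(alive.sum())
        flags = evaluate_gate(table, gate)
        und = _undefined_rows(table, gate) & alive
        passing = flags & alive
        counts.append(
            {
                "stage": stage_name,
                "entering": entering,
                "passing": int(passing.sum()),
                "undefined": int(und.sum()),
                "fraction": float(passing.sum() / entering) if entering else 0.0,
            }
        )
        membership[stage_name] = passing
        alive = passing
    stage_counts = pd.DataFrame(counts).set_index("stage")
    member_df = pd.DataFrame(membership, index=table.index)
    final = pd.Series(alive, index=table.index, name="final")
    return GatingResult(
        pipeline=pipeline.name,
        stage_counts=stage_counts,
        membership=member_df,
        final_mask=final,
    )


def cumulative_fraction(stage_fractions) -> float:
    """Product of per-stage pass fractions (empty product = 1)."""
    out = 1.0
    for f in stage_fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
        out *= f
    return out


def threshold_from_negative(negative_values, max_fpr: float) -> float:
    """Positivity cut-off from a negative-control sample.

    Returns the smallest observed negative value t such that the fraction
    of negative values strictly above t is at most ``max_fpr`` — the
    (1 - max_fpr) empirical quantile, with the guarantee holding for any
    sample size.
    """
    vals = np.asarray(list(negative_values), dtype=float)
    if vals.size == 0:
        raise ValueError("negative sample must be nonempty")
    if not 0.0 < max_fpr < 1.0:
        raise ValueError("max_fpr must be in (0, 1)")
    vals = np.sort(vals)
    n = vals.size
    k = int(np.floor(max_fpr * n))  # how many values may sit above the cut
    return float(vals[n - 1 - k])


@dataclass(frozen=True)
class ThresholdCalibration:
    """A calibrated 1D cut: pass when feature is above (or below) threshold."""

    feature: str
    threshold: float
    positive_above: bool
    balanced_accuracy: float

    def to_gate(self, name: str) -> ThresholdGate:
        if self.positive_above:
            return ThresholdGate(name=name, feature=self.feature, lo=self.threshold)
        return ThresholdGate(name=name, feature=self.feature, hi=self.threshold)


def calibrate_threshold(
    table: pd.DataFrame,
    truth: pd.Series | np.ndarray,
    feature: str,
    positive_class,
    *,
    min_positive_recall: float | None = None,
) -> ThresholdCalibration:
    """Threshold on one feature maximizing balanced accuracy between
    ``positive_class`` and the rest.

    Both classes must be present; NaN feature values are excluded from the
    calibration (they fail gates downstream anyway). When
    ``min_positive_recall`` is given, only cuts retaining at least that
    fraction of the positive class are considered (used by screening
    stages that must not consume the population of interest); if no cut
    satisfies the floor the constraint is dropped.
    """
    y = np.asarray(truth) == positive_class
    x = table[feature].to_numpy(dtype=float)
    keep = np.isfinite(x)
    x, y = x[keep], y[keep]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for calibration")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # candidate cuts between consecutive distinct values
    pos_below = np.cumsum(ys)          # positives with value <= xs[i]
    neg_below = np.cumsum(~ys)
    distinct = np.nonzero(np.diff(xs) > 0)[0]
    if distinct.size == 0:
        raise ValueError("feature is constant; cannot calibrate")
    cuts = (xs[distinct] + xs[distinct + 1]) / 2
    tpr_above = (n_pos - pos_below[distinct]) / n_pos
    tnr_above = neg_below[distinct] / n_neg
    tpr_below = pos_below[distinct] / n_pos
    ba_above = (tpr_above + tnr_above) / 2          # positive class above cut
    ba_below = (tpr_below + (n_neg - neg_below[distinct]) / n_neg) / 2

    def _best(ba, tpr):
        if min_positive_recall is not None:
            ok = tpr >= min_positive_recall
            if ok.any():
                masked = np.where(ok, ba, -np.inf)
                i = int(np.argmax(masked))
                return i, float(ba[i])
        i = int(np.argmax(ba))
        return i, float(ba[i])

    i_above, score_above = _best(ba_above, tpr_above)
    i_below, score_below = _best(ba_below, tpr_below)
    if score_above >= score_below:
        return ThresholdCalibration(
            feature=feature,
            threshold=float(cuts[i_above]),
            positive_above=True,
            balanced_accuracy=score_above,
        )
    return ThresholdCalibration(
        feature=feature,
        threshold=float(cuts[i_below]),
        positive_above=False,
        balanced_accuracy=score_below,
    )
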