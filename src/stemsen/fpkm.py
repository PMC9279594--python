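"""FPKM time-series preprocessing and monotone-trend selection.

The input is an expression matrix of FPKM values for genes or isoforms
measured in several independent cultures at a small number of passages
(time-points). The preprocessing applies, in order:

1. removal of features flagged ``fail`` by the quantification step;
2. removal of lowly expressed features — a feature is dropped globally when,
   in at least one culture, the FPKM sum across time-points is below a
   threshold (default 5) or the first time-point is below a threshold
   (default 1), both strict;
3. flagging of housekeeping-gene anomalies — time-points where the
   housekeeping series deviates from its median by more than a fold limit
   are excluded from trend classification for that culture;
4. normalization of every series by the housekeeping gene at the matching
   time-point;
5. normalization by the first time-point, so every series starts at 1;
6. the log2 of the baseline-normalized series ("log2 evolution", starting
   at 0).

A feature is then called "up" in a culture when every consecutive log2 step
exceeds ``min_step`` (strictly), "down" when every step is below
``-min_step``, otherwise "none"; a cross-culture consensus requires the same
non-none direction in every required culture. The coefficient of variation
(sample SD over mean) of the raw series is reported as a quality metric but
is not used as a filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "NormalizedSeries",
    "TrendCall",
    "FilterReport",
    "PipelineConfig",
    "PipelineResult",
    "filter_failed",
    "filter_low_expression",
    "flag_housekeeping_anomaly",
    "normalize_housekeeping",
    "normalize_baseline",
    "coefficient_of_variation",
    "log2_evolution",
    "classify_trend",
    "consensus_across_cultures",
    "run_pipeline",
]

STATUS_OK = "ok"
STATUS_FAIL = "fail"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Long-form FPKM matrix: one row per (feature, culture), time-points as columns.

    ``data`` columns: ``feature_id``, ``culture_id``, ``status`` (ok|fail),
    then ``t0 .. tK``. FPKM values are non-negative; every culture carries
    the same time-points.
    """

    data: pd.DataFrame
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        required = {"feature_id", "culture_id", "status"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"expression matrix is missing columns: {sorted(missing)}")
        tcols = self.time_columns
        if len(tcols) < 2:
            raise ValueError("expression matrix needs at least 2 time-point columns (t0, t1, ...)")
        vals = self.data[tcols].to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("FPKM values must be non-negative")
        dup = self.data.duplicated(subset=["feature_id", "culture_id"])
        if dup.any():
            raise ValueError("duplicate (feature_id, culture_id) rows")

    @property
    def time_columns(self) -> list[str]:
        cols = [c for c in self.data.columns if c.startswith("t") and c[1:].isdigit()]
        return sorted(cols, key=lambda c: int(c[1:]))

    @property
    def n_timepoints(self) -> int:
        return len(self.time_columns)

    @property
    def features(self) -> list[str]:
        return list(dict.fromkeys(self.data["feature_id"]))

    @property
    def cultures(self) -> list[str]:
        return list(dict.fromkeys(self.data["culture_id"]))

    def series(self, feature_id: str, culture_id: str) -> np.ndarray:
        sel = self.data[
            (self.data["feature_id"] == feature_id)
            & (self.data["culture_id"] == culture_id)
        ]
        if sel.empty:
            raise KeyError(f"no series for feature {feature_id!r} in culture {culture_id!r}")
        return sel[self.time_columns].to_numpy(dtype=float)[0]

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = set(feature_ids)
        return ExpressionMatrix(
            self.data[self.data["feature_id"].isin(keep)].reset_index(drop=True),
            self.feature_kind,
        )


@dataclass(frozen=True)
class NormalizedSeries:
    """One feature in one culture after housekeeping and baseline normalization."""

    feature_id: str
    culture_id: str
    hk_normalized: tuple[float, ...]
    baseline_normalized: tuple[float, ...]
    log2_evolution: tuple[float, ...]


@dataclass(frozen=True)
class TrendCall:
    feature_id: str
    per_culture: Mapping[str, str]
    consensus: str
    min_abs_log2_step: float


@dataclass
class FilterReport:
    """Accounting of the ordered filters: every input feature is counted once."""

    n_input: int = 0
    n_removed_fail: int = 0
    n_removed_low: int = 0
    n_kept: int = 0
    removed_fail: list[str] = field(default_factory=list)
    removed_low: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.n_input != self.n_removed_fail + self.n_removed_low + self.n_kept:
            raise AssertionError("filter report counts do not conserve features")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_fail": self.n_removed_fail,
            "n_removed_low": self.n_removed_low,
            "n_kept": self.n_kept,
            "removed_fail": sorted(self.removed_fail),
            "removed_low": sorted(self.removed_low),
        }


@dataclass(frozen=True)
class PipelineConfig:
    housekeeping_id: str = "GAPDH"
    sum_threshold: float = 5.0
    initial_threshold: float = 1.0
    min_step: float = 0.0
    fold_limit: float = 3.0
    required_cultures: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.sum_threshold < 0 or self.initial_threshold < 0:
            raise ValueError("expression thresholds must be non-negative")
        if self.min_step < 0:
            raise ValueError("min_step must be non-negative")
        if self.fold_limit <= 1 and math.isfinite(self.fold_limit):
            raise ValueError("fold_limit must exceed 1")


@dataclass
class PipelineResult:
    trend_calls: pd.DataFrame
    report: FilterReport
    series: dict[tuple[str, str], NormalizedSeries]
    flagged_timepoints: dict[str, list[int]]
    cv_table: pd.DataFrame
    excluded: dict[str, str]


def filter_failed(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop every feature whose status is ``fail`` in any culture."""
    report = FilterReport(n_input=len(matrix.features))
    failed = set(matrix.data.loc[matrix.data["status"] == STATUS_FAIL, "feature_id"])
    kept = [f for f in matrix.features if f not in failed]
    report.removed_fail = sorted(failed)
    report.n_removed_fail = len(failed)
    report.n_kept = len(kept)
    report.check()
    return matrix.subset(kept), report


def filter_low_expression(
    matrix: ExpressionMatrix,
    sum_threshold: float = 5.0,
    initial_threshold: float = 1.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop features not expressed in a meaningful way in at least one culture.

    A feature fails in a culture when ``sum(series) < sum_threshold`` or
    ``series[0] < initial_threshold`` (strict inequalities: boundary values
    are kept); one failing culture removes the feature everywhere.
    """
    if sum_threshold < 0 or initial_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    report = FilterReport(n_input=len(matrix.features))
    tcols = matrix.time_columns
    vals = matrix.data[tcols].to_numpy(dtype=float)
    low_mask = (vals.sum(axis=1) < sum_threshold) | (vals[:, 0] < initial_threshold)
    low = set(matrix.data.loc[low_mask, "feature_id"])
    kept = [f for f in matrix.features if f not in low]
    report.removed_low = sorted(low)
    report.n_removed_low = len(low)
    report.n_kept = len(kept)
    report.check()
    return matrix.subset(kept), report


def flag_housekeeping_anomaly(
    matrix: ExpressionMatrix,
    housekeeping_id: str,
    fold_limit: float = 3.0,
) -> dict[str, list[int]]:
    """Flag time-points where the housekeeping series departs from its median.

    A time-point is flagged for a culture when the housekeeping FPKM there
    differs from the median of that culture's housekeeping series by more
    than ``fold_limit`` in either direction. Flagged time-points are later
    excluded from trend classification for that culture.
    """
    flagged: dict[str, list[int]] = {}
    for culture in matrix.cultures:
        try:
            hk = matrix.series(housekeeping_id, culture)
        except KeyError:
            raise KeyError(
                f"housekeeping feature {housekeeping_id!r} missing in culture {culture!r}"
            ) from None
        med = float(np.median(hk))
        bad: list[int] = []
        for t, v in enumerate(hk):
            if med <= 0:
                if v > 0 and math.isfinite(fold_limit):
                    bad.append(t)
                continue
            if v == 0:
                if math.isfinite(fold_limit):
                    bad.append(t)
                continue
            ratio = v / med
            if ratio > fold_limit or 1.0 / ratio > fold_limit:
                bad.append(t)
        flagged[culture] = bad
    return flagged


def normalize_housekeeping(
    series: np.ndarray | Sequence[float], housekeeping: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Divide a series by the housekeeping series at matching time-points."""
    s = np.asarray(series, dtype=float)
    hk = np.asarray(housekeeping, dtype=float)
    if s.shape != hk.shape:
        raise ValueError("series and housekeeping series differ in length")
    zero = np.nonzero(hk <= 0)[0]
    if zero.size:
        raise ValueError(
            f"housekeeping FPKM is zero or negative at time-point t{zero[0]}"
        )
    return s / hk


def normalize_baseline(series: np.ndarray | Sequence[float]) -> np.ndarray:
    """Divide a series by its first value so it starts at exactly 1."""
    s = np.asarray(series, dtype=float)
    if s[0] <= 0:
        raise ValueError("first time-point is not positive; baseline normalization undefined")
    out = s / s[0]
    out[0] = 1.0
    return out


def coefficient_of_variation(series: np.ndarray | Sequence[float]) -> float:
    """Sample coefficient of variation: SD (n-1 denominator) over mean.

    Returns NaN for a zero mean, where the CV is undefined.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ValueError("CV requires at least 2 observations")
    mean = float(s.mean())
    if mean == 0:
        return math.nan
    return float(s.std(ddof=1)) / mean


def log2_evolution(baseline_normalized: np.ndarray | Sequence[float]) -> np.ndarray:
    """Element-wise log2 of a baseline-normalized series; starts at exactly 0."""
    s = np.asarray(baseline_normalized, dtype=float)
    if np.any(s <= 0):
        raise ValueError("log2 evolution undefined for non-positive values")
    out = np.log2(s)
    out[0] = 0.0
    return out


def classify_trend(
    log2_series: np.ndarray | Sequence[float],
    min_step: float = 0.0,
    exclude: Sequence[int] = (),
) -> str:
    """Call a series up, down or none by its consecutive log2 steps.

    ``up`` when every consecutive difference exceeds ``min_step`` strictly,
    ``down`` when every difference is below ``-min_step``; anything else is
    ``none``. Indices in ``exclude`` (e.g. housekeeping-anomaly time-points)
    are dropped before differencing; fewer than 2 remaining points yield
    ``none``.
    """
    s = np.asarray(log2_series, dtype=float)
    keep = [i for i in range(s.size) if i not in set(exclude)]
    if len(keep) < 2:
        return "none"
    diffs = np.diff(s[keep])
    if np.all(diffs > min_step):
        return "up"
    if np.all(diffs < -min_step):
        return "down"
    return "none"


def consensus_across_cultures(
    calls: Mapping[str, str], required: Sequence[str]
) -> str:
    """Shared non-none direction across all required cultures, else none."""
    missing = [c for c in required if c not in calls]
    if missing:
        raise KeyError(f"missing trend calls for cultures: {missing}")
    directions = {calls[c] for c in required}
    if len(directions) == 1 and directions != {"none"}:
        return directions.pop()
    return "none"


def run_pipeline(matrix: ExpressionMatrix, config: PipelineConfig) -> PipelineResult:
    """Run the ordered preprocessing and trend-selection pipeline.

    Filters, anomaly flagging, both normalizations, log2 evolution,
    per-culture classification and cross-culture consensus, with full count
    accounting. Deterministic: the same matrix and config always produce the
    same result.
    """
    cultures = matrix.cultures
    required = list(config.required_cultures) if config.required_cultures else cultures

    m1, rep_fail = filter_failed(matrix)
    m2, rep_low = filter_low_expression(
        m1, config.sum_threshold, config.initial_threshold
    )
    report = FilterReport(
        n_input=rep_fail.n_input,
        n_removed_fail=rep_fail.n_removed_fail,
        n_removed_low=rep_low.n_removed_low,
        n_kept=rep_low.n_kept,
        removed_fail=rep_fail.removed_fail,
        removed_low=rep_low.removed_low,
    )
    report.check()

    if not m2.features:
        empty_calls = pd.DataFrame(columns=["feature_id", *cultures, "consensus"])
        empty_cv = pd.DataFrame(columns=["feature_id", "culture_id", "cv"])
        return PipelineResult(empty_calls, report, {}, {}, empty_cv, {})

    flagged = flag_housekeeping_anomaly(m2, config.housekeeping_id, config.fold_limit)

    hk_by_culture = {c: m2.series(config.housekeeping_id, c) for c in cultures}
    store: dict[tuple[str, str], NormalizedSeries] = {}
    excluded: dict[str, str] = {}
    cv_rows = []
    per_feature_calls: dict[str, dict[str, str]] = {}

    tcols = m2.time_columns
    for _, row in m2.data.iterrows():
        fid, cid = row["feature_id"], row["culture_id"]
        raw = row[tcols].to_numpy(dtype=float)
        cv_rows.append({"feature_id": fid, "culture_id": cid, "cv": coefficient_of_variation(raw)})
        if fid in excluded:
            continue
        hk_norm = normalize_housekeeping(raw, hk_by_culture[cid])
        try:
            base = normalize_baseline(hk_norm)
            logev = log2_evolution(base)
        except ValueError as exc:
            excluded[fid] = str(exc)
            per_feature_calls.pop(fid, None)
            continue
        store[(fid, cid)] = NormalizedSeries(
            fid, cid, tuple(hk_norm), tuple(base), tuple(logev)
        )
        call = classify_trend(logev, config.min_step, flagged.get(cid, ()))
        per_feature_calls.setdefault(fid, {})[cid] = call

    call_rows = []
    for fid in m2.features:
        if fid in excluded or fid not in per_feature_calls:
            continue
        calls = per_feature_calls[fid]
        if any(c not in calls for c in required):
            excluded[fid] = "missing culture series"
            continue
        consensus = consensus_across_cultures(calls, required)
        call_rows.append({"feature_id": fid, **calls, "consensus": consensus})

    trend_calls = pd.DataFrame(call_rows, columns=["feature_id", *cultures, "consensus"])
    cv_table = pd.DataFrame(cv_rows, columns=["feature_id", "culture_id", "cv"])
    return PipelineResult(trend_calls, report, store, flagged, cv_table, excluded)
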