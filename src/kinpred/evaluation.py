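"""Prediction quality metrics and diagnostic reports.

All metrics operate on log10-scale values: the coefficient of determination
R², the Pearson correlation coefficient (PCC), root-mean-square error (RMSE),
and mean absolute error (MAE). Diagnostics include interval-stratified
errors, the high-value subsets above 4 and 5 log10 units, min–max
normalisation of projected coordinates, and a geometric-mean leakage
baseline: predicting each test sample by the geometric mean of the raw
training values sharing its enzyme (or substrate), which quantifies how far
a model's accuracy could come from memorised entities alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .datasets import KineticsRecord


def _validate_pair(y_true, y_pred, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if y_true.size != y_pred.size:
        raise ValueError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if y_true.size < min_n:
        raise ValueError(f"need at least {min_n} samples")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValueError("inputs contain non-finite values")
    return y_true, y_pred


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination, 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)²."""
    y_true, y_pred = _validate_pair(y_true, y_pred, min_n=2)
    if np.allclose(y_true, y_true[0]):
        raise ValueError("R² is undefined for constant observed values")
    return float(_skm.r2_score(y_true, y_pred))


def pcc(y_true, y_pred) -> float:
    """Pearson product-moment correlation coefficient."""
    y_true, y_pred = _validate_pair(y_true, y_pred, min_n=2)
    if np.allclose(y_true, y_true[0]) or np.allclose(y_pred, y_pred[0]):
        raise ValueError("PCC is undefined for constant input")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error."""
    y_true, y_pred = _validate_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def mae(y_true, y_pred) -> float:
    """Mean absolute error."""
    y_true, y_pred = _validate_pair(y_true, y_pred)
    return float(_skm.mean_absolute_error(y_true, y_pred))


@dataclass(frozen=True)
class MetricReport:
    """R²/PCC/RMSE/MAE for one prediction set (log10 units)."""

    r2: float
    pcc: float
    rmse: float
    mae: float
    n: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "pcc": self.pcc, "rmse": self.rmse, "mae": self.mae, "n": self.n}


def metric_report(y_true, y_pred) -> MetricReport:
    y_true, y_pred = _validate_pair(y_true, y_pred, min_n=2)
    return MetricReport(
        r2_score(y_true, y_pred),
        pcc(y_true, y_pred),
        rmse(y_true, y_pred),
        mae(y_true, y_pred),
        int(y_true.size),
    )


@dataclass(frozen=True)
class IntervalErrors:
    """Errors within one experimental-label interval; None when empty."""

    lower: float
    upper: float
    n: int
    rmse: float | None
    mae: float | None


@dataclass(frozen=True)
class IntervalReport:
    """Interval-stratified errors plus high-value subset summaries.

    High-value subsets select by the *experimental* label (> 4 and > 5 log10
    units by default), matching how high-turnover samples are counted.
    """

    intervals: tuple
    high_value: dict
    n: int


def interval_report(
    y_true,
    y_pred,
    edges: Sequence[float] | None = None,
    thresholds: Sequence[float] = (4.0, 5.0),
) -> IntervalReport:
    """Stratify errors by experimental-label intervals and high-value subsets.

    ``edges`` are sorted interval boundaries; the default covers the label
    range with unit-width integer bins. Intervals are right-open except the
    last, which includes the maximum.
    """
    y_true, y_pred = _validate_pair(y_true, y_pred)
    if edges is None:
        edges = np.arange(math.floor(y_true.min()), math.ceil(y_true.max()) + 1.0)
        if edges.size < 2:
            edges = np.array([y_true.min(), y_true.min() + 1.0])
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be sorted and define at least one interval")

    intervals = []
    for i in range(edges.size - 1):
        lower, upper = edges[i], edges[i + 1]
        if i == edges.size - 2:
            mask = (y_true >= lower) & (y_true <= upper)
        else:
            mask = (y_true >= lower) & (y_true < upper)
        n_i = int(mask.sum())
        intervals.append(
            IntervalErrors(
                float(lower),
                float(upper),
                n_i,
                rmse(y_true[mask], y_pred[mask]) if n_i else None,
                mae(y_true[mask], y_pred[mask]) if n_i else None,
            )
        )

    high_value = {}
    for thr in thresholds:
        mask = y_true > thr
        n_t = int(mask.sum())
        high_value[float(thr)] = IntervalErrors(
            float(thr),
            float("inf"),
            n_t,
            rmse(y_true[mask], y_pred[mask]) if n_t else None,
            mae(y_true[mask], y_pred[mask]) if n_t else None,
        )
    return IntervalReport(tuple(intervals), high_value, int(y_true.size))


def minmax_normalize(values) -> np.ndarray:
    """Scale values linearly onto [0, 1]: (v − min)/(max − min)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = values.min(), values.max()
    if hi <= lo:
        raise ValueError("min–max normalisation is undefined for constant input")
    return (values - lo) / (hi - lo)


def gmean_baseline(
    train_records: Sequence[KineticsRecord],
    test_records: Sequence[KineticsRecord],
    grouping: str = "enzyme",
) -> np.ndarray:
    """Leakage baseline: per-group geometric mean of raw training values.

    Each test sample is predicted by log10 of the geometric mean of the raw
    training values sharing its enzyme sequence (or substrate SMILES, with
    ``grouping="substrate"``); unseen keys fall back to the global geometric
    mean. In log space this is the arithmetic mean of the log10 training
    values per group.
    """
    if grouping not in {"enzyme", "substrate"}:
        raise ValueError("grouping must be 'enzyme' or 'substrate'")
    if not train_records:
        raise ValueError("training set must be nonempty")

    def key(rec: KineticsRecord) -> str:
        return rec.enzyme_sequence if grouping == "enzyme" else rec.substrate_smiles

    logs: dict[str, list[float]] = {}
    all_logs = []
    for rec in train_records:
        if rec.raw_value is None or rec.raw_value <= 0:
            raise ValueError("training records must carry positive raw values")
        lv = math.log10(rec.raw_value)
        logs.setdefault(key(rec), []).append(lv)
        all_logs.append(lv)
    group_mean = {k: float(np.mean(v)) for k, v in logs.items()}
    global_mean = float(np.mean(all_logs))
    return np.array([group_mean.get(key(rec), global_mean) for rec in test_records])
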