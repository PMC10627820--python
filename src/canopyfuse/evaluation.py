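"""Accuracy and uncertainty-calibration metrics.

Point metrics over N prediction/reference pairs:

    RMSE = sqrt(mean (yhat - y)^2)        MAE = mean |yhat - y|
    ME   = mean (yhat - y)                NME = 100 * ME / ybar   [%]

Balanced variants (aRMSE, aMAE, aME) compute the metric separately in
each 5-m reference-height interval and average unweighted over the
nonempty intervals, so rare tall canopies count as much as abundant low
vegetation.

Calibration compares binned empirical error against binned predicted
uncertainty: samples are sorted by predicted variance u into K
equal-count bins B_k; err(B_k) is the RMSE within the bin and
uncert(B_k) the root mean variance RMV = sqrt(mean_{i in B_k} u_i);

    UCE  = sum_k (N_k / N) |err(B_k) - uncert(B_k)|
    AUCE = (1/K) sum_k     |err(B_k) - uncert(B_k)|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "CalibrationResult",
    "point_metrics",
    "balanced_metrics",
    "calibration",
    "filter_by_uncertainty",
]

# floor (m) for predicted height in the relative-uncertainty filter;
# avoids division by near-zero predictions over bare ground
RELATIVE_FILTER_EPS = 0.1


@dataclass
class MetricsReport:
    """Point metrics, optionally with height-balanced counterparts."""

    rmse: float
    mae: float
    me: float
    nme: float            # percent; NaN when the reference mean is 0
    n: int
    armse: float = np.nan
    amae: float = np.nan
    ame: float = np.nan
    interval_table: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"rmse": self.rmse, "mae": self.mae, "me": self.me,
                "nme_percent": self.nme, "n": self.n}
        if np.isfinite(self.armse):
            cols.update(armse=self.armse, amae=self.amae, ame=self.ame)
        return pd.DataFrame([cols])


def _check_pair(pred, ref):
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    if pred.size == 0:
        raise ValueError("empty input")
    return pred, ref


def point_metrics(pred, ref) -> MetricsReport:
    """RMSE, MAE, ME and NME (in percent) over all pairs."""
    pred, ref = _check_pair(pred, ref)
    d = pred - ref
    me = float(d.mean())
    ybar = ref.mean()
    nme = float(100.0 * me / ybar) if ybar != 0 else np.nan
    return MetricsReport(rmse=float(np.sqrt(np.mean(d ** 2))),
                         mae=float(np.mean(np.abs(d))),
                         me=me, nme=nme, n=pred.size)


def balanced_metrics(pred, ref, interval: float = 5.0) -> MetricsReport:
    """Point metrics plus per-interval table and unweighted interval averages.

    Intervals are half-open [k*interval, (k+1)*interval) on the reference
    heights; empty intervals are skipped, not imputed.
    """
    pred, ref = _check_pair(pred, ref)
    base = point_metrics(pred, ref)
    idx = np.floor(ref / interval).astype(int)
    rows = []
    for k in np.unique(idx):
        sel = idx == k
        m = point_metrics(pred[sel], ref[sel])
        rows.append({"interval_low": k * interval,
                     "interval_high": (k + 1) * interval,
                     "n": int(sel.sum()), "rmse": m.rmse, "mae": m.mae,
                     "me": m.me})
    table = pd.DataFrame(rows)
    return MetricsReport(rmse=base.rmse, mae=base.mae, me=base.me, nme=base.nme,
                         n=base.n, armse=float(table["rmse"].mean()),
                         amae=float(table["mae"].mean()),
                         ame=float(table["me"].mean()), interval_table=table)


@dataclass
class CalibrationResult:
    """Equal-count calibration bins plus the scalar summaries."""

    bins: pd.DataFrame     # columns: bin, n, err_rmse, uncert_rmv
    uce: float
    auce: float

    def to_frame(self) -> pd.DataFrame:
        return self.bins


def calibration(pred, uncert, ref, n_bins: int = 10) -> CalibrationResult:
    """Bin samples by predicted variance and compare RMSE against RMV.

    ``uncert`` is the predicted *variance* per sample (sigma^2 for a
    single network, Var(yhat) for the fused ensemble). Samples are sorted
    by ``uncert`` (stable, ties broken by sample index) into ``n_bins``
    equal-count bins; remainder samples join the last bin.
    """
    pred, ref = _check_pair(pred, ref)
    uncert = np.asarray(uncert, dtype=float).ravel()
    if uncert.shape != pred.shape:
        raise ValueError("uncert must match pred length")
    if np.any(uncert < 0):
        raise ValueError("predicted variances must be >= 0")
    if n_bins < 1 or n_bins > pred.size:
        raise ValueError("need 1 <= n_bins <= n samples")
    order = np.argsort(uncert, kind="stable")
    n = pred.size
    per = n // n_bins
    rows = []
    for k in range(n_bins):
        lo = k * per
        hi = (k + 1) * per if k < n_bins - 1 else n
        sel = order[lo:hi]
        d = pred[sel] - ref[sel]
        rows.append({"bin": k, "n": sel.size,
                     "err_rmse": float(np.sqrt(np.mean(d ** 2))),
                     "uncert_rmv": float(np.sqrt(np.mean(uncert[sel])))})
    table = pd.DataFrame(rows)
    gap = np.abs(table["err_rmse"] - table["uncert_rmv"])
    uce = float((table["n"] / n * gap).sum())
    auce = float(gap.mean())
    return CalibrationResult(bins=table, uce=uce, auce=auce)


def filter_by_uncertainty(pred, uncert, fraction: float,
                          mode: str = "fixed-fraction") -> np.ndarray:
    """Boolean mask of retained samples after dropping the most uncertain.

    ``fixed-fraction`` drops the top ``fraction`` by predicted variance.
    ``adaptive-relative`` drops the top ``fraction`` by relative standard
    deviation sqrt(u) / max(yhat, eps), an adaptive threshold in predicted
    height that preserves the full height range (tall canopies have large
    absolute but small relative uncertainty).
    """
    pred = np.asarray(pred, dtype=float).ravel()
    uncert = np.asarray(uncert, dtype=float).ravel()
    if pred.shape != uncert.shape:
        raise ValueError("pred and uncert must share length")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = pred.size
    n_drop = int(np.floor(fraction * n + 1e-9))
    if n_drop == 0:
        return np.ones(n, dtype=bool)
    if mode == "fixed-fraction":
        score = uncert
    elif mode == "adaptive-relative":
        score = np.sqrt(uncert) / np.maximum(pred, RELATIVE_FILTER_EPS)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    order = np.argsort(score, kind="stable")
    keep = np.ones(n, dtype=bool)
    keep[order[n - n_drop:]] = False
    return keep
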