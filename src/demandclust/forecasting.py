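"""Croston and Syntetos–Boylan-approximation (SBA) intermittent forecasters.

Croston's method maintains two exponentially smoothed states, updated only
on demand periods: the nonzero demand size ``z_hat`` and the inter-demand
interval ``p_hat``.  The per-period forecast is ``z_hat / p_hat``, held
constant between demands.  SBA multiplies the Croston forecast by
``1 - alpha/2`` to correct Croston's positive bias; the correction matters
most when demand sizes are volatile, which is why SBA tends to win on
erratic/lumpy demand and the method comparison is a useful check on a
pattern classification.

Conventions (the classic choices):

* ``z_hat`` initialises to the first nonzero size, ``p_hat`` to the first
  inter-demand interval; both are smoothed from the second demand onward.
* The forecast for period ``t`` uses the state after the last demand
  strictly before ``t``; forecasts are undefined (NaN) up to and including
  the second demand period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import DemandSeries

__all__ = [
    "ForecastResult",
    "compare_methods",
    "croston",
    "sba",
]

DEFAULT_ALPHAS = (0.05, 0.1, 0.15, 0.2)


@dataclass(frozen=True)
class ForecastResult:
    """One-step-ahead forecasts and the accuracy of a forecaster on a series."""

    series_id: str
    method: str
    alpha: float
    forecasts: np.ndarray = field(repr=False)  # NaN where undefined
    z_hat: float = float("nan")  # final smoothed size
    p_hat: float = float("nan")  # final smoothed interval

    def metrics(self, actual: np.ndarray, train_mean: float | None = None) -> dict:
        """MAE / RMSE over defined periods, plus MAE scaled by a naive-mean MAE."""
        mask = ~np.isnan(self.forecasts)
        if not mask.any():
            return {"mae": np.nan, "rmse": np.nan, "smae": np.nan}
        err = self.forecasts[mask] - actual[mask]
        mae = float(np.abs(err).mean())
        rmse = float(np.sqrt((err**2).mean()))
        if train_mean is None:
            train_mean = float(actual.mean())
        naive_mae = float(np.abs(actual[mask] - train_mean).mean())
        smae = mae / naive_mae if naive_mae > 0 else np.nan
        return {"mae": mae, "rmse": rmse, "smae": smae}


def _croston_states(counts: np.ndarray, alpha: float) -> np.ndarray:
    """Per-period Croston forecast z_hat/p_hat; NaN before the state exists."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    nz = np.flatnonzero(counts)
    if nz.size < 2:
        raise ValueError("need at least 2 nonzero demands")
    f = np.full(counts.size, np.nan)
    z_hat = float(counts[nz[0]])
    p_hat = float(nz[1] - nz[0])
    prev = nz[0]
    for t in nz[1:]:
        interval = float(t - prev)
        p_hat = alpha * interval + (1.0 - alpha) * p_hat
        z_hat = alpha * float(counts[t]) + (1.0 - alpha) * z_hat
        prev = t
        # state after the demand at t applies from period t+1 onward,
        # until (and including) the next demand period
        f[t + 1 :] = z_hat / p_hat
    return f


def croston(series: DemandSeries, alpha: float) -> ForecastResult:
    """Croston's method: smoothed nonzero size over smoothed interval."""
    f = _croston_states(series.counts.astype(float), alpha)
    nz = series.nonzero_days()
    z, p = _final_state(series.counts, alpha, nz)
    return ForecastResult(
        series_id=series.series_id, method="croston", alpha=alpha,
        forecasts=f, z_hat=z, p_hat=p,
    )


def sba(series: DemandSeries, alpha: float) -> ForecastResult:
    """Syntetos–Boylan approximation: Croston times the (1 - alpha/2) factor."""
    f = _croston_states(series.counts.astype(float), alpha) * (1.0 - alpha / 2.0)
    nz = series.nonzero_days()
    z, p = _final_state(series.counts, alpha, nz)
    return ForecastResult(
        series_id=series.series_id, method="sba", alpha=alpha,
        forecasts=f, z_hat=z, p_hat=p,
    )


def _final_state(counts: np.ndarray, alpha: float, nz: np.ndarray) -> tuple[float, float]:
    z_hat = float(counts[nz[0]])
    p_hat = float(nz[1] - nz[0])
    prev = nz[0]
    for t in nz[1:]:
        p_hat = alpha * float(t - prev) + (1.0 - alpha) * p_hat
        z_hat = alpha * float(counts[t]) + (1.0 - alpha) * z_hat
        prev = t
    return z_hat, p_hat


def compare_methods(
    series_set: Sequence[DemandSeries],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    split: float = 0.75,
) -> pd.DataFrame:
    """Chronological train/test comparison of Croston vs SBA per series.

    For each series and method, the smoothing constant is chosen by training
    MAE; the winner is the method with lower test scaled MAE.  A series
    whose test tail contains no demand (or too few demands to forecast) is
    flagged and excluded from the winner column.

    Returns a tidy frame: series_id, method, alpha, mae, rmse, smae (test
    metrics of the selected alpha), winner ('croston'/'sba'/'' for flagged).
    """
    if not (0.0 < split < 1.0):
        raise ValueError("split must be in (0, 1)")
    rows = []
    for s in series_set:
        counts = s.counts.astype(float)
        cut = int(round(split * counts.size))
        test_has_demand = counts[cut:].sum() > 0
        train_mean = counts[:cut].mean() if cut > 0 else counts.mean()
        picked = {}
        try:
            for method, fn in (("croston", croston), ("sba", sba)):
                best = None
                for a in alphas:
                    fr = fn(s, a)
                    train = ForecastResult(
                        s.series_id, method, a,
                        forecasts=np.where(np.arange(counts.size) < cut, fr.forecasts, np.nan),
                    )
                    m_train = train.metrics(counts, train_mean=train_mean)
                    if best is None or m_train["mae"] < best[0]:
                        best = (m_train["mae"], a, fr)
                _, a, fr = best
                test = ForecastResult(
                    s.series_id, method, a,
                    forecasts=np.where(np.arange(counts.size) >= cut, fr.forecasts, np.nan),
                )
                picked[method] = (a, test.metrics(counts, train_mean=train_mean))
        except ValueError:
            test_has_demand = False  # too sparse to forecast; flag below
            picked = {}

        if picked and test_has_demand:
            winner = min(picked, key=lambda m: picked[m][1]["smae"])
            margin = abs(picked["croston"][1]["smae"] - picked["sba"][1]["smae"])
        else:
            winner, margin = "", np.nan
            if not picked:
                warnings.warn(f"series {s.series_id!r} too sparse to forecast")
            else:
                warnings.warn(f"series {s.series_id!r} has an all-zero test tail")
        for method, (a, m) in picked.items():
            rows.append(
                {
                    "series_id": s.series_id,
                    "method": method,
                    "alpha": a,
                    "mae": m["mae"],
                    "rmse": m["rmse"],
                    "smae": m["smae"],
                    "winner": winner,
                    "margin": margin,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["series_id", "method", "alpha", "mae", "rmse", "smae", "winner", "margin"],
    )
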