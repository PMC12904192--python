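"""Predictive-performance metrics for sampling strategies.

Bias is the relative mean prediction error (rMPE), precision the relative
root mean square error (rRMSE), both in percent of the simulated truth:

    rMPE%  = 100/n * sum_i (theta_hat_i - theta_true_i) / theta_true_i
    rRMSE% = 100 * sqrt( 1/n * sum_i ((theta_hat_i - theta_true_i)/theta_true_i)^2 )

Clinical-suitability criteria require at least 80% of subjects to have a
native-unit prediction error within +/-3 IU/dL for the trough (C168,
prophylactic dosing) and +/-20 IU/dL for the peak (C0.5, pre-operative
dosing).  Because relative errors blow up when the true trough is small, the
report keeps native-unit error percentiles alongside the relative metrics,
and a dedicated summary covers the low-trough subset (true C168 < 5 IU/dL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Estimand names in report order.
ESTIMANDS = ("CL", "V", "t_half", "C0.5", "C168",
             "t_above_5", "t_above_10", "t_above_40")

#: Native-unit suitability windows (IU/dL) per estimand, where defined.
CRITERION_WINDOWS = {"C168": 3.0, "C0.5": 20.0}
CRITERION_FRACTION = 0.80
LOW_TROUGH_THRESHOLD = 5.0  # IU/dL


@dataclass(frozen=True)
class EstimandSeries:
    """Per-subject truths and one strategy's estimates for one estimand."""

    name: str
    true_values: np.ndarray
    estimates: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.true_values, dtype=float)
        e = np.asarray(self.estimates, dtype=float)
        if t.shape != e.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("true_values and estimates must be equal-length 1-D")
        object.__setattr__(self, "true_values", t)
        object.__setattr__(self, "estimates", e)


def rpe(series: EstimandSeries) -> np.ndarray:
    """Per-subject relative prediction error, %."""
    if np.any(series.true_values == 0):
        raise ZeroDivisionError(
            f"{series.name}: relative metrics undefined for zero truth")
    return (series.estimates - series.true_values) / series.true_values * 100.0


def rmpe(series: EstimandSeries) -> tuple[float, tuple[float, float]]:
    """Relative mean prediction error (%) with a normal-approximation 95% CI."""
    e = rpe(series)
    mean = float(e.mean())
    half = 1.96 * float(e.std(ddof=1)) / np.sqrt(e.size) if e.size > 1 else 0.0
    return mean, (mean - half, mean + half)


def rrmse(series: EstimandSeries) -> float:
    """Relative root mean square error, %."""
    e = rpe(series)
    return float(np.sqrt(np.mean(e * e)))


def criterion_fraction(abs_errors, window: float) -> tuple[float, bool]:
    """Fraction of |error| <= window and whether it reaches 80%."""
    abs_errors = np.abs(np.asarray(abs_errors, dtype=float))
    if abs_errors.size == 0:
        raise ValueError("no errors supplied")
    if window <= 0:
        raise ValueError("window must be positive")
    frac = float(np.mean(abs_errors <= window))
    return frac, frac >= CRITERION_FRACTION


def low_trough_subset(series: EstimandSeries,
                      threshold: float = LOW_TROUGH_THRESHOLD):
    """Mean (SD) native-unit error for subjects with *true* trough < threshold.

    Returns ``(n, mean, sd)``; ``None`` when the subset is empty (metrics
    are then omitted from the report rather than reported as 0).
    """
    mask = series.true_values < threshold
    n = int(mask.sum())
    if n == 0:
        return None
    err = series.estimates[mask] - series.true_values[mask]
    sd = float(err.std(ddof=1)) if n > 1 else 0.0
    return n, float(err.mean()), sd


RPE_PCTS = (5, 25, 50, 75, 95)


def strategy_row(strategy: str, series: EstimandSeries) -> dict:
    """One report row: relative metrics, error percentiles, criterion flag."""
    errors = rpe(series)
    mean, (lo, hi) = rmpe(series)
    native = series.estimates - series.true_values
    row = {
        "strategy": strategy,
        "estimand": series.name,
        "n": series.true_values.size,
        "rmpe_pct": mean,
        "rmpe_ci_lo": lo,
        "rmpe_ci_hi": hi,
        "rrmse_pct": rrmse(series),
    }
    for p, v in zip(RPE_PCTS, np.percentile(errors, RPE_PCTS)):
        row[f"rpe_p{p}"] = float(v)
    row["abs_err_p10"] = float(np.percentile(native, 10))
    row["abs_err_p90"] = float(np.percentile(native, 90))
    window = CRITERION_WINDOWS.get(series.name)
    if window is not None:
        frac, ok = criterion_fraction(native, window)
        row["criterion_window"] = window
        row["criterion_fraction"] = frac
        row["criterion_pass"] = ok
    else:
        row["criterion_window"] = np.nan
        row["criterion_fraction"] = np.nan
        row["criterion_pass"] = pd.NA
    return row


def build_report(results: dict[str, dict[str, EstimandSeries]]) -> pd.DataFrame:
    """Strategy x estimand metric table.

    ``results`` maps strategy name -> estimand name -> series.  Missing
    estimands yield a row flagged incomplete rather than being dropped.
    """
    rows = []
    for strategy, by_estimand in results.items():
        for name in ESTIMANDS:
            series = by_estimand.get(name)
            if series is None:
                rows.append({"strategy": strategy, "estimand": name,
                             "incomplete": True})
                continue
            row = strategy_row(strategy, series)
            row["incomplete"] = False
            rows.append(row)
    return pd.DataFrame(rows)


def criteria_summary(results: dict[str, dict[str, EstimandSeries]]) -> pd.DataFrame:
    """Per-strategy suitability: the 80%-within-window tests and the
    low-trough subset error summary."""
    rows = []
    for strategy, by_estimand in results.items():
        row: dict = {"strategy": strategy}
        for name, window in CRITERION_WINDOWS.items():
            series = by_estimand.get(name)
            if series is None:
                continue
            native = series.estimates - series.true_values
            frac, ok = criterion_fraction(native, window)
            key = name.replace(".", "")
            row[f"{key}_within_{window:g}_fraction"] = frac
            row[f"{key}_pass"] = ok
        c168 = by_estimand.get("C168")
        if c168 is not None:
            sub = low_trough_subset(c168)
            if sub is None:
                row["low_trough_n"] = 0
            else:
                row["low_trough_n"], row["low_trough_mean_err"], \
                    row["low_trough_sd_err"] = sub
        rows.append(row)
    return pd.DataFrame(rows)
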