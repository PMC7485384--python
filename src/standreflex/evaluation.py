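"""Comparison of simulated and experimental joint-angle/moment time series.

Experimental tables are low-pass filtered (zero-phase second-order
Butterworth, 16 Hz cut-off, applied forward-backward at the table's native
rate), resampled by linear interpolation onto the simulation's time points,
and correlated signal-by-signal with Pearson's r (two-sided p from the
t-transform with n-2 degrees of freedom).  Simulation output is noise-free
and is not filtered.  Six signals are compared: hip, knee and ankle angles
and moments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

EVAL_COLUMNS = ["time_s", "hip_deg", "knee_deg", "ankle_deg",
                "hip_Nm", "knee_Nm", "ankle_Nm"]
SIGNALS = EVAL_COLUMNS[1:]


def load_trajectory_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time must be strictly increasing")
    return df


def butterworth_lowpass(series, fs: float, order: int = 2,
                        fc: float = 16.0) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass, DC gain 1."""
    if fs <= 2 * fc:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the "
                         f"cut-off {fc} Hz")
    b, a = sp_signal.butter(order, fc, fs=fs)
    return sp_signal.filtfilt(b, a, np.asarray(series, dtype=float))


def resample_to(times, values, target_times) -> np.ndarray:
    """Linear interpolation onto target times (no extrapolation)."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    target = np.asarray(target_times, float)
    if target.min() < times[0] - 1e-9 or target.max() > times[-1] + 1e-9:
        raise ValueError("target times extend beyond the source span")
    return np.interp(target, times, values)


def pearson(x, y) -> tuple[float, float]:
    """Pearson's product-moment r with two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series of at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


def compare(sim: pd.DataFrame, exp: pd.DataFrame,
            fc: float = 16.0, filter_experiment: bool = True) -> pd.DataFrame:
    """Correlation report between a simulated and an experimental table.

    Both tables use the evaluation CSV dialect.  Returns one row per signal
    with Pearson r, p, the number of samples, and the mean offset
    (simulation minus experiment) in the signal's own units.
    """
    for name, df in (("sim", sim), ("experiment", exp)):
        missing = set(EVAL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    t_sim = sim["time_s"].to_numpy(float)
    t_exp = exp["time_s"].to_numpy(float)
    lo = max(t_sim[0], t_exp[0])
    hi = min(t_sim[-1], t_exp[-1])
    if hi <= lo:
        raise ValueError("tables have no overlapping time span")
    mask = (t_sim >= lo - 1e-12) & (t_sim <= hi + 1e-12)
    t_common = t_sim[mask]
    fs_exp = 1.0 / np.median(np.diff(t_exp))

    rows = []
    for col in SIGNALS:
        x = sim[col].to_numpy(float)[mask]
        y_native = exp[col].to_numpy(float)
        if filter_experiment:
            y_native = butterworth_lowpass(y_native, fs_exp, fc=fc)
        y = resample_to(t_exp, y_native, t_common)
        r, p = pearson(x, y)
        rows.append({"signal": col, "r": r, "p": p, "n": len(t_common),
                     "mean_offset": float(np.mean(x - y))})
    return pd.DataFrame(rows, columns=["signal", "r", "p", "n", "mean_offset"])


def mean_correlation(report: pd.DataFrame, which: str = "all") -> float:
    """Average r over angle rows, moment rows, or all six."""
    sel = {
        "angles": report["signal"].str.endswith("_deg"),
        "moments": report["signal"].str.endswith("_Nm"),
        "all": np.ones(len(report), dtype=bool),
    }[which]
    return float(report.loc[sel, "r"].mean())
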