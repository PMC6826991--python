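"""Logistic growth-curve fitting: intensity time series → cell proliferation
parameters (CPPs).

Each culture's image-intensity series G(t) is fit by least squares to
``G(t) = K / (1 + exp(-r (t - l)))`` under the assumption G(0) < K, yielding
the CPPs: K (carrying capacity, intensity units), r (maximum specific growth
rate, 1/h) and L (time at half carrying capacity, h; the moment of maximal
absolute growth rate). Cultures that never grow are flagged instead of fit.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import logistic_curve

NO_GROWTH_L = np.nan  # sentinel: L unobserved for a culture with no curve

CPP_TABLE_COLUMNS = [
    "plate", "row", "col", "strain", "drug", "dose",
    "K", "r", "L", "rss", "converged", "no_growth",
]


@dataclass(frozen=True)
class GrowthCurveFit:
    K_cpp: float
    r_cpp: float
    L_cpp: float
    rss: float
    converged: bool
    no_growth: bool

    def predict(self, t) -> np.ndarray:
        return logistic_curve(t, self.K_cpp, self.r_cpp, self.L_cpp)


NO_GROWTH_FIT = GrowthCurveFit(0.0, 0.0, NO_GROWTH_L, np.nan, False, True)


def classify_no_growth(
    times,
    intensities,
    min_fold_change: float = 1.5,
    min_final_intensity: float = 10.0,
) -> bool:
    """True iff the culture produced no growth curve.

    A culture is no-growth when its peak intensity stays below
    ``min_final_intensity`` or its peak-to-initial fold change stays below
    ``min_fold_change``; both comparisons are strict, so a series exactly at
    threshold counts as growth.
    """
    y = np.asarray(intensities, dtype=float)
    peak = float(y.max())
    if peak < min_final_intensity:
        return True
    initial = max(float(y[0]), 1e-9)
    return peak / initial < min_fold_change


def _validate_series(times: np.ndarray, intensities: np.ndarray) -> None:
    if times.size < 4:
        raise ValueError("need >= 4 timepoints for a 3-parameter fit")
    if times.size != intensities.size:
        raise ValueError("times and intensities differ in length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(intensities < 0):
        raise ValueError("intensities must be non-negative")


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Heuristic start: K from the peak, L from the half-max crossing by
    linear interpolation, r from the log-slope of the middle of the rise."""
    K0 = float(y.max())
    half = K0 / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
        L0 = t0 + (half - y0) / max(y1 - y0, 1e-12) * (t1 - t0)
    elif above.size:
        L0 = float(t[0])
    else:  # never reaches half max (should have been no-growth)
        L0 = float(t[-1])
    # logit-transform points in the exponential phase; slope of the line = r
    mask = (y > 0.1 * K0) & (y < 0.9 * K0)
    if mask.sum() >= 2:
        z = np.log(y[mask] / np.maximum(K0 * 1.02 - y[mask], 1e-9))
        slope = np.polyfit(t[mask], z, 1)[0]
        r0 = float(np.clip(slope, 0.01, 10.0))
    else:
        r0 = 4.0 / max(t[-1] - t[0], 1.0)
    return K0, r0, L0


def default_bounds(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parameter box: K in (0, 2*max], r in (0, 10], l in [-24, 2*t_max]."""
    ymax = max(float(y.max()), 1e-6)
    return (
        np.array([1e-9, 1e-9, -24.0]),
        np.array([2.0 * ymax, 10.0, 2.0 * float(t[-1])]),
    )


def restart_seed(tag: str) -> int:
    """Deterministic per-culture restart seed derived from its identifier."""
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


def fit_logistic(
    times,
    intensities,
    baseline: str = "none",
    bounds=None,
    min_fold_change: float = 1.5,
    min_final_intensity: float = 10.0,
    max_restarts: int = 5,
    seed: int = 0,
) -> GrowthCurveFit:
    """Least-squares logistic fit of one culture.

    baseline
        "none" (default) fits the raw intensities; "subtract_min" subtracts
        the minimum of the first two timepoints first (agar background, for
        real-plate exports with an additive offset).
    Returns a no-growth fit (K = r = 0, L unobserved) for flat series; on
    optimizer failure after ``max_restarts`` perturbed restarts, returns the
    best-effort parameters with ``converged=False``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    _validate_series(t, y)
    if classify_no_growth(t, y, min_fold_change, min_final_intensity):
        return NO_GROWTH_FIT
    if baseline == "subtract_min":
        y = np.maximum(y - float(np.min(y[:2])), 0.0)
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if bounds is None:
        bounds = default_bounds(t, y)
    lo, hi = bounds
    p0 = np.clip(_initial_guess(t, y), lo, hi)

    rng = np.random.default_rng(seed)
    best, best_rss = None, np.inf
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else np.clip(
            p0 * rng.uniform(0.5, 1.5, size=3), lo, hi
        )
        try:
            # unbounded Levenberg-Marquardt is much faster; fall back to
            # bounded trust-region only if it wanders out of the box
            popt, _ = curve_fit(logistic_curve, t, y, p0=start, method="lm", maxfev=2000)
            if np.any(popt < lo) or np.any(popt > hi):
                popt, _ = curve_fit(
                    logistic_curve, t, y, p0=start, bounds=(lo, hi), maxfev=2000
                )
        except RuntimeError:
            continue
        rss = float(np.sum((logistic_curve(t, *popt) - y) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
            if attempt == 0:
                break  # first try succeeded; restarts are for failures only

    if best is None:
        K0, r0, L0 = p0
        return GrowthCurveFit(K0, r0, L0, np.nan, False, False)
    K, r, l = (float(v) for v in best)
    dt = float(np.median(np.diff(t)))
    in_window = (t[0] - dt) <= l <= t[-1] + 0.5 * (t[-1] - t[0])
    converged = K > 0 and r > 0 and in_window
    return GrowthCurveFit(K, r, l, best_rss, converged, False)


_DOSE_SUFFIX = re.compile(r"[_-]d\d+$")


def array_id(plate: str) -> str:
    """Strip the dose token from a plate id, leaving the physical array id
    shared across the dose series (``gemcitabine_a00_d3`` → ``gemcitabine_a00``)."""
    return _DOSE_SUFFIX.sub("", plate)


def fit_cpp_table(
    timeseries: pd.DataFrame,
    baseline: str = "none",
    min_fold_change: float = 1.5,
    min_final_intensity: float | None = None,
    max_restarts: int = 5,
) -> pd.DataFrame:
    """Fit every culture in a long-format time-series table.

    Cultures are identified by (plate, row, col, strain, drug, dose). When
    ``min_final_intensity`` is None it defaults to 10% of the median final
    intensity across all cultures: high enough that the extreme-value peak of
    a pure-noise blank series stays below it, low enough that any culture
    reaching a respectable fraction of carrying capacity clears it.
    Returns the CPP table (one row per culture).
    """
    ts = timeseries.sort_values(["plate", "row", "col", "time_h"], kind="stable")
    if min_final_intensity is None:
        finals = ts.groupby(["plate", "row", "col"], sort=False)["intensity"].last()
        min_final_intensity = 0.10 * float(finals.median())

    records = []
    for (plate, row, col, strain, drug, dose), grp in ts.groupby(
        ["plate", "row", "col", "strain", "drug", "dose"], sort=False
    ):
        fit = fit_logistic(
            grp["time_h"].to_numpy(),
            grp["intensity"].to_numpy(),
            baseline=baseline,
            min_fold_change=min_fold_change,
            min_final_intensity=min_final_intensity,
            max_restarts=max_restarts,
            seed=restart_seed(f"{strain}|{plate}|{row}|{col}"),
        )
        records.append(
            (plate, row, col, strain, drug, dose,
             fit.K_cpp, fit.r_cpp, fit.L_cpp, fit.rss, fit.converged, fit.no_growth)
        )
    return pd.DataFrame(records, columns=CPP_TABLE_COLUMNS)
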