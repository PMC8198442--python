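"""Finite-difference kinetics of dose-time quantities.

The growth-dynamics analysis treats each measured quantity X(d, t) as a
trajectory per dose and reports its "velocity" dX/dt (first finite
difference over each sampling interval), its "acceleration" d2X/dt2
(difference of consecutive interval rates over the spacing of interval
midpoints) and a "Total" rate/acceleration summarising the whole 0->72 h
window.  Doubling time uses the classical decadic-log formula
t_d = dt / (3.32 * dlog10 N) with the constant fixed at 3.32.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DoseTimeSeries

__all__ = [
    "KineticsResult",
    "DoublingTime",
    "finite_differences",
    "doubling_time",
    "subpopulation_counts",
    "DOUBLING_CONSTANT",
]

#: Dimensionless constant of the doubling-time formula (approx. 1/log10(2)).
DOUBLING_CONSTANT = 3.32


@dataclass
class KineticsResult:
    """Finite-difference derivatives of one quantity, one row per dose.

    ``rates`` holds one interval rate per consecutive time pair, labelled by
    the interval's right endpoint; ``accelerations`` one value per pair of
    consecutive intervals, labelled by the right interval's endpoint and
    computed over interval-midpoint spacing.  ``total_rate`` is
    (X(t_last) - X(t_first)) / (t_last - t_first) and ``total_acceleration``
    the first-to-last rate change over the midpoint span.
    """

    quantity_name: str
    unit: str
    rates: pd.DataFrame
    accelerations: pd.DataFrame
    total_rate: pd.Series
    total_acceleration: pd.Series
    interval_midpoints: np.ndarray

    def to_tidy(self) -> pd.DataFrame:
        rates = self.rates.stack(future_stack=True).rename("rate").reset_index()
        rates.columns = ["dose_uM", "interval_end_h", "rate"]
        acc = self.accelerations.stack(future_stack=True).rename("acceleration").reset_index()
        acc.columns = ["dose_uM", "interval_end_h", "acceleration"]
        out = rates.merge(acc, on=["dose_uM", "interval_end_h"], how="left")
        out["total_rate"] = out["dose_uM"].map(self.total_rate)
        out["total_acceleration"] = out["dose_uM"].map(self.total_acceleration)
        out.insert(0, "quantity", self.quantity_name)
        return out


@dataclass
class DoublingTime:
    """Population doubling time over one interval."""

    t_d: float  # hours; inf when the population did not grow
    t_start: float
    t_end: float
    constant_c: float = DOUBLING_CONSTANT

    @property
    def growing(self) -> bool:
        return math.isfinite(self.t_d)


def finite_differences(series: DoseTimeSeries, include_pretreatment: bool = False) -> KineticsResult:
    """First and second finite differences of X(d, t) per dose.

    The pre-dosing time point (t < 0) is excluded by default: cells are
    seeded 24 h before treatment and that interval reflects seeding, not
    drug response.  Missing values propagate as NaN into exactly the rates
    and accelerations that depend on them.
    """
    if not include_pretreatment:
        series = series.restrict_times(0.0)
    t = series.times
    if len(t) < 2:
        raise ValueError("need at least 2 time points for rates")
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate time points")
    X = series.data.to_numpy(dtype=float)
    dt = np.diff(t)
    rates = np.diff(X, axis=1) / dt  # one per interval
    mid = (t[:-1] + t[1:]) / 2.0
    if len(t) >= 3:
        acc = np.diff(rates, axis=1) / np.diff(mid)
    else:
        acc = np.empty((X.shape[0], 0))
    doses = series.doses
    rates_df = pd.DataFrame(rates, index=doses, columns=t[1:])
    acc_df = pd.DataFrame(acc, index=doses, columns=t[2:])
    total_rate = pd.Series((X[:, -1] - X[:, 0]) / (t[-1] - t[0]), index=doses)
    if len(t) >= 3:
        total_acc = pd.Series((rates[:, -1] - rates[:, 0]) / (mid[-1] - mid[0]), index=doses)
    else:
        total_acc = pd.Series(np.nan, index=doses)
    for df in (rates_df, acc_df):
        df.index.name = "dose_uM"
        df.columns.name = "interval_end_h"
    return KineticsResult(
        quantity_name=series.quantity_name,
        unit=f"{series.unit}/h" if series.unit else "1/h",
        rates=rates_df,
        accelerations=acc_df,
        total_rate=total_rate,
        total_acceleration=total_acc,
        interval_midpoints=mid,
    )


def doubling_time(n_start: float, n_end: float, delta_t: float,
                  t_start: float = 0.0) -> DoublingTime:
    """Doubling time t_d = dt / (3.32 * log10(N_end / N_start)).

    A non-growing culture (N_end <= N_start) is flagged by t_d = inf rather
    than returning a negative number silently.
    """
    if n_start <= 0 or n_end <= 0:
        raise ValueError("cell counts must be positive")
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    dlog = math.log10(n_end / n_start)
    if dlog <= 0:
        return DoublingTime(math.inf, t_start, t_start + delta_t)
    return DoublingTime(delta_t / (DOUBLING_CONSTANT * dlog), t_start, t_start + delta_t)


def subpopulation_counts(
    total: DoseTimeSeries,
    fractions: tuple[DoseTimeSeries, DoseTimeSeries, DoseTimeSeries],
    tol: float = 1e-6,
) -> tuple[DoseTimeSeries, DoseTimeSeries, DoseTimeSeries]:
    """Absolute viable/apoptotic/necrotic populations from total counts.

    Fractions must lie in [0, 1] and sum to 1 within *tol* at every
    (dose, time); the three output counts then sum to the total exactly.
    """
    if (total.data.to_numpy() < 0).any():
        raise ValueError("negative total counts")
    stack = np.stack([f.data.to_numpy(dtype=float) for f in fractions])
    if (stack < 0).any() or (stack > 1).any():
        raise ValueError("fractions must lie in [0, 1]")
    s = stack.sum(axis=0)
    if np.nanmax(np.abs(s - 1.0)) > tol:
        raise ValueError(f"fractions do not sum to 1 (max deviation {np.nanmax(np.abs(s - 1.0)):.3g})")
    out = []
    for f in fractions:
        counts = total.data * f.data
        out.append(DoseTimeSeries(f"{total.quantity_name}_{f.quantity_name}", total.unit, counts))
    return tuple(out)
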