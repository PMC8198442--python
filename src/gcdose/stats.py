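"""Differential expression, correlation battery and surface regression.

Differential expression uses a per-probe two-sample Student's t-test
(equal variance by default, Welch optional) with Benjamini-Hochberg FDR
control; a probe is called significant only if it passes both the raw
p < alpha and the FDR < threshold cut in every experiment (the AND rule).

The derivative-pair battery correlates first/second finite-difference
derivatives of a metabolite concentration with the matching derivatives
of population, cell size, and necrotic/apoptotic counts, pairing values
across doses at a fixed sampling interval.

The surface regression is a biharmonic (Green's function) scattered-data
interpolant, g(r) = r^2 (ln r - 1) plus an affine trend, which passes
through every data point exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .kinetics import KineticsResult

__all__ = [
    "DEGTable",
    "differential_expression",
    "combine_experiments",
    "correlate",
    "CorrelationBattery",
    "derivative_battery",
    "biharmonic_surface",
    "BATTERY_PAIRS",
]


@dataclass
class DEGTable:
    """Per-probe differential-expression summary for one comparison."""

    table: pd.DataFrame  # columns: mean_a, mean_b, t, p, fdr, significant
    alpha: float = 0.05
    fdr_threshold: float = 0.05

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def to_csv(self, path) -> None:
        self.table.rename_axis("probe_id").to_csv(path)


def differential_expression(
    values: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    fdr_threshold: float = 0.05,
    equal_var: bool = True,
) -> DEGTable:
    """Per-probe Student's t-test with Benjamini-Hochberg FDR.

    Parameters
    ----------
    values : DataFrame
        Probes x samples expression values.
    groups : sequence
        One label per sample column; exactly two distinct labels, each with
        >= 2 samples.
    equal_var : bool
        Classical Student's test (pooled variance) by default; False gives
        Welch's variant.

    Probes where both groups are constant with equal means get p = 1 by
    convention (no evidence of difference, zero information).
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two group labels required")
    a = values.loc[:, groups == labels[0]].to_numpy(dtype=float)
    b = values.loc[:, groups == labels[1]].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = np.isnan(t)
    same_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t = np.where(degenerate & same_mean, 0.0, t)
    p = np.where(degenerate & same_mean, 1.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "t": t,
            "p": p,
            "fdr": fdr,
            "significant": (p < alpha) & (fdr < fdr_threshold),
        },
        index=values.index,
    )
    return DEGTable(table, alpha=alpha, fdr_threshold=fdr_threshold)


def combine_experiments(tables: dict[str, DEGTable]) -> pd.DataFrame:
    """AND-rule combination: significant in every experiment.

    Returns a per-probe frame with each experiment's p/FDR and the combined
    flag (p < alpha and FDR < threshold in all experiments).
    """
    if not tables:
        raise ValueError("no experiments given")
    frames = []
    flag = None
    for name, deg in tables.items():
        sub = deg.table[["p", "fdr", "significant"]].add_prefix(f"{name}_")
        frames.append(sub)
        flag = deg.table["significant"] if flag is None else (flag & deg.table["significant"])
    out = pd.concat(frames, axis=1)
    out["significant_all"] = flag
    return out


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its p-value.

    The p-value comes from the t-approximation with n-2 degrees of
    freedom.  Zero variance in either input leaves the coefficient
    undefined: (nan, nan) is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", RuntimeWarning, stacklevel=2)
        return (float("nan"), float("nan"))
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


#: The eight unique derivative pairs (Latin numeral -> (order, counterpart)).
#: Odd rows pair first derivatives, even rows second derivatives, of the
#: metabolite against population (N), cell size (FS), necrotic and apoptotic
#: counts respectively.
BATTERY_PAIRS = {
    "I": (1, "population"),
    "II": (2, "population"),
    "III": (1, "fs"),
    "IV": (2, "fs"),
    "V": (1, "necrotic"),
    "VI": (2, "necrotic"),
    "VII": (1, "apoptotic"),
    "VIII": (2, "apoptotic"),
}


@dataclass
class CorrelationBattery:
    """Derivative-pair correlations: one row per (metabolite, pair, interval)."""

    table: pd.DataFrame  # columns: metabolite, pair, interval_end_h, r, p, n

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def derivative_battery(
    metabolite_kinetics: dict[str, KineticsResult],
    quantity_kinetics: dict[str, KineticsResult],
    method: str = "pearson",
) -> CorrelationBattery:
    """Correlate metabolite derivatives with growth/death/size derivatives.

    For each metabolite (glucose, lactate), each of the eight pair
    definitions and each sampling interval, the derivative values are
    paired across doses and correlated.  Grids must match across inputs.
    """
    rows = []
    for met_name, met_kin in metabolite_kinetics.items():
        for numeral, (order, counterpart) in BATTERY_PAIRS.items():
            if counterpart not in quantity_kinetics:
                raise ValueError(f"missing kinetics for {counterpart!r}")
            qty_kin = quantity_kinetics[counterpart]
            met_df = met_kin.rates if order == 1 else met_kin.accelerations
            qty_df = qty_kin.rates if order == 1 else qty_kin.accelerations
            if not met_df.columns.equals(qty_df.columns) or not met_df.index.equals(qty_df.index):
                raise ValueError("derivative grids do not match")
            for interval in met_df.columns:
                xv = met_df[interval].to_numpy()
                yv = qty_df[interval].to_numpy()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    r, p = correlate(xv, yv, method=method)
                rows.append(
                    {
                        "metabolite": met_name,
                        "pair": numeral,
                        "order": order,
                        "counterpart": counterpart,
                        "interval_end_h": float(interval),
                        "r": r,
                        "p": p,
                        "n": int(np.sum(~(np.isnan(xv) | np.isnan(yv)))),
                    }
                )
    return CorrelationBattery(pd.DataFrame(rows))


def biharmonic_surface(points: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Biharmonic scattered-data surface interpolation.

    Solves for weights w and affine trend a in

        z(q) = sum_i w_i g(|q - p_i|) + a0 + a1 x + a2 y,
        g(r) = r^2 (ln r - 1),  g(0) = 0,

    subject to the usual orthogonality side conditions, and evaluates the
    surface on the given (x, y) targets.  The interpolant passes through
    every data site exactly and reproduces affine surfaces.
    """
    points = np.asarray(points, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of (x, y, z)")
    n = len(points)
    if n < 3:
        raise ValueError("need at least 3 points")
    xy = points[:, :2]
    z = points[:, 2]
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    off_diag = ~np.eye(n, dtype=bool)
    if (d[off_diag] == 0).any():
        raise ValueError("duplicate (x, y) sites")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), xy])) < 3:
        raise ValueError("points are collinear; surface is underdetermined")

    def g(r):
        with np.errstate(divide="ignore", invalid="ignore"):
            val = r**2 * (np.log(r) - 1.0)
        return np.where(r > 0, val, 0.0)

    G = g(d)
    P = np.column_stack([np.ones(n), xy])
    A = np.block([[G, P], [P.T, np.zeros((3, 3))]])
    rhs = np.concatenate([z, np.zeros(3)])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular interpolation system") from exc
    w, a = sol[:n], sol[n:]
    dq = np.linalg.norm(grid[:, None, :] - xy[None, :, :], axis=2)
    return g(dq) @ w + a[0] + grid @ a[1:]
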