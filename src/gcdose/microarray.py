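"""Two-channel microarray preprocessing.

The chain mirrors classic cDNA-array practice: multiplicative background
correction (divide each channel by a robust per-array background estimate,
i.e. subtract log backgrounds from log foregrounds), geometric-mean
averaging of replicates, per-probe mean log2 ratios, normalization (local
quadratic loess on an MA representation, rank-invariant, or quantile), and
the internal consistency check of the simple-loop design: the log2 ratio
of the 0v3 contrast should equal the sum of the 0v1 and 1v3 ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TwoChannelArray",
    "ExpressionMatrix",
    "read_spot_table",
    "mbc_correct",
    "average_replicates",
    "mean_log_ratio",
    "normalize",
    "loop_consistency",
    "LOOP_DESIGNS",
    "REFERENCE_DESIGNS",
]

LOOP_DESIGNS = ("0v1", "1v3", "0v3")
REFERENCE_DESIGNS = ("4", "5")


@dataclass
class TwoChannelArray:
    """Per-probe spot intensities of one two-channel hybridization.

    ``f_r``/``f_g`` are foreground and ``b_r``/``b_g`` local background
    intensities of the red (Cy5) and green (Cy3) channels.  ``mask`` flags
    spots excluded from analysis (non-positive intensities etc.).
    """

    probe_id: list[str]
    f_r: np.ndarray
    b_r: np.ndarray
    f_g: np.ndarray
    b_g: np.ndarray
    replicate: int = 1
    design: str = "0v1"
    mask: np.ndarray | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        n = len(self.probe_id)
        for name in ("f_r", "b_r", "f_g", "b_g"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape == ():
                arr = np.full(n, float(arr))
            if len(arr) != n:
                raise ValueError(f"{name} length != number of probes")
            setattr(self, name, arr)
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_id,
                "F_R": self.f_r,
                "B_R": self.b_r,
                "F_G": self.f_g,
                "B_G": self.b_g,
                "replicate": self.replicate,
                "design": self.design,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


#: GenePix GPR column aliases mapped onto the native schema.
_GPR_ALIASES = {
    "F635 Median": "F_R",
    "B635 Median": "B_R",
    "F532 Median": "F_G",
    "B532 Median": "B_G",
    "F635 Mean": "F_R",
    "B635 Mean": "B_R",
    "F532 Mean": "F_G",
    "B532 Mean": "B_G",
    "ID": "probe_id",
    "Name": "probe_id",
}


def read_spot_table(path, replicate: int | None = None, design: str | None = None) -> TwoChannelArray:
    """Read a TSV spot table (native schema or GenePix-GPR-like dialect).

    GPR files may start with an ``ATF`` preamble; header lines before the
    one containing the intensity columns are skipped.  F635/B635 (Cy5) and
    F532/B532 (Cy3) median columns map onto F_R/B_R/F_G/B_G.
    """
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = 0
    for i, line in enumerate(lines):
        if "F_R" in line or "F635" in line:
            header_idx = i
            break
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines[header_idx:])), sep="\t")
    rename = {}
    for col in frame.columns:
        key = col.strip().strip('"')
        if key in _GPR_ALIASES:
            rename[col] = _GPR_ALIASES[key]
    frame = frame.rename(columns=rename)
    frame = frame.loc[:, ~frame.columns.duplicated()]
    required = {"probe_id", "F_R", "B_R", "F_G", "B_G"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"spot table lacks columns {sorted(missing)}")
    return TwoChannelArray(
        probe_id=[str(p) for p in frame["probe_id"]],
        f_r=frame["F_R"].to_numpy(dtype=float),
        b_r=frame["B_R"].to_numpy(dtype=float),
        f_g=frame["F_G"].to_numpy(dtype=float),
        b_g=frame["B_G"].to_numpy(dtype=float),
        replicate=int(replicate if replicate is not None else frame.get("replicate", pd.Series([1])).iloc[0]),
        design=str(design if design is not None else frame.get("design", pd.Series(["0v1"])).iloc[0]),
    )


def mbc_correct(
    array: TwoChannelArray,
    background_estimator: str = "median",
    quantile: float = 0.25,
    per_spot: bool = False,
) -> TwoChannelArray:
    """Multiplicative background correction.

    Per channel, a robust scalar background estimate Bl (median of the
    local backgrounds by default, a lower quantile as the alternative) is
    divided out: corrected log2 intensity = log2(F) - log2(Bl), reported on
    the absolute scale 2^(log2 F - log2 Bl) = F / Bl.  With ``per_spot``
    each spot's own local background is used instead of the array scalar.
    """
    ok = ~array.mask & (array.f_r > 0) & (array.f_g > 0)
    if not ok.any():
        raise ValueError("no usable spots")
    for name, bg in (("red", array.b_r), ("green", array.b_g)):
        if (bg[ok] <= 0).any():
            raise ValueError(f"non-positive local background in {name} channel")
    if per_spot:
        bl_r, bl_g = array.b_r, array.b_g
    elif background_estimator == "median":
        bl_r = float(np.median(array.b_r[ok]))
        bl_g = float(np.median(array.b_g[ok]))
    elif background_estimator == "quantile":
        bl_r = float(np.quantile(array.b_r[ok], quantile))
        bl_g = float(np.quantile(array.b_g[ok], quantile))
    else:
        raise ValueError(f"unknown background estimator {background_estimator!r}")
    if np.any(np.asarray(bl_r) <= 0) or np.any(np.asarray(bl_g) <= 0):
        raise ValueError("non-positive background estimate")
    corrected = replace(
        array,
        f_r=2.0 ** (np.log2(array.f_r) - np.log2(bl_r)),
        f_g=2.0 ** (np.log2(array.f_g) - np.log2(bl_g)),
        mask=~ok,
        corrected=True,
    )
    return corrected


@dataclass
class ExpressionMatrix:
    """Replicate-averaged two-channel intensities and log2 ratios per contrast.

    ``intensities`` maps design label -> DataFrame with columns ``Fa_R``,
    ``Fa_G`` (geometric-mean averaged, background-corrected intensities)
    indexed by probe.  ``replicate_ratios`` maps design label -> DataFrame
    of per-replicate log2(R/G) ratios (one column per replicate).
    """

    intensities: dict[str, pd.DataFrame] = field(default_factory=dict)
    replicate_ratios: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_replicates: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def contrasts(self) -> list[str]:
        return list(self.intensities)

    @property
    def probes(self) -> pd.Index:
        return next(iter(self.intensities.values())).index

    def log_ratios(self) -> pd.DataFrame:
        """Per-probe mean log2 ratio per contrast (Fa_R over Fa_G)."""
        out = {}
        for lab, df in self.intensities.items():
            out[lab] = np.log2(df["Fa_R"] / df["Fa_G"])
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        self.log_ratios().rename_axis("probe_id").to_csv(path)


def average_replicates(arrays: list[TwoChannelArray]) -> ExpressionMatrix:
    """Geometric-mean replicate averaging, grouped by design label.

    Fa = (F_r1 * F_r2 * ... * F_rn)^(1/n) per channel per probe; spots
    masked in a replicate are dropped from that probe's product, recorded
    in ``n_replicates``.  Arrays must be background-corrected first.
    """
    if not arrays:
        raise ValueError("no arrays given")
    by_design: dict[str, list[TwoChannelArray]] = {}
    for a in arrays:
        if not a.corrected:
            raise ValueError("arrays must be MBC-corrected before averaging")
        by_design.setdefault(a.design, []).append(a)
    matrix = ExpressionMatrix()
    for lab, group in by_design.items():
        probes = group[0].probe_id
        for a in group[1:]:
            if a.probe_id != probes:
                raise ValueError(f"probe sets differ within design {lab!r}")
        logs_r = np.stack([np.where(a.mask, np.nan, np.log2(a.f_r)) for a in group])
        logs_g = np.stack([np.where(a.mask, np.nan, np.log2(a.f_g)) for a in group])
        n_ok = np.sum(~np.isnan(logs_r) & ~np.isnan(logs_g), axis=0)
        fa_r = 2.0 ** np.nanmean(logs_r, axis=0)
        fa_g = 2.0 ** np.nanmean(logs_g, axis=0)
        matrix.intensities[lab] = pd.DataFrame({"Fa_R": fa_r, "Fa_G": fa_g}, index=pd.Index(probes, name="probe_id"))
        rep_cols = {f"rep{a.replicate}": lr - lg for a, lr, lg in zip(group, logs_r, logs_g)}
        matrix.replicate_ratios[lab] = pd.DataFrame(rep_cols, index=pd.Index(probes, name="probe_id"))
        matrix.n_replicates[lab] = pd.Series(n_ok, index=pd.Index(probes, name="probe_id"))
    return matrix


def mean_log_ratio(ratios) -> float | np.ndarray:
    """Mean expression ratio R = (1/j) sum log2(ratio_i) = log2(geometric mean)."""
    arr = np.asarray(ratios, dtype=float)
    if (arr <= 0).any():
        raise ValueError("ratios must be positive")
    return np.mean(np.log2(arr), axis=-1)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _local_polynomial_fit(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
                          span: float, degree: int) -> np.ndarray:
    """Loess-style local polynomial regression with tricube weights.

    For each evaluation point the ``span`` fraction of nearest neighbours
    (by |x|-distance) is fit with a weighted degree-``degree`` polynomial.
    """
    n = len(x)
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError(f"span window of {k} points too small for degree {degree}")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        lo = np.searchsorted(xs, x0)
        lo = min(max(lo - k // 2, 0), n - k)
        xi, yi = xs[lo:lo + k], ys[lo:lo + k]
        d = np.abs(xi - x0)
        dmax = d.max()
        w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
        V = np.vander(xi - x0, degree + 1, increasing=True)
        W = np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(V * W, yi * W.ravel(), rcond=None)
        out[i] = coef[0]
    return out


def _loess_normalize_contrast(fa_r: np.ndarray, fa_g: np.ndarray, span: float) -> np.ndarray:
    """Return normalized M = log2(R/G) after removing the loess(A) trend."""
    m = np.log2(fa_r / fa_g)
    a = 0.5 * np.log2(fa_r * fa_g)
    fit = _local_polynomial_fit(a, m, a, span=span, degree=2)
    return m - fit


def _rank_invariant_normalize_contrast(
    fa_r: np.ndarray, fa_g: np.ndarray, threshold_frac: float, max_iter: int = 20
) -> np.ndarray:
    """Rank-invariant normalization of one contrast.

    Iteratively selects probes whose red/green intensity ranks differ by
    less than ``threshold_frac`` of the current set size (excluding the
    extreme ranks); convergence is the selected set not changing.  A local
    linear curve fit through the invariant set on the MA plot is subtracted.
    """
    n = len(fa_r)
    m = np.log2(fa_r / fa_g)
    a = 0.5 * np.log2(fa_r * fa_g)
    selected = np.arange(n)
    for _ in range(max_iter):
        sub_r, sub_g = fa_r[selected], fa_g[selected]
        ranks_r = pd.Series(sub_r).rank().to_numpy()
        ranks_g = pd.Series(sub_g).rank().to_numpy()
        thresh = max(threshold_frac * len(selected), 1.0)
        keep = np.abs(ranks_r - ranks_g) < thresh
        # drop the extreme ranks, which are trivially "invariant"
        lo, hi = 0.02 * len(selected), 0.98 * len(selected)
        keep &= (ranks_r > lo) & (ranks_r < hi)
        new = selected[keep]
        if len(new) < 10:
            break
        if len(new) == len(selected):
            break
        selected = new
    span = max(0.3, 20.0 / len(selected))
    fit = _local_polynomial_fit(a[selected], m[selected], a, span=min(span, 1.0), degree=1)
    return m - fit


def _quantile_normalize_columns(columns: pd.DataFrame) -> pd.DataFrame:
    """Replace each column by the mean of order statistics (ties averaged)."""
    values = columns.to_numpy(dtype=float)
    ref = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = pd.Series(values[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (ref[lo] + ref[hi]) / 2.0
    return pd.DataFrame(out, index=columns.index, columns=columns.columns)


def normalize(
    matrix: ExpressionMatrix,
    method: str = "loess",
    span: float = 0.10,
    rank_threshold: float = 0.05,
) -> ExpressionMatrix:
    """Normalize replicate-averaged intensities.

    ``loess``: per contrast, local quadratic regression of M = log2(R/G) on
    A = 0.5 log2(R G) with the given span (default 10%); the fitted trend is
    removed from M and reapportioned symmetrically to the two channels.
    ``rank_invariant``: per contrast, curve through iteratively selected
    rank-invariant probes, subtracted the same way.  ``quantile``: all
    channel vectors across arrays are mapped onto the mean of their order
    statistics.
    """
    if method not in ("loess", "rank_invariant", "quantile"):
        raise ValueError(f"unknown normalization method {method!r}")
    out = ExpressionMatrix(
        replicate_ratios={k: v.copy() for k, v in matrix.replicate_ratios.items()},
        n_replicates={k: v.copy() for k, v in matrix.n_replicates.items()},
    )
    if method == "quantile":
        cols = {}
        for lab, df in matrix.intensities.items():
            cols[f"{lab}:R"] = df["Fa_R"]
            cols[f"{lab}:G"] = df["Fa_G"]
        normed = _quantile_normalize_columns(pd.DataFrame(cols))
        for lab, df in matrix.intensities.items():
            out.intensities[lab] = pd.DataFrame(
                {"Fa_R": normed[f"{lab}:R"], "Fa_G": normed[f"{lab}:G"]}, index=df.index
            )
        return out
    for lab, df in matrix.intensities.items():
        fa_r = df["Fa_R"].to_numpy()
        fa_g = df["Fa_G"].to_numpy()
        if len(fa_r) < 20:
            raise ValueError(f"{method} normalization needs >= 20 probes")
        if method == "loess":
            m_new = _loess_normalize_contrast(fa_r, fa_g, span=span)
        else:
            m_new = _rank_invariant_normalize_contrast(fa_r, fa_g, threshold_frac=rank_threshold)
        a = 0.5 * np.log2(fa_r * fa_g)
        out.intensities[lab] = pd.DataFrame(
            {"Fa_R": 2.0 ** (a + m_new / 2.0), "Fa_G": 2.0 ** (a - m_new / 2.0)},
            index=df.index,
        )
    return out


def loop_consistency(r01: pd.Series, r13: pd.Series, r03: pd.Series) -> pd.DataFrame:
    """Per-probe loop residual r(0v1) + r(1v3) - r(0v3).

    In the simple-loop design the three contrasts are additively
    constrained in log2 space, so the residual is zero for noiseless data.
    Returns the residual per probe; the median absolute residual is the
    summary statistic in ``DataFrame.attrs['median_abs_residual']``.
    """
    common = r01.index.intersection(r13.index).intersection(r03.index)
    if len(common) == 0:
        raise ValueError("probe sets are disjoint")
    residual = r01.loc[common] + r13.loc[common] - r03.loc[common]
    out = pd.DataFrame({"residual": residual})
    out.attrs["median_abs_residual"] = float(np.nanmedian(np.abs(residual)))
    return out
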