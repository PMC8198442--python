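"""Glycolytic stoichiometry and reaction efficiency.

Anaerobic glycolysis converts one mole of glucose into two moles of
lactate (the lumped reaction C6H12O6 -> 2 CH3CHOHCOOH).  The reaction
efficiency alpha compares the observed molar lactate yield with the
theoretical yield had every consumed glucose molecule been converted:

    alpha = C_observed / C_theoretical,
    C_theoretical(t) = 2 * ([Glc]_ref - [Glc]_t)   (mmol/L lactate)
    C_observed(t)    = [Lac]_t - [Lac]_ref         (mmol/L)

The reference is either the pre-dosing (-24 h) grand mean across doses
("baseline" mode — all flasks share medium before dosing) or the previous
sampled time per dose ("stepwise" mode).  alpha is a diagnostic, not a
bounded estimator: values outside (0, 1] are reported with a flag, never
clamped, since noisy or non-glycolytic data can produce them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MetabolitePanel

__all__ = [
    "MOLAR_MASS",
    "LACTATE_PER_GLUCOSE",
    "to_molar",
    "from_molar",
    "EfficiencyResult",
    "efficiency",
]

#: Molar masses in g/mol.
MOLAR_MASS = {"glucose": 180.16, "lactate": 90.08}

#: Moles of lactate per mole of glucose in the lumped glycolysis reaction.
LACTATE_PER_GLUCOSE = 2.0


def to_molar(value, analyte: str):
    """Convert mg/dL to mmol/L: value * 10 / MW."""
    if analyte not in MOLAR_MASS:
        raise ValueError(f"unknown analyte {analyte!r}")
    arr = np.asarray(value, dtype=float)
    if (arr < 0).any():
        raise ValueError("concentrations must be non-negative")
    out = arr * 10.0 / MOLAR_MASS[analyte]
    return out.item() if np.isscalar(value) else out


def from_molar(value, analyte: str):
    """Inverse of :func:`to_molar`: mmol/L back to mg/dL."""
    if analyte not in MOLAR_MASS:
        raise ValueError(f"unknown analyte {analyte!r}")
    arr = np.asarray(value, dtype=float)
    out = arr * MOLAR_MASS[analyte] / 10.0
    return out.item() if np.isscalar(value) else out


@dataclass
class EfficiencyResult:
    """alpha per (dose, time) with the yields it was computed from.

    ``flags`` per cell: "" (ok), "undefined" (no net glucose consumption),
    "alpha>1" or "alpha<0" (outside the modelling bound, retained).
    """

    mode: str
    alpha: pd.DataFrame
    c_observed: pd.DataFrame
    c_theoretical: pd.DataFrame
    flags: pd.DataFrame

    def to_tidy(self) -> pd.DataFrame:
        parts = {
            "C_observed_mM": self.c_observed,
            "C_theoretical_mM": self.c_theoretical,
            "alpha": self.alpha,
            "flag": self.flags,
        }
        out = None
        for name, df in parts.items():
            t = df.stack(future_stack=True).rename(name).reset_index()
            t.columns = ["dose_uM", "time_h", name]
            out = t if out is None else out.merge(t, on=["dose_uM", "time_h"])
        out.insert(2, "mode", self.mode)
        return out


def efficiency(panel: MetabolitePanel, mode: str = "baseline") -> EfficiencyResult:
    """Reaction efficiency alpha per (dose, time).

    Parameters
    ----------
    panel : MetabolitePanel
        Must contain ``glucose`` and ``lactate`` in mg/dL.
    mode : {"baseline", "stepwise"}
        Reference concentrations: the grand mean at the earliest (pre-dosing)
        time across doses, or the previous sampled time per dose.
    """
    if mode not in ("baseline", "stepwise"):
        raise ValueError(f"unknown mode {mode!r}")
    for analyte in ("glucose", "lactate"):
        if analyte not in panel:
            raise ValueError(f"panel lacks {analyte!r}")
    glc = to_molar(panel["glucose"].data.to_numpy(dtype=float), "glucose")
    lac = to_molar(panel["lactate"].data.to_numpy(dtype=float), "lactate")
    index = panel["glucose"].data.index
    times = panel["glucose"].data.columns

    if mode == "baseline":
        glc_ref = np.full_like(glc, np.nanmean(glc[:, 0]))
        lac_ref = np.full_like(lac, np.nanmean(lac[:, 0]))
        c_theor = LACTATE_PER_GLUCOSE * (glc_ref - glc)
        c_obs = lac - lac_ref
        c_theor[:, 0] = np.nan  # the reference time itself carries no yield
        c_obs[:, 0] = np.nan
    else:
        c_theor = np.full_like(glc, np.nan)
        c_obs = np.full_like(lac, np.nan)
        c_theor[:, 1:] = LACTATE_PER_GLUCOSE * (glc[:, :-1] - glc[:, 1:])
        c_obs[:, 1:] = lac[:, 1:] - lac[:, :-1]

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(c_theor > 0, c_obs / np.where(c_theor > 0, c_theor, np.nan), np.nan)

    flags = np.full(alpha.shape, "", dtype=object)
    defined_cols = slice(1, None)
    undef = ~(c_theor > 0)
    flags[:, defined_cols][undef[:, defined_cols]] = "undefined"
    flags[(alpha > 1) & ~np.isnan(alpha)] = "alpha>1"
    flags[(alpha < 0) & ~np.isnan(alpha)] = "alpha<0"

    def _df(a):
        df = pd.DataFrame(a, index=index, columns=times)
        df.index.name = "dose_uM"
        df.columns.name = "time_h"
        return df

    return EfficiencyResult(mode, _df(alpha), _df(c_obs), _df(c_theor), _df(flags))
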