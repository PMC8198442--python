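"""Core containers shared across the analysis stages.

Everything measured in the dose-response experiment lives on the same
(dose, time) grid: cell counts, flow-cytometric fractions, forward-scatter
size and supernatant metabolite concentrations.  :class:`DoseTimeSeries`
is the universal container for one such quantity; :class:`MetabolitePanel`
bundles the biochemical analytes with their units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DoseTimeSeries", "MetabolitePanel", "METABOLITE_UNITS"]

#: Units of the analytes reported by the biochemical analyzer.
METABOLITE_UNITS = {
    "glucose": "mg/dL",
    "lactate": "mg/dL",
    "ldh": "IU/L",
    "alp": "IU/L",
    "k": "mmol/L",
    "na": "mmol/L",
    "ca": "mmol/L",
    "mg": "mmol/L",
}


@dataclass
class DoseTimeSeries:
    """One measured quantity on the dose x time grid.

    Parameters
    ----------
    quantity_name : str
        What is measured (e.g. ``"population"``, ``"fs"``, ``"glucose"``).
    unit : str
        Physical unit of the values.
    data : pandas.DataFrame
        Values X(d, t); rows indexed by dose (uM), columns by time (h).
        Missing measurements are NaN.
    """

    quantity_name: str
    unit: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        times = np.asarray(self.data.columns, dtype=float)
        if len(times) < 2:
            raise ValueError("DoseTimeSeries needs at least 2 time points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("time grid must be strictly increasing")
        doses = np.asarray(self.data.index, dtype=float)
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        self.data = self.data.copy()
        self.data.index = doses
        self.data.columns = times
        self.data.index.name = "dose_uM"
        self.data.columns.name = "time_h"

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def doses(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float)

    def restrict_times(self, t_min: float) -> "DoseTimeSeries":
        """Drop time points earlier than *t_min* (e.g. the pre-dosing point)."""
        keep = [c for c in self.data.columns if c >= t_min]
        return DoseTimeSeries(self.quantity_name, self.unit, self.data[keep])

    def to_tidy(self) -> pd.DataFrame:
        """Long format: one row per (dose, time)."""
        out = self.data.stack().rename("value").reset_index()
        out["quantity"] = self.quantity_name
        out["unit"] = self.unit
        return out[["dose_uM", "time_h", "quantity", "unit", "value"]]

    @classmethod
    def from_tidy(cls, frame: pd.DataFrame, quantity_name: str) -> "DoseTimeSeries":
        sub = frame[frame["quantity"] == quantity_name]
        if sub.empty:
            raise ValueError(f"quantity {quantity_name!r} not present")
        unit = str(sub["unit"].iloc[0]) if "unit" in sub else ""
        wide = sub.pivot(index="dose_uM", columns="time_h", values="value")
        return cls(quantity_name, unit, wide)


@dataclass
class MetabolitePanel:
    """Supernatant biochemistry per (dose, time), with unit metadata."""

    analytes: dict[str, DoseTimeSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, series in self.analytes.items():
            if (series.data.to_numpy() < 0).any():
                raise ValueError(f"negative concentration in analyte {name!r}")

    def __getitem__(self, analyte: str) -> DoseTimeSeries:
        return self.analytes[analyte]

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.analytes

    def to_tidy(self) -> pd.DataFrame:
        return pd.concat([s.to_tidy() for s in self.analytes.values()], ignore_index=True)

    @classmethod
    def from_tidy(cls, frame: pd.DataFrame) -> "MetabolitePanel":
        names = frame["quantity"].unique()
        return cls({n: DoseTimeSeries.from_tidy(frame, n) for n in names})
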