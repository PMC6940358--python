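"""Rate estimation from batch-culture time courses and flux-unit conversion.

Growth rate, specific productivity and metabolite exchange rates are the
per-cell derivatives of viable cell density (VCD), titer and concentration:

    mu  = (1/VCD) d(VCD)/dt          [1/h]
    q_p = (1/VCD) d(Titer)/dt        [pg/cell/h, reported per day]
    v_x = (1/VCD) d[x]/dt            [mmol/gDW/h, via the cell dry weight]

The default estimator is a log-linear (exponential-phase) regression over a
user-declared window, which reduces to the pointwise derivative for exactly
exponential growth and is more robust to measurement noise. Specific
productivity regresses titer on cumulative cell-hours (the trapezoidal
integral of VCD), the standard bioprocess estimator.

Flux-unit conversion uses a fixed cell dry weight (default 456.3 pg/cell):

    v [mmol/gDW/h] = 1000 * q_p [pg/cell/day] / (DW [pg] * MW [Da] * 24)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "TimeCourse",
    "RateEstimates",
    "UnitConversionConfig",
    "growth_rate_estimate",
    "specific_productivity_estimate",
    "exchange_rate_estimate",
    "estimate_rates",
    "productivity_to_flux",
    "flux_to_productivity",
    "read_timecourse_csv",
]

#: 1 mg/L expressed in pg/mL.
_PG_PER_ML_PER_MG_PER_L = 1.0e6


@dataclass(frozen=True)
class UnitConversionConfig:
    """Bioprocess-to-flux conversion constants."""

    cell_dry_weight_pg: float = 456.3
    hours_per_day: float = 24.0

    def __post_init__(self) -> None:
        if self.cell_dry_weight_pg <= 0:
            raise ValueError("cell_dry_weight_pg must be positive")


@dataclass
class TimeCourse:
    """Batch-culture measurements on a shared, strictly increasing time grid.

    times in hours; vcd in viable cells per mL; titer in mg per L (optional);
    metabolite concentrations in mM (optional).
    """

    times: np.ndarray
    vcd: np.ndarray
    titer: np.ndarray | None = None
    metabolites: dict[str, np.ndarray] = field(default_factory=dict)
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vcd = np.asarray(self.vcd, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need >= 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.vcd.shape != self.times.shape:
            raise ValueError("vcd must share the time grid")
        if np.any(self.vcd <= 0):
            raise ValueError("vcd must be positive at all points")
        if self.titer is not None:
            self.titer = np.asarray(self.titer, dtype=float)
            if self.titer.shape != self.times.shape:
                raise ValueError("titer must share the time grid")
        for name, series in self.metabolites.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.times.shape:
                raise ValueError(f"{name} series must share the time grid")
            self.metabolites[name] = series

    def window_mask(self, window: tuple[float, float] | None) -> np.ndarray:
        if window is None:
            return np.ones_like(self.times, dtype=bool)
        lo, hi = window
        if lo > hi:
            raise ValueError("window start exceeds window end")
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError(f"window [{lo}, {hi}] contains no samples")
        return mask


@dataclass
class RateEstimates:
    """Estimated culture rates with the window and diagnostics used."""

    mu_per_h: float
    qp_pg_per_cell_day: float | None
    exchange_rates: dict[str, float]
    window: tuple[float, float] | None
    diagnostics: dict[str, float] = field(default_factory=dict)


def _derivative(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Central differences; one-sided at the endpoints."""
    return np.gradient(y, t)


def growth_rate_estimate(tc: TimeCourse,
                         window: tuple[float, float] | None = None,
                         method: str = "loglinear") -> float:
    """Growth rate in 1/h over the window.

    ``loglinear`` fits ln(VCD) against time by least squares and returns the
    slope (needs >= 3 samples); ``pointwise`` averages the central-difference
    derivative of VCD divided by VCD (needs >= 2 samples).
    """
    mask = tc.window_mask(window)
    t, v = tc.times[mask], tc.vcd[mask]
    if method == "loglinear":
        if len(t) < 3:
            raise ValueError("loglinear method needs >= 3 samples in window")
        slope = np.polyfit(t, np.log(v), 1)[0]
        return float(slope)
    if method == "pointwise":
        if len(t) < 2:
            raise ValueError("pointwise method needs >= 2 samples in window")
        return float(np.mean(_derivative(v, t) / v))
    raise ValueError(f"unknown method {method!r}")


def specific_productivity_estimate(tc: TimeCourse,
                                   window: tuple[float, float] | None = None,
                                   method: str = "cumulative") -> float:
    """Specific productivity in pg/cell/day over the window.

    ``cumulative`` regresses titer on the trapezoidal integral of VCD
    (cumulative cell-hours), the robust estimator; ``pointwise`` averages the
    titer derivative divided by VCD. Negative estimates (product consumption)
    are returned as-is.
    """
    if tc.titer is None:
        raise ValueError("time course has no titer series")
    mask = tc.window_mask(window)
    t, v, titer = tc.times[mask], tc.vcd[mask], tc.titer[mask]
    if len(t) < 2:
        raise ValueError("need >= 2 samples in window")
    hours_per_day = 24.0
    if method == "cumulative":
        cum_cell_hours = np.concatenate(
            [[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))]
        )
        slope = np.polyfit(cum_cell_hours, titer, 1)[0]  # (mg/L)/(cell h/mL)
        qp_per_hour = slope * _PG_PER_ML_PER_MG_PER_L  # pg/(cell h)
        return float(qp_per_hour * hours_per_day)
    if method == "pointwise":
        qp_h = np.mean(_derivative(titer, t) / v)  # (mg/L/h)/(cells/mL)
        return float(qp_h * _PG_PER_ML_PER_MG_PER_L * hours_per_day)
    raise ValueError(f"unknown method {method!r}")


def exchange_rate_estimate(tc: TimeCourse, metabolite: str,
                           window: tuple[float, float] | None = None,
                           conv: UnitConversionConfig = UnitConversionConfig(),
                           method: str = "cumulative") -> float:
    """Exchange rate of a metabolite in mmol/gDW/h over the window.

    Concentration derivative divided by biomass density (VCD times cell dry
    weight). Consumption is negative, production positive.
    """
    if metabolite not in tc.metabolites:
        raise ValueError(f"no series for metabolite {metabolite!r}")
    mask = tc.window_mask(window)
    t, v = tc.times[mask], tc.vcd[mask]
    conc = tc.metabolites[metabolite][mask]
    if len(t) < 2:
        raise ValueError("need >= 2 samples in window")
    # biomass density gDW/L = VCD[cells/mL] * 1e3[mL/L] * DW[pg] * 1e-12[g/pg]
    if method == "cumulative":
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))]
        )
        slope = np.polyfit(cum, conc, 1)[0]  # mM per (cell h/mL)
        return float(slope / (1.0e3 * conv.cell_dry_weight_pg * 1.0e-12))
    if method == "pointwise":
        gdw_per_l = v * 1.0e3 * conv.cell_dry_weight_pg * 1.0e-12
        return float(np.mean(_derivative(conc, t) / gdw_per_l))
    raise ValueError(f"unknown method {method!r}")


def estimate_rates(tc: TimeCourse,
                   window: tuple[float, float] | None = None,
                   conv: UnitConversionConfig = UnitConversionConfig()
                   ) -> RateEstimates:
    """Estimate mu, q_p and every metabolite exchange rate over one window."""
    mu = growth_rate_estimate(tc, window)
    qp = (specific_productivity_estimate(tc, window)
          if tc.titer is not None else None)
    exchange = {name: exchange_rate_estimate(tc, name, window, conv)
                for name in tc.metabolites}
    mask = tc.window_mask(window)
    t = tc.times[mask]
    resid = np.log(tc.vcd[mask]) - np.polyval(
        np.polyfit(t, np.log(tc.vcd[mask]), 1), t)
    return RateEstimates(
        mu_per_h=mu, qp_pg_per_cell_day=qp, exchange_rates=exchange,
        window=window,
        diagnostics={"loglinear_rmse": float(np.sqrt(np.mean(resid**2)))},
    )


def productivity_to_flux(qp_pg_per_cell_day: float, molecular_weight: float,
                         conv: UnitConversionConfig = UnitConversionConfig()
                         ) -> float:
    """Convert q_p [pg/cell/day] to a demand flux [mmol/gDW/h]."""
    if qp_pg_per_cell_day < 0:
        raise ValueError("qp must be >= 0")
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    return (1000.0 * qp_pg_per_cell_day
            / (conv.cell_dry_weight_pg * molecular_weight * conv.hours_per_day))


def flux_to_productivity(flux_mmol_gdw_h: float, molecular_weight: float,
                         conv: UnitConversionConfig = UnitConversionConfig()
                         ) -> float:
    """Exact inverse of :func:`productivity_to_flux`."""
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    return (flux_mmol_gdw_h * conv.cell_dry_weight_pg * molecular_weight
            * conv.hours_per_day / 1000.0)


def read_timecourse_csv(path: str, replicate_id: str = "") -> TimeCourse:
    """Read a time course from CSV.

    Expected columns: ``time_h``, ``vcd_cells_per_ml``, optionally
    ``titer_mg_per_l`` and any number of ``<metabolite>_mM`` columns.
    """
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("time_h", "vcd_cells_per_ml"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    mets = {c[:-3]: df[c].to_numpy() for c in df.columns if c.endswith("_mM")}
    return TimeCourse(
        times=df["time_h"].to_numpy(),
        vcd=df["vcd_cells_per_ml"].to_numpy(),
        titer=(df["titer_mg_per_l"].to_numpy()
               if "titer_mg_per_l" in df.columns else None),
        metabolites=mets,
        replicate_id=replicate_id,
    )
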