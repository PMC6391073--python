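"""Culture physiology calculus: growth rates, gas exchange, morphology.

Covers the quantities derived from turbidostat and probe traces:
specific growth rate from the OD680 signal or from medium consumption,
doubling times, net/gross photosynthesis and dark respiration from
dissolved-O2 traces recorded through alternating 5-min light/dark phases,
the derived P:R and PQ ratios, spherical-cell morphology conversions, and
the nutrient refill-vs-consumption balance of quasi-continuous cultivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# growth rate estimation
# ---------------------------------------------------------------------------

@dataclass
class ODTrace:
    """Optical-density (680 nm) time series from a turbidostat culture.

    ``time`` in hours (strictly increasing), ``od680`` dimensionless and
    positive.  ``dilution_events`` marks the reset times; if omitted they
    are detected as relative OD drops larger than ``drop_threshold``
    between consecutive samples.
    """

    time: np.ndarray
    od680: np.ndarray
    dilution_events: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od680 = np.asarray(self.od680, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.od680.shape:
            raise ValueError("time and od680 must be 1-D and equally long")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od680 <= 0):
            raise ValueError("od680 must be positive")
        if self.dilution_events is not None:
            self.dilution_events = np.asarray(self.dilution_events,
                                              dtype=float)

    def detect_dilutions(self, drop_threshold: float = 0.03) -> np.ndarray:
        """Timestamps where OD drops by more than ``drop_threshold`` (rel.)."""
        rel = np.diff(self.od680) / self.od680[:-1]
        idx = np.where(rel < -drop_threshold)[0] + 1
        return self.time[idx]

    def segments(self, drop_threshold: float = 0.03) -> list[slice]:
        """Index slices of the inter-dilution growth segments."""
        events = (self.dilution_events if self.dilution_events is not None
                  else self.detect_dilutions(drop_threshold))
        bounds = [0]
        for t in np.sort(events):
            i = int(np.searchsorted(self.time, t))
            if i - bounds[-1] >= 1:
                bounds.append(i)
        bounds.append(len(self.time))
        return [slice(a, b) for a, b in zip(bounds, bounds[1:]) if b - a >= 2]


def growth_rate_from_od(trace: ODTrace,
                        window: tuple[float, float] | None = None,
                        drop_threshold: float = 0.03,
                        ) -> tuple[float, float, pd.DataFrame]:
    """Specific growth rate mu = ln(OD(t2)/OD(t1)) / (t2 - t1).

    Evaluated per inter-dilution segment (endpoint form, which equals the
    log-linear regression exactly for noiseless exponential growth);
    returns ``(mean, sd, per_segment_table)`` over all segments that fall
    inside ``window`` (whole trace if None).

    Raises if the requested window spans a dilution event without
    segmentation being possible (fewer than 2 samples per segment).
    """
    t0, t1 = window if window is not None else (trace.time[0], trace.time[-1])
    if t1 <= t0:
        raise ValueError("window must have positive length")
    rows = []
    for seg in trace.segments(drop_threshold):
        ts, od = trace.time[seg], trace.od680[seg]
        keep = (ts >= t0) & (ts <= t1)
        if keep.sum() < 2:
            continue
        ts, od = ts[keep], od[keep]
        mu = math.log(od[-1] / od[0]) / (ts[-1] - ts[0])
        rows.append({"t_start": ts[0], "t_end": ts[-1], "mu": mu})
    if not rows:
        raise ValueError(
            "window contains no growth segment with >= 2 samples; "
            "it may span a dilution event")
    table = pd.DataFrame(rows)
    mean = float(table["mu"].mean())
    sd = float(table["mu"].std(ddof=1)) if len(table) > 1 else 0.0
    return mean, sd, table


def doubling_time(mu: float) -> float:
    """Doubling time TD = ln 2 / mu (hours) for mu in h^-1."""
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    return LN2 / mu


@dataclass(frozen=True)
class BalanceTrace:
    """Medium-consumption summary: average inflow f (mL/h), volume V (mL)."""

    f: float
    V: float

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError("culture volume V must be > 0")
        if self.f < 0:
            raise ValueError("flow rate f must be >= 0")


def growth_rate_from_balance(trace: BalanceTrace) -> float:
    """Specific growth rate mu = f / V from medium depletion."""
    return trace.f / trace.V


def flow_rate_from_readings(time_h: Sequence[float],
                            mass_g: Sequence[float],
                            density: float = 1.0) -> tuple[float, float]:
    """Average inflow rate (mL/h) and its SE from balance readings.

    The spare-medium bottle loses mass as the culture is diluted; the
    negative OLS slope of mass over time divided by the medium density is
    the mean flow.  Returns ``(f_hat, se)``.
    """
    t = np.asarray(time_h, dtype=float)
    w = np.asarray(mass_g, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 readings")
    slope, _, se = _ols_slope(t, w)
    return -slope / density, se / density


# ---------------------------------------------------------------------------
# gas exchange
# ---------------------------------------------------------------------------

@dataclass
class GasExchangeRecord:
    """Photosynthesis / respiration rates with GP = NP + R_dark identity.

    All rates share one unit (tagged in ``units``), e.g.
    mmol O2 per gDW per h.  ``co2_uptake`` may be NaN when not measured.
    """

    NP: float
    R_dark: float
    co2_uptake: float = float("nan")
    units: str = "mmol gDW^-1 h^-1"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.R_dark < 0:
            raise ValueError("R_dark must be >= 0 after sign convention")

    @property
    def GP(self) -> float:
        """Gross photosynthesis: GP = NP + R (photorespiration neglected)."""
        return self.NP + self.R_dark


def gas_exchange_rates(time_s: Sequence[float], dO2: Sequence[float],
                       phases: Sequence[tuple[float, float, str]],
                       co2_efflux_deficit: float = float("nan"),
                       skip_transient_s: float = 30.0,
                       to_output_units: float = 1.0,
                       ) -> GasExchangeRecord:
    """Extract NP, R and GP from a dissolved-O2 trace with light/dark phases.

    Parameters
    ----------
    time_s, dO2
        Trace sampled while aeration is off (seconds, O2 concentration).
    phases
        Annotated intervals ``(t_start, t_end, "light"|"dark")``; slopes
        are estimated by OLS per phase excluding the first
        ``skip_transient_s`` seconds (mixing transient).
    co2_efflux_deficit
        Net CO2 uptake from the steady-state efflux deficit, already in
        output units.
    to_output_units
        Factor converting the raw slope (conc/s) to the output unit
        (e.g. per-gDW-per-hour given biomass and volume bookkeeping).

    NP is the mean light-phase slope; R_dark the negative of the mean
    dark-phase slope (clamped at 0 with a warning if positive);
    GP = NP + R_dark.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(dO2, dtype=float)
    if not phases:
        raise ValueError("phase annotation is required")
    slopes: dict[str, list[float]] = {"light": [], "dark": []}
    for start, end, kind in phases:
        if kind not in slopes:
            raise ValueError(f"unknown phase kind {kind!r}")
        keep = (t >= start + skip_transient_s) & (t <= end)
        if keep.sum() < 2:
            raise ValueError(f"phase ({start}, {end}) has < 2 usable samples")
        slope, _, _ = _ols_slope(t[keep], y[keep])
        slopes[kind].append(slope)
    if not slopes["light"] or not slopes["dark"]:
        raise ValueError("need at least one light and one dark phase")
    warnings = []
    NP = float(np.mean(slopes["light"])) * to_output_units
    dark = float(np.mean(slopes["dark"])) * to_output_units
    R = -dark
    if R < 0:
        warnings.append(f"positive dark-phase O2 slope ({dark:g}); "
                        "R_dark clamped at 0")
        R = 0.0
    return GasExchangeRecord(NP=NP, R_dark=R,
                             co2_uptake=co2_efflux_deficit,
                             warnings=warnings)


def photosynthesis_ratios(rec: GasExchangeRecord
                          ) -> tuple[float, float]:
    """(P:R, PQ) = (GP / R_dark, NP / CO2 uptake); NaN where undefined."""
    pr = rec.GP / rec.R_dark if rec.R_dark > 0 else float("nan")
    pq = (rec.NP / rec.co2_uptake
          if rec.co2_uptake and rec.co2_uptake > 0 else float("nan"))
    return pr, pq


# ---------------------------------------------------------------------------
# morphology and content conversions
# ---------------------------------------------------------------------------

def sphere_volume(diameter: float) -> float:
    """Volume pi d^3 / 6 of a spherical cell (um -> um^3)."""
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi * diameter ** 3 / 6.0


@dataclass(frozen=True)
class CellMorphology:
    """Spherical-cell morphology: diameter (um) with derived volume."""

    diameter: float
    dry_weight_pg: float
    counts_per_ml: float = float("nan")

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.dry_weight_pg <= 0:
            raise ValueError("diameter and dry weight must be > 0")

    @property
    def volume(self) -> float:
        return sphere_volume(self.diameter)


def per_gdw_to_per_cell(amount_mg_per_gdw: float,
                        dry_weight_pg_per_cell: float) -> float:
    """mg gDW^-1 x pg cell^-1 -> fg cell^-1 (exact unit bookkeeping).

    1 mg/g = 1e-3 (mass ratio); times pg = 1e-3 pg = 1 fg.
    """
    if dry_weight_pg_per_cell <= 0:
        raise ValueError("dry weight must be > 0")
    return amount_mg_per_gdw * dry_weight_pg_per_cell


def per_cell_to_per_gdw(amount_fg_per_cell: float,
                        dry_weight_pg_per_cell: float) -> float:
    """Inverse of :func:`per_gdw_to_per_cell`; exact round-trip."""
    if dry_weight_pg_per_cell <= 0:
        raise ValueError("dry weight must be > 0")
    return amount_fg_per_cell / dry_weight_pg_per_cell


# ---------------------------------------------------------------------------
# nutrient balance
# ---------------------------------------------------------------------------

def nutrient_balance(dilution_rate: float,
                     medium_mg_per_l: Mapping[str, float],
                     quota_mg_per_g: Mapping[str, float],
                     biomass_g_per_l: float) -> pd.DataFrame:
    """Refill-vs-consumption margin per element in quasi-continuous culture.

    refill = D * medium concentration; consumption = D * biomass * quota
    (at steady state the specific growth rate equals the dilution rate D).
    Elements present in only one of the tables are reported with NaN and
    flagged ``missing`` rather than raising.
    """
    if dilution_rate < 0 or biomass_g_per_l <= 0:
        raise ValueError("dilution rate must be >= 0 and biomass > 0")
    rows = []
    for element in sorted(set(medium_mg_per_l) | set(quota_mg_per_g)):
        refill = consumption = float("nan")
        status = "ok"
        if element in medium_mg_per_l:
            refill = dilution_rate * medium_mg_per_l[element]
        else:
            status = "missing in medium"
        if element in quota_mg_per_g:
            consumption = (dilution_rate * biomass_g_per_l
                           * quota_mg_per_g[element])
        else:
            status = "missing in quotas"
        margin = refill - consumption
        rows.append({
            "element": element, "refill": refill,
            "consumption": consumption, "margin": margin,
            "deficient": bool(margin < 0) if math.isfinite(margin) else False,
            "status": status,
        })
    return pd.DataFrame(rows)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, slope SE) by ordinary least squares."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate x values for slope estimation")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    if n > 2:
        se = math.sqrt(float((resid ** 2).sum()) / (n - 2) / sxx)
    else:
        se = 0.0
    return slope, intercept, se
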