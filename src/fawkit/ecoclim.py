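"""Simplified ecoclimatic-index (EI) model for climate suitability.

A desk-scale reimplementation of the ecoclimatic-index family of
species-distribution models, driven by 52-week series of mean
temperature (deg C) and soil moisture (dimensionless: 0 = bone dry,
1 = field capacity) and parameterized for fall armyworm:

* weekly Growth Index: product of trapezoidal temperature and moisture
  response functions (0 below/above the outer thresholds, 1 on the
  optimal plateau, linear ramps between); the annual GI is 100 times
  the weekly mean;
* four stress indices (cold, heat, dry, wet), each accumulating
  ``|rate| * deficit * 100`` per week beyond its threshold, capped at
  100 for the year;
* a degree-day gate: sum of ``max(0, T - DV0) * 7`` over weeks must
  reach PDD (the minimum to complete a generation) or EI is 0;
* EI = GI * SI with SI the product of ``(1 - S/100)`` over the four
  stresses, on a 0-100 scale where 100 is year-round incubator
  conditions.  EI >= 30 is conventionally favorable for long-term
  establishment; maps are often shaded at EI >= 33.

This is an explicit simplification of the commercial model it mimics:
no stress compounding over time, no internal soil-moisture hydrology
(soil moisture is a direct input), no irrigation or climate-change
scenarios.  Outputs are labelled "EI (simplified)".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ClimexParams",
    "WeeklyClimate",
    "EIResult",
    "temperature_index",
    "moisture_index",
    "annual_growth_index",
    "stress_indices",
    "degree_days",
    "ecoclimatic_index",
    "map_ei",
    "read_climate_csv",
    "write_climate_csv",
]

WEEKS_PER_YEAR = 52
DAYS_PER_WEEK = 7


@dataclass(frozen=True)
class ClimexParams:
    """Fall-armyworm parameter set.

    Temperature thresholds DV0..DV3 in deg C; soil-moisture thresholds
    SM0..SM3 dimensionless; stress thresholds paired with weekly
    accumulation rates (magnitudes used; published tables carry sign
    conventions on the cold/dry rates); PDD in degree-days per
    generation.
    """

    SM0: float = 0.15
    SM1: float = 0.8
    SM2: float = 1.5
    SM3: float = 2.5
    DV0: float = 12.0
    DV1: float = 25.0
    DV2: float = 30.0
    DV3: float = 39.0
    TTCS: float = 12.0
    THCS: float = -0.001
    TTHS: float = 39.0
    THHS: float = 0.005
    SMDS: float = 0.1
    HDS: float = -0.005
    SMWS: float = 3.0
    HWS: float = 0.002
    PDD: float = 600.0

    def __post_init__(self):
        if not self.SM0 < self.SM1 < self.SM2 < self.SM3:
            raise ValueError("soil-moisture thresholds must be increasing")
        if not self.DV0 < self.DV1 < self.DV2 < self.DV3:
            raise ValueError("temperature thresholds must be increasing")
        if self.PDD <= 0:
            raise ValueError("PDD must be positive")


@dataclass
class WeeklyClimate:
    """52 weekly records of mean temperature and soil moisture."""

    temperature: np.ndarray
    soil_moisture: np.ndarray

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.soil_moisture = np.asarray(self.soil_moisture, dtype=float)
        for name, arr in (("temperature", self.temperature),
                          ("soil_moisture", self.soil_moisture)):
            if arr.shape != (WEEKS_PER_YEAR,):
                raise ValueError(f"{name}: expected {WEEKS_PER_YEAR} weeks, "
                                 f"got shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name}: non-finite values")


@dataclass
class EIResult:
    GI: float
    CS: float
    HS: float
    DS: float
    WS: float
    SI: float
    degree_days: float
    EI: float
    favorable_30: bool = field(init=False)
    shaded_33: bool = field(init=False)

    def __post_init__(self):
        self.favorable_30 = self.EI >= 30.0
        self.shaded_33 = self.EI >= 33.0


def _trapezoid(x, lo, opt_lo, opt_hi, hi):
    x = np.asarray(x, dtype=float)
    up = (x - lo) / (opt_lo - lo)
    down = (hi - x) / (hi - opt_hi)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def temperature_index(T, params: ClimexParams = ClimexParams()):
    """Trapezoidal weekly temperature response on (DV0, DV1, DV2, DV3):
    zero at or below DV0 and at or above DV3, one on [DV1, DV2]."""
    return _trapezoid(T, params.DV0, params.DV1, params.DV2, params.DV3)


def moisture_index(SM, params: ClimexParams = ClimexParams()):
    """Trapezoidal weekly soil-moisture response on (SM0, SM1, SM2, SM3)."""
    return _trapezoid(SM, params.SM0, params.SM1, params.SM2, params.SM3)


def annual_growth_index(climate: WeeklyClimate,
                        params: ClimexParams = ClimexParams()) -> float:
    """GI = 100 * mean over weeks of (temperature index * moisture index)."""
    ti = temperature_index(climate.temperature, params)
    mi = moisture_index(climate.soil_moisture, params)
    return float(100.0 * np.mean(ti * mi))


def stress_indices(climate: WeeklyClimate,
                   params: ClimexParams = ClimexParams()) -> tuple[float, float, float, float]:
    """Annual (CS, HS, DS, WS), each min(100, sum of weekly
    ``|rate| * deficit * 100``) where the deficit is the excursion past
    the stress threshold (0 when the threshold is never crossed)."""
    T, SM = climate.temperature, climate.soil_moisture

    def accumulate(deficit, rate):
        weekly = abs(rate) * np.maximum(0.0, deficit) * 100.0
        return float(min(100.0, weekly.sum()))

    cs = accumulate(params.TTCS - T, params.THCS)
    hs = accumulate(T - params.TTHS, params.THHS)
    ds = accumulate(params.SMDS - SM, params.HDS)
    ws = accumulate(SM - params.SMWS, params.HWS)
    return cs, hs, ds, ws


def degree_days(climate: WeeklyClimate,
                params: ClimexParams = ClimexParams()) -> float:
    """Annual thermal accumulation above DV0:
    sum over weeks of ``max(0, T - DV0) * 7`` deg C-days."""
    return float(
        (np.maximum(0.0, climate.temperature - params.DV0) * DAYS_PER_WEEK).sum()
    )


def ecoclimatic_index(climate: WeeklyClimate,
                      params: ClimexParams = ClimexParams()) -> EIResult:
    """EI (simplified): GI scaled by the multiplicative stress index,
    gated to zero when annual degree-days fall short of PDD."""
    gi = annual_growth_index(climate, params)
    cs, hs, ds, ws = stress_indices(climate, params)
    si = (1 - cs / 100) * (1 - hs / 100) * (1 - ds / 100) * (1 - ws / 100)
    dd = degree_days(climate, params)
    ei = gi * si if dd >= params.PDD else 0.0
    ei = float(np.clip(ei, 0.0, 100.0))
    return EIResult(GI=gi, CS=cs, HS=hs, DS=ds, WS=ws, SI=si,
                    degree_days=dd, EI=ei)


def map_ei(temperature_grid, soil_moisture_grid,
           params: ClimexParams = ClimexParams()) -> dict[str, np.ndarray]:
    """Cell-wise EI over a rectangular grid.

    Inputs are arrays of shape (52, nrows, ncols); a cell with any NaN
    week is missing and propagates as NaN.  Returns ``{"EI", "GI",
    "mask_30", "mask_33"}``; the masks are float arrays (1/0 with NaN
    for missing) so missingness survives.
    """
    T = np.asarray(temperature_grid, dtype=float)
    SM = np.asarray(soil_moisture_grid, dtype=float)
    if T.shape != SM.shape or T.ndim != 3 or T.shape[0] != WEEKS_PER_YEAR:
        raise ValueError("expected matching (52, nrows, ncols) grids")
    _, nr, nc = T.shape
    ei = np.full((nr, nc), np.nan)
    gi = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            t, sm = T[:, i, j], SM[:, i, j]
            if np.isnan(t).any() or np.isnan(sm).any():
                continue
            res = ecoclimatic_index(WeeklyClimate(t, sm), params)
            ei[i, j], gi[i, j] = res.EI, res.GI
    mask_30 = np.where(np.isnan(ei), np.nan, (ei >= 30.0).astype(float))
    mask_33 = np.where(np.isnan(ei), np.nan, (ei >= 33.0).astype(float))
    return {"EI": ei, "GI": gi, "mask_30": mask_30, "mask_33": mask_33}


def read_climate_csv(path) -> WeeklyClimate:
    """Read a (week, temperature, soil_moisture) CSV into a series."""
    df = pd.read_csv(path)
    for col in ("week", "temperature", "soil_moisture"):
        if col not in df.columns:
            raise ValueError(f"climate CSV missing column {col!r}")
    df = df.sort_values("week")
    return WeeklyClimate(df["temperature"].to_numpy(),
                         df["soil_moisture"].to_numpy())


def write_climate_csv(climate: WeeklyClimate, path) -> None:
    pd.DataFrame(
        {
            "week": np.arange(1, WEEKS_PER_YEAR + 1),
            "temperature": climate.temperature,
            "soil_moisture": climate.soil_moisture,
        }
    ).to_csv(path, index=False)


def plot_ei_map(ei_grid: np.ndarray, path, shade_threshold: float = 33.0) -> None:
    """Render an EI grid as a raster with cells at or above the shading
    threshold hatched (the display convention for suitability maps)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ei_grid, origin="lower", cmap="viridis", vmin=0, vmax=100)
    shade = np.where(ei_grid >= shade_threshold, 1.0, np.nan)
    ax.contourf(shade, levels=[0.5, 1.5], hatches=["//"], colors="none")
    fig.colorbar(im, ax=ax, label="EI (simplified)")
    ax.set_title(f"Ecoclimatic index (shaded: EI >= {shade_threshold:g})")
    fig.savefig(path, dpi=120)
    plt.close(fig)
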